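"""Treatment-benefit evaluation within signature-defined subgroups.

Patients are stratified by the signature cutoff into a high-score
(NCHT-preferable) and a low-score (NHT-preferable) subgroup; within each,
the two arms are compared by Kaplan-Meier curves and the log-rank test, and
an overall Cox model {group, treatment, group x treatment} quantifies the
interaction between grouping and treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import CoxPH
from .km import KMCurve, km_estimate, logrank_test, median_survival
from .signature import assign_group

__all__ = ["SubgroupReport", "evaluate_subgroups", "unstratified_comparison",
           "multivariable_cox"]

ARM_NAMES = {0: "NCHT", 1: "NHT"}


@dataclass
class SubgroupBlock:
    """Per-subgroup summary: arm sizes, KM curves, log-rank, medians."""

    n: int
    n_per_arm: dict[str, int]
    evaluable: bool
    km: dict[str, KMCurve] = field(default_factory=dict)
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    median_per_arm: dict[str, float | None] = field(default_factory=dict)


@dataclass
class SubgroupReport:
    groups: dict[str, SubgroupBlock]
    interaction_hr: float | None
    interaction_ci: tuple[float, float] | None
    interaction_p: float | None
    n_total: int

    def to_dict(self) -> dict:
        out = {"n_total": self.n_total,
               "interaction": {"hr": self.interaction_hr,
                               "ci": self.interaction_ci,
                               "p": self.interaction_p},
               "groups": {}}
        for name, blk in self.groups.items():
            out["groups"][name] = {
                "n": blk.n, "n_per_arm": blk.n_per_arm,
                "evaluable": blk.evaluable,
                "logrank_chi2": blk.logrank_chi2, "logrank_p": blk.logrank_p,
                "median_per_arm": blk.median_per_arm,
            }
        return out


def _align(scores, clinical):
    scores = pd.Series(scores)
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns \
        else clinical
    if set(scores.index) != set(clin.index):
        raise ValueError("scores and clinical are misaligned")
    return scores, clin.loc[scores.index]


def evaluate_subgroups(scores, clinical: pd.DataFrame, cutoff: float) -> SubgroupReport:
    """Stratify by ``cutoff`` and compare arms within each subgroup.

    A subgroup missing an arm (or empty) is flagged non-evaluable rather
    than aborting the whole report.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores, clin = _align(scores, clinical)
    group = scores.map(lambda v: assign_group(v, cutoff))
    time = clin["time_months"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    arm = clin["treatment"].to_numpy(dtype=int)

    blocks: dict[str, SubgroupBlock] = {}
    for name in ("high", "low"):
        mask = (group == name).to_numpy()
        n = int(mask.sum())
        n_per_arm = {ARM_NAMES[a]: int(np.sum(arm[mask] == a)) for a in (0, 1)}
        blk = SubgroupBlock(n=n, n_per_arm=n_per_arm, evaluable=False)
        if n > 0 and min(n_per_arm.values()) > 0:
            tm, em, am = time[mask], event[mask], arm[mask]
            for a in (0, 1):
                curve = km_estimate(tm[am == a], em[am == a])
                blk.km[ARM_NAMES[a]] = curve
                blk.median_per_arm[ARM_NAMES[a]] = median_survival(curve)
            try:
                lr = logrank_test(tm[am == 0], em[am == 0],
                                  tm[am == 1], em[am == 1])
                blk.logrank_chi2, blk.logrank_p = lr.chi2, lr.p
                blk.evaluable = True
            except ValueError:
                pass
        blocks[name] = blk

    high = (group == "high").to_numpy(dtype=float)
    hr = ci = p = None
    if 0 < high.sum() < len(high):
        X = pd.DataFrame({"group": high, "treatment": arm.astype(float),
                          "interaction": high * arm})
        try:
            fit = CoxPH(time, event, X).fit()
            if fit.converged:
                hr, ci = fit.hazard_ratio("interaction")
                _, p = fit.wald_z("interaction")
        except ValueError:
            pass
    return SubgroupReport(groups=blocks, interaction_hr=hr, interaction_ci=ci,
                          interaction_p=p, n_total=len(scores))


@dataclass
class ArmComparison:
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    median_per_arm: dict[str, float | None]


def unstratified_comparison(clinical: pd.DataFrame) -> ArmComparison:
    """Whole-cohort arm comparison: log-rank plus single-covariate Cox HR.

    The hazard ratio is for NHT (t=1) relative to NCHT (t=0).
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns \
        else clinical
    time = clin["time_months"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    arm = clin["treatment"].to_numpy(dtype=int)
    if len(np.unique(arm)) < 2:
        raise ValueError("both treatment arms must be present")
    lr = logrank_test(time[arm == 0], event[arm == 0],
                      time[arm == 1], event[arm == 1])
    fit = CoxPH(time, event, pd.DataFrame({"treatment": arm.astype(float)})).fit()
    hr, ci = fit.hazard_ratio("treatment")
    medians = {}
    for a in (0, 1):
        medians[ARM_NAMES[a]] = median_survival(
            km_estimate(time[arm == a], event[arm == a]))
    return ArmComparison(logrank_chi2=lr.chi2, logrank_p=lr.p, hr=hr,
                         hr_ci=ci, median_per_arm=medians)


def multivariable_cox(clinical: pd.DataFrame, covariates: list[str],
                      *, time_col: str = "time_months", event_col: str = "event"):
    """Forest-plot style multivariable Cox fit over clinical covariates.

    Categorical columns are dummy-coded with the first category (in the
    declared order of appearance) as the reference level.
    """
    clin = clinical.reset_index(drop=True)
    parts = []
    for col in covariates:
        s = clin[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).rename(col))
        else:
            levels = list(pd.unique(s))
            for lev in levels[1:]:
                parts.append((s == lev).astype(float).rename(f"{col}[{lev}]"))
    X = pd.concat(parts, axis=1)
    return CoxPH(clin[time_col], clin[event_col], X).fit()
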