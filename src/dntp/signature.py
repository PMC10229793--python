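"""The z-weighted predictive signature (DNTP score) and its cutoff scan.

The differential neoadjuvant treatment predictive (DNTP) score of a patient
is the linear combination of signature-gene expression weighted by the
interaction z-scores from the screen:

    score = sum_g z_g * expr_g        (expr on the log2(TPM+1) scale)

Smaller scores indicate a relatively greater chance of benefiting from NHT,
larger scores from NCHT.  A single cutoff splits the cohort into a
high-score (NCHT-preferable) and a low-score (NHT-preferable) subgroup; the
cutoff is chosen by scanning candidate thresholds and minimising the Wald
p-value of the group-by-treatment interaction in a Cox model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import CoxPH, DegenerateDesignError
from .km import logrank_test

__all__ = ["SignatureModel", "PUBLISHED_SIGNATURE", "build_signature",
           "compute_score", "score_samples", "scan_cutoff", "assign_group",
           "CutoffScan"]


class SignatureError(ValueError):
    pass


@dataclass
class SignatureModel:
    """A gene -> weight map plus an optional score cutoff.

    Weights are interaction z-scores; the sign encodes treatment preference
    direction (positive: high expression favours NCHT).
    """

    weights: dict[str, float]
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.weights:
            raise SignatureError("signature has no genes")
        if any(w == 0 for w in self.weights.values()):
            raise SignatureError("zero weights are not allowed")

    @property
    def genes(self) -> list[str]:
        return list(self.weights)

    def to_json(self, path=None) -> str:
        payload = json.dumps({"weights": self.weights, "cutoff": self.cutoff},
                             indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "SignatureModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(weights={str(k): float(v) for k, v in obj["weights"].items()},
                   cutoff=obj.get("cutoff"))


#: The published 10-gene signature: Wald z-scores of the treatment-by-gene
#: interaction for each marker, and the score cutoff separating the
#: NCHT-preferable (>= cutoff) from the NHT-preferable (< cutoff) subgroup.
PUBLISHED_SIGNATURE = SignatureModel(
    weights={
        "GNAS": 3.74,
        "COX15": -3.65,
        "NMRK1": -3.693,
        "CLYBL": -4.332,
        "PNCK": -3.629,
        "MMS19": -3.75,
        "COL4A5": -3.514,
        "ZNF774": -3.569,
        "HBA1": -3.654,
        "DBNDD2": -3.496,
    },
    cutoff=-95.798,
)


def build_signature(results, alpha: float = 0.05) -> SignatureModel:
    """Build a signature from screen results: weights are the z-scores of
    every selected (p < alpha, converged) gene; the cutoff is left unset."""
    table = results.table if hasattr(results, "table") else pd.DataFrame(results)
    sel = table[(table["p"] < alpha) & table["converged"]]
    if len(sel) == 0:
        raise SignatureError("no genes pass the selection threshold")
    return SignatureModel(weights=dict(zip(sel["gene"], sel["z"])))


def compute_score(expr_vector, model: SignatureModel) -> float:
    """Evaluate the linear score for one patient.

    ``expr_vector`` maps gene -> log2(TPM+1).  Every signature gene must be
    present; missing genes raise rather than silently contributing zero.
    """
    missing = [g for g in model.weights if g not in expr_vector]
    if missing:
        raise SignatureError(f"expression vector is missing signature genes: "
                             f"{', '.join(missing)}")
    return float(sum(w * float(expr_vector[g]) for g, w in model.weights.items()))


def score_samples(expression: pd.DataFrame, model: SignatureModel) -> pd.Series:
    """Score every sample of a genes x samples expression matrix."""
    missing = [g for g in model.weights if g not in expression.index]
    if missing:
        raise SignatureError(f"expression matrix is missing signature genes: "
                             f"{', '.join(missing)}")
    w = pd.Series(model.weights)
    scores = expression.loc[w.index].T @ w
    scores.name = "score"
    return scores


def assign_group(score: float, cutoff: float) -> str:
    """"high" iff score >= cutoff (the cutoff itself belongs to the
    high-score, NCHT-preferable group)."""
    if not (np.isfinite(score) and np.isfinite(cutoff)):
        raise ValueError("score and cutoff must be finite")
    return "high" if score >= cutoff else "low"


@dataclass
class CutoffScan:
    """Chosen cutoff plus the per-candidate diagnostics surface."""

    cutoff: float
    diagnostics: pd.DataFrame = field(repr=False)
    objective: str = "interaction"


def scan_cutoff(scores, clinical: pd.DataFrame, *,
                min_group_fraction: float = 0.2,
                objective: str = "interaction") -> CutoffScan:
    """Scan score cutoffs and pick the best split.

    Candidate cutoffs are midpoints between consecutive sorted unique
    scores, restricted so that each side keeps at least
    ``min_group_fraction`` of patients and both arms appear on both sides.
    For each candidate a Cox model {group, treatment, group x treatment} is
    fitted and the interaction Wald p recorded; the default objective picks
    the candidate minimising it.  ``objective="logrank"`` instead maximises
    the smaller of the two within-group log-rank chi-squares.

    Diagnostics include, per candidate, the within-group log-rank p-values.
    """
    scores = pd.Series(scores)
    if scores.nunique() <= 1:
        raise SignatureError("scores are constant; no cutoff exists")
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns \
        else clinical
    if len(scores) != len(clin):
        raise ValueError("scores and clinical are misaligned")
    if not scores.index.equals(clin.index):
        if set(scores.index) != set(clin.index):
            raise ValueError("scores and clinical are misaligned")
        clin = clin.loc[scores.index]
    t = clin["treatment"].to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("both treatment arms must be present")
    time = clin["time_months"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    s = scores.to_numpy(dtype=float)
    n = len(s)
    uniq = np.unique(s)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    rows = []
    for c in candidates:
        high = s >= c
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_group_fraction * n:
            continue
        if len(np.unique(t[high])) < 2 or len(np.unique(t[~high])) < 2:
            continue
        X = pd.DataFrame({"group": high.astype(float), "treatment": t,
                          "interaction": high.astype(float) * t})
        try:
            fit = CoxPH(time, event, X).fit()
        except (DegenerateDesignError, ValueError):
            continue
        if fit.converged:
            _, p_inter = fit.wald_z("interaction")
        else:
            p_inter = np.nan
        lr = {}
        for label, mask in (("high", high), ("low", ~high)):
            tm, em, am = time[mask], event[mask], t[mask]
            try:
                res = logrank_test(tm[am == 1], em[am == 1],
                                   tm[am == 0], em[am == 0])
                lr[label] = (res.chi2, res.p)
            except ValueError:
                lr[label] = (np.nan, np.nan)
        rows.append({"cutoff": c, "n_high": n_high, "n_low": n - n_high,
                     "interaction_p": p_inter,
                     "logrank_chi2_high": lr["high"][0],
                     "logrank_p_high": lr["high"][1],
                     "logrank_chi2_low": lr["low"][0],
                     "logrank_p_low": lr["low"][1],
                     "converged": fit.converged})
    diag = pd.DataFrame(rows)
    if len(diag) == 0:
        raise SignatureError("no admissible cutoff candidate")
    if objective == "interaction":
        usable = diag[diag["interaction_p"].notna()]
        if len(usable) == 0:
            raise SignatureError("no candidate produced a converged fit")
        best = usable.loc[usable["interaction_p"].idxmin()]
    elif objective == "logrank":
        crit = diag[["logrank_chi2_high", "logrank_chi2_low"]].min(axis=1)
        best = diag.loc[crit.idxmax()]
    else:
        raise ValueError(f"unknown objective {objective!r}")
    return CutoffScan(cutoff=float(best["cutoff"]), diagnostics=diag,
                      objective=objective)
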