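"""Synthetic two-arm neoadjuvant cohorts with planted interaction effects.

The generator emulates the study design the pipeline targets: a 64-patient
cohort split 32/32 between neoadjuvant chemo-hormonal therapy (NCHT, t=0)
and hormonal therapy alone (NHT, t=1), biochemical progression-free
survival with roughly a 58% event rate and a median near 10 months, and
log2(TPM+1) expression.  Event times follow the proportional-hazards model

    h_i(t) = h0(t) * exp(b_treat * t_i + sum_g b_main_g * g_i
                         + sum_g b_inter_g * t_i * g_i)

sampled by inverse transform; censoring is the minimum of an independent
exponential and an administrative horizon.

One seed drives everything through independent substreams (assignment,
expression, event times, censoring, covariates), so changing ``n_genes``
does not perturb the clinical draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["BaselineHazard", "SyntheticConfig", "SyntheticCohort",
           "generate_cohort", "generate_split_cohort"]

LN2 = math.log(2.0)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineHazard:
    """Parametric baseline hazard, per month.

    kind="exponential": constant rate ``rate``.
    kind="weibull": shape k and scale s with S0(t) = exp(-(t/s)^k).
    """

    kind: str = "exponential"
    rate: float = LN2 / 10.0     # median 10 months
    shape: float = 1.0
    scale: float = 10.0 / LN2

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "weibull"):
            raise ConfigurationError(f"unknown baseline hazard {self.kind!r}")
        if self.kind == "exponential" and self.rate <= 0:
            raise ConfigurationError("baseline rate must be positive")
        if self.kind == "weibull" and (self.shape <= 0 or self.scale <= 0):
            raise ConfigurationError("Weibull shape/scale must be positive")

    def inverse_cumulative(self, u: np.ndarray, lp: np.ndarray) -> np.ndarray:
        """Event time T with S(T | lp) = u, by inverting H0(t)*exp(lp)."""
        target = -np.log(u) / np.exp(lp)
        if self.kind == "exponential":
            return target / self.rate
        return self.scale * target ** (1.0 / self.shape)

    def survival(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "exponential":
            return np.exp(-self.rate * t)
        return np.exp(-((t / self.scale) ** self.shape))


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generation parameters; defaults mirror the target study design."""

    n_patients: int = 64
    arm_fraction: float = 0.5
    exact_split: bool = True
    n_genes: int = 200
    expr_mean: float = 3.0
    expr_sd: float = 1.0
    beta_treat: float = 0.0
    beta_main: dict[str, float] = field(default_factory=dict)
    beta_inter: dict[str, float] = field(default_factory=dict)
    baseline: BaselineHazard = field(default_factory=BaselineHazard)
    censor_rate: float = 0.05
    admin_censor_time: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("need at least 2 patients")
        if not 0.0 <= self.arm_fraction <= 1.0:
            raise ConfigurationError("arm_fraction must lie in [0, 1]")
        if self.n_genes < 1:
            raise ConfigurationError("need at least one gene")
        if self.expr_sd <= 0:
            raise ConfigurationError("expr_sd must be positive")
        if self.censor_rate <= 0 or self.admin_censor_time <= 0:
            raise ConfigurationError("censoring rates/horizon must be positive")
        named = set(self.beta_main) | set(self.beta_inter)
        unknown = named - set(self.gene_names)
        if unknown:
            raise ConfigurationError(
                f"effect genes not among the {self.n_genes} simulated genes: "
                f"{sorted(unknown)[:5]}")

    @property
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def sample_names(self) -> list[str]:
        width = max(3, len(str(self.n_patients)))
        return [f"P{i:0{width}d}" for i in range(1, self.n_patients + 1)]


@dataclass
class SyntheticCohort:
    """Expression + clinical tables plus the generating configuration."""

    expression: pd.DataFrame  # genes x samples, log2(TPM+1)
    clinical: pd.DataFrame    # one row per patient
    truth: SyntheticConfig

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.clinical["sample_id"]):
            raise ValueError("expression and clinical sample order differ")


def _substreams(seed: int):
    ss = np.random.SeedSequence(seed)
    keys = ("assignment", "expression", "event", "censor", "covariates")
    return dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))


def _draw_assignment(cfg: SyntheticConfig, rng) -> np.ndarray:
    n = cfg.n_patients
    if cfg.exact_split:
        n1 = int(round(cfg.arm_fraction * n))
        arm = np.zeros(n, dtype=int)
        arm[rng.permutation(n)[:n1]] = 1
        return arm
    return (rng.random(n) < cfg.arm_fraction).astype(int)


def _draw_expression(cfg: SyntheticConfig, rng) -> pd.DataFrame:
    vals = rng.normal(cfg.expr_mean, cfg.expr_sd,
                      size=(cfg.n_genes, cfg.n_patients))
    np.maximum(vals, 0.0, out=vals)  # truncate at 0: log2(TPM+1) >= 0
    return pd.DataFrame(vals, index=cfg.gene_names, columns=cfg.sample_names)


# marginal frequencies used for the nuisance clinical covariates
_PSA_CATS = (["0-10 ng/ml", "10-20 ng/ml", "20-100 ng/ml", ">100 ng/ml"],
             [2 / 64, 2 / 64, 32 / 64, 28 / 64])
_T_CATS = (["T2c", "T3a", "T3b", "T4"], [3 / 64, 21 / 64, 21 / 64, 19 / 64])


def _draw_covariates(cfg: SyntheticConfig, rng) -> pd.DataFrame:
    n = cfg.n_patients
    age = np.clip(np.round(rng.normal(68.0, 5.4, n)), 50, 75).astype(int)
    return pd.DataFrame({
        "age": age,
        "psa_cat": rng.choice(_PSA_CATS[0], size=n, p=_PSA_CATS[1]),
        "gleason_cat": rng.choice(["<8", ">=8"], size=n, p=[23 / 64, 41 / 64]),
        "t_stage": rng.choice(_T_CATS[0], size=n, p=_T_CATS[1]),
        "n_stage": rng.choice(["N0", "N1"], size=n, p=[0.5, 0.5]),
    })


def _linear_predictor(cfg: SyntheticConfig, arm, expression) -> np.ndarray:
    lp = cfg.beta_treat * arm.astype(float)
    for gene, b in cfg.beta_main.items():
        lp = lp + b * expression.loc[gene].to_numpy()
    for gene, b in cfg.beta_inter.items():
        lp = lp + b * arm * expression.loc[gene].to_numpy()
    return lp


def _assemble(cfg, arm, expression, lp, rngs) -> SyntheticCohort:
    u = rngs["event"].random(cfg.n_patients)
    event_time = cfg.baseline.inverse_cumulative(u, lp)
    censor_time = rngs["censor"].exponential(1.0 / cfg.censor_rate,
                                             cfg.n_patients)
    observed = np.minimum(np.minimum(event_time, censor_time),
                          cfg.admin_censor_time)
    # guard: strictly positive observed times
    observed = np.maximum(observed, 1e-9)
    event = (event_time <= np.minimum(censor_time,
                                      cfg.admin_censor_time)).astype(int)
    clinical = pd.DataFrame({"sample_id": cfg.sample_names,
                             "treatment": arm,
                             "time_months": observed,
                             "event": event})
    clinical = pd.concat([clinical, _draw_covariates(cfg, rngs["covariates"])],
                         axis=1)
    return SyntheticCohort(expression=expression, clinical=clinical, truth=cfg)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort from the configured proportional-hazards model.

    Identical seeds give bit-identical cohorts.
    """
    rngs = _substreams(config.seed)
    arm = _draw_assignment(config, rngs["assignment"])
    expression = _draw_expression(config, rngs["expression"])
    lp = _linear_predictor(config, arm, expression)
    return _assemble(config, arm, expression, lp, rngs)


def generate_split_cohort(config: SyntheticConfig, signature, true_cutoff: float,
                          benefit_hr: float) -> SyntheticCohort:
    """Cohort with a true treatment-benefit crossover at a score threshold.

    Patients whose signature score is >= ``true_cutoff`` get hazard
    multiplier ``benefit_hr`` under NHT (t=1) and 1 under NCHT; patients
    below get the reverse.  ``benefit_hr > 1`` therefore makes the
    high-score group benefit from NCHT and the low-score group from NHT;
    ``benefit_hr = 1`` reduces to :func:`generate_cohort`.
    """
    if benefit_hr <= 0:
        raise ConfigurationError("benefit_hr must be positive")
    missing = [g for g in signature.weights if g not in config.gene_names]
    if missing:
        raise ConfigurationError(
            f"signature genes absent from the simulated genes: {missing[:5]}")
    rngs = _substreams(config.seed)
    arm = _draw_assignment(config, rngs["assignment"])
    expression = _draw_expression(config, rngs["expression"])
    from .signature import score_samples

    scores = score_samples(expression, signature).to_numpy()
    high = scores >= true_cutoff
    log_hr = math.log(benefit_hr)
    crossover = np.where(high, arm * log_hr, (1 - arm) * log_hr)
    lp = _linear_predictor(config, arm, expression) + crossover
    return _assemble(config, arm, expression, lp, rngs)


def null_config(**overrides) -> SyntheticConfig:
    """A convenience all-null configuration (no treatment or gene effects)."""
    return replace(SyntheticConfig(), **overrides)
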