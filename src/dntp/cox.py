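"""Cox proportional-hazards fitting by Newton-Raphson on the partial likelihood.

This is the statistical engine behind the gene-by-treatment interaction
screen and the subgroup evaluation.  The model is

    h_i(t) = h0(t) * exp(x_i' beta)

and ``beta`` is estimated by maximising the partial likelihood, with Efron's
approximation for tied event times (Breslow available by option).  Inference
is Wald-type from the inverse observed information.

The implementation is deliberately self-contained: the screening stage needs
access to convergence diagnostics per gene (monotone-likelihood fits must be
surfaced, not silently stabilised), and the subgroup report asserts exact
internal consistency between the interaction hazard ratio and the Wald test,
both of which are easier to guarantee against a single in-package fitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateDesignError(ValueError):
    """Raised when the covariate matrix cannot identify the coefficients."""


@dataclass
class SurvivalData:
    """Right-censored survival data with covariates.

    Parameters
    ----------
    time : array-like of positive floats, months
    event : array-like of {0, 1}
    covariates : DataFrame (subjects x named columns)
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(np.asarray(self.covariates, dtype=float))
            self.covariates.columns = [f"x{j}" for j in range(self.covariates.shape[1])]
        n = len(self.time)
        if len(self.event) != n or len(self.covariates) != n:
            raise ValueError("time, event and covariates must have equal length")
        if n == 0:
            raise ValueError("empty survival data")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("times must be positive and finite")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0/1")
        if self.event.sum() == 0:
            raise ValueError("at least one event is required for fitting")
        vals = self.covariates.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError("covariates contain missing or non-finite values")


class CoxPH:
    """Cox proportional-hazards model (statsmodels-style: build, then ``fit``).

    Parameters
    ----------
    time, event, covariates
        See :class:`SurvivalData`; a prepared ``SurvivalData`` may be passed
        as the single first argument.
    ties : {"efron", "breslow"}
        Handling of tied event times.  Efron is the default.
    """

    def __init__(self, time, event=None, covariates=None, *, ties: str = "efron"):
        if isinstance(time, SurvivalData):
            data = time
        else:
            data = SurvivalData(time, event, covariates)
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie method {ties!r}")
        self.data = data
        self.ties = ties
        X = data.covariates.to_numpy(dtype=float)
        sd = X.std(axis=0)
        for j, s in enumerate(sd):
            if s == 0.0:
                raise DegenerateDesignError(
                    f"covariate {data.covariates.columns[j]!r} is constant"
                )
        self._sd = sd
        # sort ascending by time; at equal times events stay at risk together
        # with censorings (risk set = {time >= t}), the standard convention.
        order = np.argsort(data.time, kind="stable")
        self._T = data.time[order]
        self._E = data.event[order]
        self._X = X[order]
        self.exog_names = list(data.covariates.columns)
        self.nobs = len(self._T)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, time_col: str = "time_months",
                       event_col: str = "event", covariate_cols=None, ties="efron"):
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns if c not in (time_col, event_col)]
        return cls(df[time_col], df[event_col], df[covariate_cols], ties=ties)

    # -- partial likelihood -------------------------------------------------

    def _loglik_grad_hess(self, beta: np.ndarray):
        T, E, X = self._T, self._E, self._X
        n, p = X.shape
        eta = X @ beta
        eta = eta - eta.max()  # overflow guard; PL is invariant to the shift
        w = np.exp(eta)
        wx = w[:, None] * X
        wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])
        # reverse cumulative sums: entry i = sum over subjects with index >= i
        S = np.cumsum(w[::-1])[::-1]
        Z = np.cumsum(wx[::-1], axis=0)[::-1]
        Q = np.cumsum(wxx[::-1], axis=0)[::-1]

        ll = 0.0
        g = np.zeros(p)
        H = np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            while j < n and T[j] == T[i]:
                j += 1
            tied = [k for k in range(i, j) if E[k] == 1]
            d = len(tied)
            if d > 0:
                s_r, z_r, q_r = S[i], Z[i], Q[i]
                xs = X[tied]
                ll += float(eta[tied].sum())
                if self.ties == "efron":
                    s_d = w[tied].sum()
                    z_d = wx[tied].sum(axis=0)
                    q_d = wxx[tied].sum(axis=0)
                else:
                    s_d = 0.0
                    z_d = np.zeros(p)
                    q_d = np.zeros((p, p))
                g += xs.sum(axis=0)
                for l in range(d):
                    frac = l / d if self.ties == "efron" else 0.0
                    s_l = s_r - frac * s_d
                    z_l = z_r - frac * z_d
                    q_l = q_r - frac * q_d
                    ll -= math.log(s_l)
                    zl_over = z_l / s_l
                    g -= zl_over
                    H -= q_l / s_l - np.outer(zl_over, zl_over)
            i = j
        return ll, g, H

    def loglike(self, beta) -> float:
        """Partial log-likelihood at ``beta`` (useful for oracle checks)."""
        beta = np.asarray(beta, dtype=float)
        return self._loglik_grad_hess(beta)[0]

    # -- fitting ------------------------------------------------------------

    def fit(self, *, start=None, max_iter: int = 100, tol_score: float = 1e-9,
            tol_step: float = 1e-10) -> "CoxPHResults":
        """Newton-Raphson with step-halving; starts at beta = 0.

        Convergence requires the score sup-norm below ``tol_score`` or a step
        change below ``tol_step``.  Monotone likelihoods (perfect separation)
        leave ``converged`` False and are reported, never masked.
        """
        p = self._X.shape[1]
        beta = np.zeros(p) if start is None else np.asarray(start, dtype=float)
        ll, g, H = self._loglik_grad_hess(beta)
        ll_path = [ll]
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError as exc:
                raise DegenerateDesignError(
                    "singular information matrix (collinear covariates?)"
                ) from exc
            # step-halving: the partial log-likelihood must not decrease
            scale = 1.0
            for _ in range(40):
                cand = beta + scale * step
                ll_new, g_new, H_new = self._loglik_grad_hess(cand)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            step_change = float(np.max(np.abs(scale * step)))
            beta, ll, g, H = cand, ll_new, g_new, H_new
            ll_path.append(ll)
            if float(np.max(np.abs(g))) < tol_score or step_change < tol_step:
                converged = True
                break
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            converged = False
        # monotone likelihood (separation): on the scale-invariant
        # standardised axes the estimate runs away and the curvature
        # flattens out; flag, never stabilise.
        se_std = np.sqrt(np.maximum(np.diag(cov), 0.0)) * self._sd
        if np.any(np.abs(beta) * self._sd > 20) or np.any(se_std > 50):
            converged = False
        cov = (cov + cov.T) / 2.0
        return CoxPHResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            llf=ll,
            n_iter=n_iter,
            converged=converged,
            llf_path=ll_path,
        )


@dataclass
class CoxPHResults:
    """Fit results: estimates, covariance, Wald inference, summary table."""

    model: CoxPH
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n_iter: int
    converged: bool
    llf_path: list = field(default_factory=list, repr=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def wald_z(self, name: str) -> tuple[float, float]:
        """Wald statistic z = beta/se(beta) and its two-sided normal p."""
        if name not in self.params.index:
            raise KeyError(name)
        se = float(self.bse[name])
        if not se > 0:
            raise ValueError(f"zero variance for covariate {name!r}")
        z = float(self.params[name]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        return z, p

    def hazard_ratio(self, name: str, alpha: float = 0.05):
        """exp(beta) with a Wald 1-alpha confidence interval."""
        b = float(self.params[name])
        se = float(self.bse[name])
        q = stats.norm.ppf(1 - alpha / 2)
        return math.exp(b), (math.exp(b - q * se), math.exp(b + q * se))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.params.index:
            z, p = self.wald_z(name)
            hr, (lo, hi) = self.hazard_ratio(name)
            rows.append({"coef": self.params[name], "se(coef)": self.bse[name],
                         "HR": hr, "HR 95% low": lo, "HR 95% high": hi,
                         "z": z, "p": p})
        return pd.DataFrame(rows, index=self.params.index)


def wald_z(fit: CoxPHResults, name: str) -> tuple[float, float]:
    """Module-level alias for :meth:`CoxPHResults.wald_z`."""
    return fit.wald_z(name)


def fit_cox(time, event, covariates, *, ties: str = "efron", **fit_kw) -> CoxPHResults:
    """Convenience wrapper: build a :class:`CoxPH` and fit it."""
    return CoxPH(time, event, covariates, ties=ties).fit(**fit_kw)


_Z975 = 1.959964


def z_from_hr_ci(hr: float, ci_low: float, ci_high: float) -> float:
    """Reconstruct a Wald z from a hazard ratio and its 95% CI.

    The CI half-width on the log scale equals 1.959964 standard errors, so

        z = ln(hr) / ((ln(ci_high) - ln(ci_low)) / (2 * 1.959964))

    Used to audit the internal consistency of published interaction tables.
    """
    if hr <= 0 or ci_low <= 0 or ci_high <= 0:
        raise ValueError("hazard ratio and CI bounds must be positive")
    if not (ci_low <= hr <= ci_high):
        raise ValueError("CI must contain the hazard ratio")
    if hr == 1.0 and ci_low == ci_high:
        return 0.0
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * _Z975)
    if se == 0:
        raise ValueError("degenerate CI of zero width")
    return math.log(hr) / se
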