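"""Genome-wide gene-by-treatment interaction screening.

For each candidate gene g the three-covariate Cox model

    h_i(t) = h0(t) * exp(b1 * t_i + b2 * g_i + b3 * t_i * g_i)

is fitted, where t_i is the treatment arm (0 = NCHT, 1 = NHT) and g_i the
log2(TPM+1) expression.  The Wald statistic z = b3/se(b3) on the interaction
term measures predictive (treatment-modifying) value: a positive z means
high expression favours NCHT, negative favours NHT.  Genes with interaction
p below alpha are selected to seed the signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import CoxPH, DegenerateDesignError

__all__ = ["InteractionScreen", "InteractionScreenResults", "favor_label",
           "screen_genes"]


def favor_label(z: float) -> str:
    """Which arm high expression favours: NCHT when z > 0, NHT when z < 0."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if z > 0:
        return "NCHT"
    if z < 0:
        return "NHT"
    raise ValueError("z is exactly 0: no treatment preference")


class InteractionScreen:
    """Per-gene treatment-interaction Cox screen over an expression matrix.

    Parameters
    ----------
    expression : DataFrame, genes x samples, log2(TPM+1)
    clinical : DataFrame with columns sample_id, treatment, time_months, event
    alpha : selection threshold on the interaction p-value
    min_expr_fraction : a gene must be nonzero in at least this fraction of
        samples to enter the screen (default 0.2)
    """

    def __init__(self, expression: pd.DataFrame, clinical: pd.DataFrame, *,
                 alpha: float = 0.05, min_expr_fraction: float = 0.2):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        samples = list(expression.columns)
        clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns \
            else clinical
        if set(samples) != set(clin.index):
            raise ValueError("expression and clinical samples are misaligned")
        self.expression = expression
        self.clinical = clin.loc[samples]
        self.alpha = alpha
        self.min_expr_fraction = min_expr_fraction

    def fit(self, *, adjust: str | None = None) -> "InteractionScreenResults":
        """Fit the per-gene interaction models.

        adjust : None (raw p < alpha selection, the default) or "bh" for
            Benjamini-Hochberg adjusted selection.
        """
        t = self.clinical["treatment"].to_numpy(dtype=float)
        time = self.clinical["time_months"].to_numpy(dtype=float)
        event = self.clinical["event"].to_numpy(dtype=int)
        rows = []
        for gene, expr in self.expression.iterrows():
            g = expr.to_numpy(dtype=float)
            frac_nonzero = float(np.mean(g != 0))
            if frac_nonzero < self.min_expr_fraction:
                continue
            if g.std() == 0:
                warnings.warn(f"gene {gene!r} has zero variance; skipped")
                continue
            X = pd.DataFrame({"treatment": t, "gene": g, "interaction": t * g})
            try:
                res = CoxPH(time, event, X).fit()
            except DegenerateDesignError:
                warnings.warn(f"gene {gene!r}: degenerate design; skipped")
                continue
            beta3 = float(res.params["interaction"])
            se3 = float(res.bse["interaction"])
            if res.converged and se3 > 0:
                z, p = res.wald_z("interaction")
                ihr, (lo, hi) = res.hazard_ratio("interaction")
                favor = favor_label(z) if z != 0 else "none"
            else:
                z = p = ihr = lo = hi = np.nan
                favor = "none"
            rows.append({"gene": gene, "beta3": beta3, "se3": se3, "z": z,
                         "p": p, "ihr": ihr, "ci_low": lo, "ci_high": hi,
                         "favor": favor, "converged": res.converged})
        table = pd.DataFrame(rows)
        if len(table):
            table = table.sort_values("p", kind="stable", na_position="last")
            table = table.reset_index(drop=True)
            if adjust == "bh":
                from statsmodels.stats.multitest import multipletests

                ok = table["converged"] & table["p"].notna()
                padj = np.full(len(table), np.nan)
                if ok.any():
                    padj[ok.to_numpy()] = multipletests(
                        table.loc[ok, "p"], method="fdr_bh")[1]
                table["p_adj"] = padj
                table["selected"] = table["converged"] & (table["p_adj"] < self.alpha)
            elif adjust is None:
                table["selected"] = table["converged"] & (table["p"] < self.alpha)
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
        else:
            table["selected"] = pd.Series(dtype=bool)
        return InteractionScreenResults(table=table, alpha=self.alpha)


@dataclass
class InteractionScreenResults:
    """Screen output: one row per tested gene, ordered by p-value."""

    table: pd.DataFrame
    alpha: float

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    def summary(self) -> pd.DataFrame:
        cols = ["gene", "beta3", "se3", "z", "p", "ihr", "ci_low", "ci_high",
                "favor", "selected", "converged"]
        return self.table[[c for c in cols if c in self.table.columns]]

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def screen_genes(expression: pd.DataFrame, clinical: pd.DataFrame,
                 alpha: float = 0.05, min_expr_fraction: float = 0.2,
                 adjust: str | None = None) -> InteractionScreenResults:
    """Functional wrapper around :class:`InteractionScreen`."""
    screen = InteractionScreen(expression, clinical, alpha=alpha,
                               min_expr_fraction=min_expr_fraction)
    return screen.fit(adjust=adjust)
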