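"""Baseline cohort tables and the exact categorical/continuous tests.

Exact two-sided p-values follow the minimum-likelihood rule: sum, over all
tables with the observed margins, of the (multivariate) hypergeometric
probabilities no greater than that of the observed table.  This is the
convention of R's ``fisher.test`` and is what published clinical tables are
computed with.  2x2 tables go through scipy (same rule); r x c tables are
enumerated exactly in-package, since no installed Python routine offers the
exact conditional r x c test.
"""

from __future__ import annotations

import math
import warnings
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = ["ContingencyTable", "fisher_2x2", "fisher_rxc",
           "wilcoxon_rank_sum", "wilson_ci", "build_cohort_table",
           "format_percent"]


class EnumerationBoundError(RuntimeError):
    """Exact r x c enumeration would exceed the configured table budget."""


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("contingency table entries must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if arr.sum() == 0:
        raise ValueError("contingency table total must be positive")
    return arr.astype(np.int64)


class ContingencyTable:
    """r x c counts with optional row/column labels."""

    def __init__(self, counts, row_labels=None, col_labels=None):
        self.counts = _as_table(counts)
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        self.row_labels = list(row_labels) if row_labels else [str(i) for i in range(r)]
        self.col_labels = list(col_labels) if col_labels else [str(j) for j in range(c)]

    def fisher_p(self, **kwargs) -> float:
        if self.counts.shape == (2, 2):
            return fisher_2x2(self.counts)
        return fisher_rxc(self.counts, **kwargs)


def fisher_2x2(table) -> float:
    """Two-sided exact Fisher p for a 2x2 table (minimum-likelihood rule)."""
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_2x2 expects a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin: exact p defined as 1")
        return 1.0
    return float(stats.fisher_exact(arr)[1])


def _log_table_prob(arr, log_fact):
    # log multivariate hypergeometric probability given both margins
    rs, cs, n = arr.sum(axis=1), arr.sum(axis=0), arr.sum()
    lp = (log_fact[rs].sum() + log_fact[cs].sum() - log_fact[n]
          - log_fact[arr].sum())
    return lp


def fisher_rxc(table, *, max_tables: int = 2_000_000) -> float:
    """Exact conditional test for an r x c table by full enumeration.

    Enumerates every table with the observed margins (recursive
    margin-constrained composition of rows) and sums the probabilities of
    those no more probable than the observed table.  Reduces exactly to the
    2x2 test on 2x2 input.  Raises :class:`EnumerationBoundError` instead of
    silently falling back to Monte-Carlo when the enumeration exceeds
    ``max_tables``.
    """
    arr = _as_table(table)
    # zero rows/columns carry no information
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        warnings.warn("table degenerate after dropping empty margins; p = 1")
        return 1.0
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    n = int(arr.sum())
    log_fact = np.array([math.lgamma(k + 1) for k in range(n + 1)])
    lp_obs = _log_table_prob(arr, log_fact)

    r, c = arr.shape
    total = 0.0
    count = 0

    def row_compositions(total_row, remaining_cols):
        # all ways to write total_row as c nonneg ints bounded by remaining_cols
        if len(remaining_cols) == 1:
            if total_row <= remaining_cols[0]:
                yield (total_row,)
            return
        upper = min(total_row, remaining_cols[0])
        lower = max(0, total_row - sum(remaining_cols[1:]))
        for v in range(lower, upper + 1):
            for rest in row_compositions(total_row - v, remaining_cols[1:]):
                yield (v,) + rest

    def recurse(i, cols_left, lp_rows_done):
        nonlocal total, count
        if i == r - 1:
            # last row is forced
            count += 1
            if count > max_tables:
                raise EnumerationBoundError(
                    f"exact enumeration exceeds {max_tables} tables")
            last = np.array(cols_left)
            lp = lp_rows_done - log_fact[last].sum()
            if lp <= lp_obs + 1e-9:
                total += math.exp(lp)
            return
        for comp in row_compositions(int(row_sums[i]), list(cols_left)):
            comp_a = np.array(comp)
            recurse(i + 1, tuple(np.array(cols_left) - comp_a),
                    lp_rows_done - log_fact[comp_a].sum())

    lp_base = log_fact[row_sums].sum() + log_fact[col_sums].sum() - log_fact[n]
    recurse(0, tuple(int(x) for x in col_sums), lp_base)
    return float(min(total, 1.0))


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p: exact for small tie-free samples, otherwise a
    normal approximation with tie and continuity correction (R defaults)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (x.size < 50 and y.size < 50 and not has_ties) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n with n > 0")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Percent with round-half-to-even at 2 d.p., e.g. 17/32 -> '53.12%'.

    Half-even is what clinical tables produced with R's ``round`` print
    (53.125 -> 53.12, 65.625 -> 65.62).
    """
    q = Decimal(10) ** -decimals
    val = (Decimal(repr(float(fraction))) * 100).quantize(
        q, rounding=ROUND_HALF_EVEN)
    return f"{val}%"


def build_cohort_table(clinical: pd.DataFrame, grouping: str, *,
                       categorical: list[str] | None = None,
                       continuous: list[str] | None = None,
                       missing_label: str = "Missing") -> pd.DataFrame:
    """Baseline characteristics table split by ``grouping``.

    Categorical variables get per-group counts with percentages and an
    exact Fisher p (2x2 or r x c as dimensioned); continuous variables get
    mean (SD), median [IQR] and a Wilcoxon rank-sum p.  ``Missing`` rows are
    displayed when present but excluded from the tests.
    """
    clin = clinical.reset_index(drop=True)
    levels = list(pd.unique(clin[grouping].dropna()))
    if len(levels) < 2:
        raise ValueError("grouping must have at least 2 levels")
    if categorical is None and continuous is None:
        categorical, continuous = [], []
        for col in clin.columns:
            if col in (grouping, "sample_id"):
                continue
            (continuous if pd.api.types.is_numeric_dtype(clin[col])
             and clin[col].nunique() > 6 else categorical).append(col)
    categorical = categorical or []
    continuous = continuous or []

    group_masks = {lev: (clin[grouping] == lev) for lev in levels}
    group_n = {lev: int(m.sum()) for lev, m in group_masks.items()}
    header = {lev: f"{lev}(n = {group_n[lev]})" for lev in levels}
    rows = []

    for col in continuous:
        vals = {lev: clin.loc[m, col].dropna() for lev, m in group_masks.items()}
        overall = clin[col].dropna()
        if len(levels) == 2:
            p = wilcoxon_rank_sum(vals[levels[0]], vals[levels[1]])
            p_str = f"{p:.3f}(wilcox.test)"
        else:
            p_str = ""
        row = {"variable": col, "level": "Mean(SD)",
               "Overall": f"{overall.mean():.2f} ({overall.std():.2f})",
               "p": p_str}
        for lev in levels:
            row[header[lev]] = f"{vals[lev].mean():.2f} ({vals[lev].std():.2f})"
        rows.append(row)
        row = {"variable": col, "level": "median[IQR]",
               "Overall": _median_iqr(overall), "p": ""}
        for lev in levels:
            row[header[lev]] = _median_iqr(vals[lev])
        rows.append(row)

    for col in categorical:
        s = clin[col].astype(str)
        cats = [c for c in pd.unique(s) if c != missing_label]
        if missing_label in set(s):
            cats = cats + [missing_label]
        counts = np.array([[int(((s == cat) & m).sum()) for lev, m in
                            group_masks.items()] for cat in cats])
        test_rows = [i for i, cat in enumerate(cats) if cat != missing_label]
        test_counts = counts[test_rows]
        test_counts = test_counts[test_counts.sum(axis=1) > 0]
        if test_counts.shape[0] >= 2:
            tab = ContingencyTable(test_counts)
            p_str = f"{tab.fisher_p():.3f}(fisher.test)"
        else:
            p_str = ""
        n_total = len(clin)
        for i, cat in enumerate(cats):
            row = {"variable": col, "level": cat,
                   "Overall": f"{counts[i].sum()} "
                              f"({format_percent(counts[i].sum() / n_total)})",
                   "p": p_str if i == 0 else ""}
            for j, lev in enumerate(levels):
                row[header[lev]] = (f"{counts[i, j]} "
                                    f"({format_percent(counts[i, j] / group_n[lev])})")
            rows.append(row)

    return pd.DataFrame(rows)


def _median_iqr(s: pd.Series) -> str:
    q1, med, q3 = s.quantile([0.25, 0.5, 0.75])
    return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"
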