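"""Kaplan-Meier estimation, median survival, and the two-group log-rank test.

All bPFS comparisons in the pipeline go through these functions.  The median
is the step-function convention: the first observed time at which the
survival curve drops to 0.5 or below, with no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit curve evaluated at the distinct observed event times."""

    event_times: np.ndarray  # increasing
    surv: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray      # n at risk just before each event time
    n_events: np.ndarray     # events at each event time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "surv": self.surv,
                             "at_risk": self.at_risk, "events": self.n_events})


@dataclass
class LogRankResult:
    chi2: float
    p: float
    observed: np.ndarray  # per group
    expected: np.ndarray  # per group


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored-only input yields a curve flat at 1 (no event times).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty input")
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    uniq = np.unique(time[event == 1])
    surv = np.empty(uniq.size)
    at_risk = np.empty(uniq.size, dtype=int)
    n_events = np.empty(uniq.size, dtype=int)
    s = 1.0
    for i, t in enumerate(uniq):
        n_i = int(np.sum(time >= t))
        d_i = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d_i / n_i
        surv[i] = s
        at_risk[i] = n_i
        n_events[i] = d_i
    return KMCurve(uniq, surv, at_risk, n_events)


def median_survival(curve: KMCurve) -> float | None:
    """First event time with S(t) <= 0.5, or ``None`` when never reached."""
    below = np.nonzero(curve.surv <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


def logrank_test(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Two-group log-rank test (O-E chi-square, 1 df).

    Per distinct event time the expected events in group A follow the
    hypergeometric mean and variance given the pooled margin.
    """
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a, dtype=int)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("each group must be nonempty")
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    if e_all.sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(t_all[e_all == 1])
    o_a = e_a_exp = var = 0.0
    for t in event_times:
        n = int(np.sum(t_all >= t))
        n_a = int(np.sum(ta >= t))
        d = int(np.sum((t_all == t) & (e_all == 1)))
        d_a = int(np.sum((ta == t) & (ea == 1)))
        o_a += d_a
        e_a_exp += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = (o_a - e_a_exp) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    d_total = float(e_all.sum())
    return LogRankResult(chi2=float(chi2), p=p,
                         observed=np.array([o_a, d_total - o_a]),
                         expected=np.array([e_a_exp, d_total - e_a_exp]))


def export_curve(curve: KMCurve, path) -> None:
    """Write a curve as TSV (time, surv, at_risk, events) for plotting."""
    curve.to_frame().to_csv(path, sep="\t", index=False)
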