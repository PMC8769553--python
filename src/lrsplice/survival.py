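"""Kaplan-Meier estimation and the (multi-group) log-rank test.

Both are implemented directly from their defining formulas: the
product-limit estimator with right censoring, and the log-rank statistic
summing observed-minus-expected deaths under the hypergeometric law at each
distinct death time, referred to a chi-square with (g - 1) degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class KaplanMeier:
    """Right-continuous step function: S(t) for t >= 0, S(0) = 1."""

    times: np.ndarray  # distinct death times, ascending
    survival: np.ndarray  # S(t) just after each death time

    def __call__(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def predict(self, ts: Sequence[float]) -> np.ndarray:
        return np.array([self(t) for t in np.asarray(ts, dtype=float)])


def km_estimator(times: Sequence[float], events: Sequence[bool]) -> KaplanMeier:
    """Product-limit survival estimate with right censoring."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("no observations")
    if (t < 0).any():
        raise ValueError("negative time")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    death_times = np.unique(t[e])
    surv = []
    s = 1.0
    for dt in death_times:
        at_risk = np.sum(t >= dt)
        deaths = np.sum((t == dt) & e)
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return KaplanMeier(death_times, np.asarray(surv))


def logrank_test(
    groups: Sequence[Tuple[Sequence[float], Sequence[bool]]]
) -> Tuple[float, float]:
    """Log-rank test across >= 2 groups; returns (chi-square, p).

    At each distinct death time the observed deaths per group are compared
    with their hypergeometric expectation given the risk sets; the
    statistic uses the first g-1 groups with the full covariance matrix.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    ts, es, gs = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {gi} has zero subjects")
        if (t < 0).any():
            raise ValueError("negative time")
        ts.append(t)
        es.append(e)
        gs.append(np.full(t.size, gi))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(gs)
    k = len(groups)
    death_times = np.unique(t[e])

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for dt in death_times:
        at_risk = t >= dt
        n = at_risk.sum()
        d = ((t == dt) & e).sum()
        if n <= 1 or d == 0:
            continue
        n_i = np.array([(at_risk & (g == i)).sum() for i in range(k)], dtype=float)
        d_i = np.array([((t == dt) & e & (g == i)).sum() for i in range(k)], dtype=float)
        observed += d_i
        expected += d * n_i / n
        frac = n_i / n
        hyper = d * (n - d) / (n - 1)
        cov += hyper * (np.diag(frac) - np.outer(frac, frac))

    diff = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    try:
        chisq = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        chisq = float(diff @ np.linalg.pinv(v) @ diff)
    chisq = max(chisq, 0.0)
    p = float(stats.chi2.sf(chisq, k - 1))
    return chisq, p
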