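"""Kaplan-Meier estimation, two-group logrank test with hazard ratio, and
the expression best-cutoff scan.

The best-cutoff scan reproduces the behavior of 'auto select best cutoff'
survival tools: every distinct expression value inside a percentile band is
tried as a dichotomization threshold and the split minimizing the nominal
logrank p-value is returned.  The reported p-value is NOT corrected for
the scan and is anti-conservative; a warning is logged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "SurvivalResult",
    "km_curve",
    "logrank",
    "best_cutoff_split",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalResult:
    chi_square: float
    p: float
    hazard_ratio: float
    cutoff: float
    n_high: int
    n_low: int
    median_rfs_high: float  # NaN when the curve never reaches 0.5
    median_rfs_low: float
    hr_stable: bool = True


def km_curve(time, event) -> tuple[np.ndarray, np.ndarray, float]:
    """Product-limit survival estimate.

    Returns (times, S(times), median), with times the observed (event or
    censoring) times including t=0, S right-continuous and non-increasing.
    The median is the first time with S(t) <= 0.5, NaN if never reached.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return times, surv, median


def _logrank_grid(
    time: np.ndarray, event: np.ndarray, membership: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Logrank O/E tabulation for many group-A membership vectors at once.

    membership is (C, n) boolean; returns per row (chi2, p, O_A, E_A,
    O_B/E_B-based HR).  Ties in event times are handled by the standard
    hypergeometric variance with the (N-d)/(N-1) correction.
    """
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order]
    g = membership[:, order]  # C x n
    n = t.size
    # suffix counts of group-A members still at risk at index i
    suffix = np.cumsum(g[:, ::-1].astype(np.int64), axis=1)[:, ::-1]  # C x n
    event_idx = np.flatnonzero(e)
    if event_idx.size == 0:
        raise ValueError("no events in cohort")
    # distinct event times -> first position and multiplicity among events
    ev_times = t[event_idx]
    first_mask = np.ones(ev_times.size, dtype=bool)
    first_mask[1:] = ev_times[1:] != ev_times[:-1]
    # first index in the full sorted array where each distinct event time starts
    starts = np.searchsorted(t, ev_times[first_mask], side="left")
    d = np.add.reduceat(np.ones(ev_times.size), np.flatnonzero(first_mask))
    # events in A at each distinct time, per cutoff
    dA = np.add.reduceat(
        g[:, event_idx].astype(np.float64), np.flatnonzero(first_mask), axis=1
    )  # C x T
    N = (n - starts).astype(np.float64)  # T
    NA = suffix[:, starts].astype(np.float64)  # C x T
    frac = NA / N
    EA = d * frac  # C x T
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(N > 1, (N - d) / (N - 1), 0.0)
    V = d * frac * (1.0 - frac) * corr
    O_A = dA.sum(axis=1)
    E_A = EA.sum(axis=1)
    Vsum = V.sum(axis=1)
    d_tot = float(d.sum())
    O_B = d_tot - O_A
    E_B = d_tot - E_A
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(Vsum > 0, (O_A - E_A) ** 2 / Vsum, 0.0)
        hr = (O_A / E_A) / (O_B / E_B)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p, O_A, E_A, hr


def logrank(
    time_a, event_a, time_b, event_b
) -> tuple[float, float, float]:
    """Two-group logrank (Mantel-Cox) test.

    Returns (chi_square, p, hazard_ratio) with HR = (O_A/E_A)/(O_B/E_B),
    group A versus group B.  With zero events in one group the HR is
    degenerate (inf or 0) and a warning is logged; the p-value remains the
    chi-square upper tail.
    """
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a, dtype=bool)
    event_b = np.asarray(event_b, dtype=bool)
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    membership = np.zeros((1, time.size), dtype=bool)
    membership[0, : time_a.size] = True
    chi2, p, O_A, E_A, hr = _logrank_grid(time, event, membership)
    d_tot = float(event.sum())
    if O_A[0] == 0 or (d_tot - O_A[0]) == 0:
        logger.warning("a group has zero events; hazard ratio is unstable")
        hr = np.where(O_A == 0, 0.0, np.inf)
    return float(chi2[0]), float(p[0]), float(hr[0])


def best_cutoff_split(
    cohort: pd.DataFrame, lower_q: float = 0.1, upper_q: float = 0.9
) -> SurvivalResult:
    """Scan distinct expression values between the lower_q and upper_q
    quantiles, split the cohort at each (high = expression strictly greater
    than the cutoff), and return the split with the smallest nominal
    logrank p-value.

    The scan optimizes over many hypotheses; the returned p-value is
    nominal and inflates the type-I error.
    """
    required = {"time", "event", "expression"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=bool)
    expr = cohort["expression"].to_numpy(dtype=float)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    lo, hi = np.quantile(expr, [lower_q, upper_q])
    candidates = np.unique(expr[(expr >= lo) & (expr <= hi)])
    # a cutoff at the maximum leaves the high group empty
    candidates = candidates[candidates < expr.max()]
    if candidates.size == 0:
        raise ValueError("no candidate cutoffs (constant or near-constant expression)")
    membership = expr[None, :] > candidates[:, None]  # C x n, True = high
    # valid splits need at least one event on each side
    ev = event[None, :]
    valid = (membership & ev).any(axis=1) & (~membership & ev).any(axis=1)
    if not valid.any():
        raise ValueError("no cutoff with events on both sides")
    candidates = candidates[valid]
    membership = membership[valid]
    chi2, p, O_A, E_A, hr = _logrank_grid(time, event, membership)
    best = int(np.argmin(p))
    high = membership[best]
    _, _, med_high = km_curve(time[high], event[high])
    _, _, med_low = km_curve(time[~high], event[~high])
    logger.warning(
        "best-cutoff scan over %d candidates returns a nominal p-value; "
        "the scan inflates type-I error",
        candidates.size,
    )
    d_tot = float(event.sum())
    stable = bool(O_A[best] > 0 and (d_tot - O_A[best]) > 0)
    return SurvivalResult(
        chi_square=float(chi2[best]),
        p=float(p[best]),
        hazard_ratio=float(hr[best]),
        cutoff=float(candidates[best]),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        median_rfs_high=med_high,
        median_rfs_low=med_low,
        hr_stable=stable,
    )
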