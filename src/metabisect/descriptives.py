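"""Descriptive analyses of bisection/metacognition sessions.

The central device is *re-sorting*: each trial pair of estimates is split
into a "best" and a "worst" member, either by the observer's own
second-order choice (subjective sorting) or by distance to the veridical
midpoint (ideal sorting). The variance ratio of the best and worst sets,
referenced to the ideal observer, yields the Metacognitive Index

    MCI = (Vi.best / Vi.worst) / (Vs.best / Vs.worst)

which is 1 for an observer with perfect insight into their own trial-level
performance and tends to 0 for an observer with none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trials import SessionDataset

__all__ = [
    "SortedEstimates",
    "MciResult",
    "BinnedSeries",
    "DegenerateVarianceError",
    "sort_subjective",
    "sort_ideal",
    "compute_mci",
    "mci_from_dataset",
    "coefficient_of_variation",
    "binned_series",
    "estimate_histogram",
    "trial_autocorrelation",
]


class DegenerateVarianceError(ValueError):
    """A variance in a ratio denominator is zero."""


@dataclass(frozen=True)
class SortedEstimates:
    """Best/worst re-sorted estimates for one subject-condition slice."""

    best: np.ndarray  # seconds, one per trial
    worst: np.ndarray
    true_mid: float
    kind: str  # "subjective" or "ideal"

    def __post_init__(self):
        if len(self.best) != len(self.worst):
            raise ValueError("best and worst must have equal length")


@dataclass(frozen=True)
class MciResult:
    v_subj_best: float
    v_subj_worst: float
    v_ideal_best: float
    v_ideal_worst: float
    mci: float


@dataclass(frozen=True)
class BinnedSeries:
    """Bin means with t-based confidence intervals over the trial series."""

    bin_size: int
    centers: np.ndarray  # trial index (1-based) at bin midpoints
    means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    partial_last_bin: bool


def _pairs(trials: SessionDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    f = trials.frame
    if len(f) == 0:
        raise ValueError("empty trial slice")
    if f["total_duration"].nunique() > 1:
        raise ValueError("slice spans multiple durations; subset first")
    e1 = f["estimate1"].to_numpy(float)
    e2 = f["estimate2"].to_numpy(float)
    choice = f["meta_choice"].to_numpy(int)
    return e1, e2, choice, float(f["total_duration"].iloc[0])


def sort_subjective(trials: SessionDataset) -> SortedEstimates:
    """Route each pair by the observer's own choice: chosen -> best."""
    e1, e2, choice, dur = _pairs(trials)
    pick1 = choice == 1
    return SortedEstimates(
        best=np.where(pick1, e1, e2),
        worst=np.where(pick1, e2, e1),
        true_mid=dur / 2.0,
        kind="subjective",
    )


def sort_ideal(trials: SessionDataset, true_mid: float | None = None) -> SortedEstimates:
    """Route each pair by distance to the veridical midpoint.

    ``ideal_best`` minimises |estimate - true_mid| within the pair; exact
    ties go to interval 1.
    """
    e1, e2, choice, dur = _pairs(trials)
    if true_mid is None:
        true_mid = dur / 2.0
    if not true_mid > 0:
        raise ValueError("true_mid must be positive")
    pick1 = np.abs(e1 - true_mid) <= np.abs(e2 - true_mid)
    return SortedEstimates(
        best=np.where(pick1, e1, e2),
        worst=np.where(pick1, e2, e1),
        true_mid=float(true_mid),
        kind="ideal",
    )


def compute_mci(sorted_subj: SortedEstimates, sorted_ideal: SortedEstimates) -> MciResult:
    """Metacognitive Index from the two sortings of the same trial set.

    Variances are unbiased (n-1) sample variances. Zero denominators raise
    :class:`DegenerateVarianceError` rather than propagating infinities.
    """
    if len(sorted_subj.best) != len(sorted_ideal.best):
        raise ValueError("sortings cover different trial counts")
    if len(sorted_subj.best) < 2:
        raise ValueError("need at least 2 trials for a variance")
    vsb = float(np.var(sorted_subj.best, ddof=1))
    vsw = float(np.var(sorted_subj.worst, ddof=1))
    vib = float(np.var(sorted_ideal.best, ddof=1))
    viw = float(np.var(sorted_ideal.worst, ddof=1))
    if viw == 0.0 or vsw == 0.0 or vsb == 0.0:
        raise DegenerateVarianceError(
            "zero variance in an MCI denominator "
            f"(Vs.best={vsb}, Vs.worst={vsw}, Vi.worst={viw})"
        )
    return MciResult(vsb, vsw, vib, viw, mci=(vib / viw) / (vsb / vsw))


def mci_from_dataset(trials: SessionDataset, true_mid: float | None = None) -> MciResult:
    """Convenience: subjective + ideal sorting and MCI in one call."""
    return compute_mci(sort_subjective(trials), sort_ideal(trials, true_mid))


def coefficient_of_variation(estimates) -> float:
    """Sample SD divided by mean; the Weber's-law summary of a series."""
    x = np.asarray(estimates, float)
    m = x.mean()
    if m == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(np.std(x, ddof=1) / m)


def binned_series(estimates, bin_size: int = 50, level: float = 0.95) -> BinnedSeries:
    """Bin an ordered trial series and attach t-based confidence intervals.

    The final bin is retained (and flagged) when ``n`` is not a multiple of
    ``bin_size``; a ``bin_size`` exceeding ``n`` yields a single bin.
    """
    x = np.asarray(estimates, float)
    n = len(x)
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    if n == 0:
        raise ValueError("empty series")
    edges = np.arange(0, n, bin_size)
    means, lo, hi, centers = [], [], [], []
    for start in edges:
        chunk = x[start : start + bin_size]
        m = chunk.mean()
        means.append(m)
        centers.append(start + (len(chunk) + 1) / 2.0)  # 1-based midpoint
        if len(chunk) > 1 and np.ptp(chunk) > 0:
            sem = stats.sem(chunk, ddof=1)
            tcrit = stats.t.ppf(0.5 + level / 2.0, df=len(chunk) - 1)
            half = tcrit * sem
        else:
            half = 0.0
        lo.append(m - half)
        hi.append(m + half)
    return BinnedSeries(
        bin_size=bin_size,
        centers=np.asarray(centers),
        means=np.asarray(means),
        ci_low=np.asarray(lo),
        ci_high=np.asarray(hi),
        partial_last_bin=bool(n % bin_size),
    )


def estimate_histogram(estimates, n_bins: int = 150, upper: float = None):
    """Equal-width histogram on [0, upper] (the total stimulus duration).

    Bins are half-open except the last, which is closed, so counts always
    sum to the number of estimates. Returns ``(edges, counts)``.
    """
    if upper is None or not upper > 0:
        raise ValueError("upper (total duration) must be positive")
    edges = np.linspace(0.0, float(upper), n_bins + 1)
    counts, _ = np.histogram(np.asarray(estimates, float), bins=edges)
    return edges, counts


def trial_autocorrelation(estimates, max_lag: int) -> np.ndarray:
    """Pearson autocorrelation of the trial series at lags 0..max_lag.

    Each lag correlates the series with its shifted copy over the
    overlapping region, so a strictly alternating series scores exactly -1
    at lag 1. A constant series has no defined correlation beyond lag 0.
    """
    x = np.asarray(estimates, float)
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    if np.ptp(x) == 0 and max_lag > 0:
        raise ValueError("autocorrelation undefined for a constant series")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for lag in range(1, max_lag + 1):
        a, b = x[:-lag], x[lag:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            out[lag] = np.nan
        else:
            out[lag] = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return out
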