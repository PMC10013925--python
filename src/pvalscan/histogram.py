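"""Histogram-shape classification of p-value sets.

A calibrated test of a mostly-null feature panel produces p-values that are
uniform except for a spike of true effects near zero. Departures from that
shape (spikes at one, humps in the middle, peaks at both ends) flag problems
with the underlying test. This module bins a p-value set into B fixed-width
bins and assigns one of five distributional classes using a peak-detection
rule: a bin is a peak when its count exceeds a Bonferroni-corrected binomial
quantile for the bin count under uniformity.

Classes
-------
uniform
    No bin exceeds the threshold; consistent with no detectable effects.
anti_conservative
    A single contiguous peak anchored at the left boundary, spanning at most
    one third of the unit interval — the theoretically expected shape when
    some features are truly differentially expressed.
conservative
    The mirror image: a right-boundary peak, typical of discrete or
    underpowered tests.
bimodal
    Peaks at both boundaries and none in the interior.
other
    Any interior peak, or a boundary run wider than one third of the range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

CLASSES = ("uniform", "anti_conservative", "conservative", "bimodal", "other")
UNCLASSIFIABLE = "unclassifiable"

#: Default number of histogram bins.
DEFAULT_BINS = 40
#: Default family-wise error level for peak detection.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class HistogramReport:
    """Binned histogram of a p-value set plus its assigned class.

    Attributes
    ----------
    counts : ndarray of int, length ``bins``
        Bin counts over [0, 1]; bin b covers [(b-1)/B, b/B), last bin closed.
    m : int
        Total finite p-values binned; equals ``counts.sum()``.
    bins, alpha : histogram geometry and family-wise peak-detection level.
    qc_threshold : int
        Peak threshold; a bin is flagged iff its count is strictly greater.
    flagged_bins : tuple of int
        1-based indices of flagged bins.
    klass : str
        One of ``CLASSES``, or ``"unclassifiable"`` when m < bins.
    """

    counts: np.ndarray
    m: int
    bins: int
    alpha: float
    qc_threshold: int
    flagged_bins: tuple[int, ...]
    klass: str

    def to_dict(self) -> dict:
        return {
            "counts": [int(c) for c in self.counts],
            "m": int(self.m),
            "bins": int(self.bins),
            "alpha": float(self.alpha),
            "qc_threshold": int(self.qc_threshold),
            "flagged_bins": [int(b) for b in self.flagged_bins],
            "class": self.klass,
        }


def bin_pvalues(values, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Bin p-values into ``bins`` equal-width bins over [0, 1].

    Bin b (1-based) covers [(b-1)/B, b/B) for b < B; the last bin is closed
    on the right so p = 1.0 lands in bin B. NaN values are dropped.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cannot bin an empty p-value set")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    edges = np.arange(bins + 1) / bins
    counts, _ = np.histogram(values, bins=edges)
    return counts


def qc_threshold(m: int, bins: int = DEFAULT_BINS, alpha: float = DEFAULT_ALPHA) -> int:
    """Bonferroni-corrected binomial quantile used as the peak threshold.

    Under uniformity each of the B bin counts is Binomial(m, 1/B). The
    threshold is the smallest integer c with CDF(c; m, 1/B) >= 1 - alpha/B,
    so that flagging any bin whose count strictly exceeds c controls the
    family-wise false-peak rate at ~alpha.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return int(stats.binom.ppf(1 - alpha / bins, m, 1.0 / bins))


def _runs(flagged: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of 1-based flagged bin indices."""
    runs: list[tuple[int, int]] = []
    for b in flagged:
        if runs and b == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], b)
        else:
            runs.append((b, b))
    return runs


def classify(counts, threshold: int) -> str:
    """Assign one of the five classes from bin counts and a peak threshold.

    Decision order: no flagged bin -> uniform; any flagged run touching
    neither boundary -> other; runs at both boundaries -> bimodal; a single
    boundary-anchored run of length <= floor(B/3) -> anti_conservative
    (left) or conservative (right), longer -> other.
    """
    counts = np.asarray(counts)
    B = counts.size
    flagged = np.flatnonzero(counts > threshold) + 1
    if flagged.size == 0:
        return "uniform"
    runs = _runs(flagged)
    if any(start != 1 and end != B for start, end in runs):
        return "other"
    left = next((r for r in runs if r[0] == 1), None)
    right = next((r for r in runs if r[1] == B), None)
    if left is not None and right is not None:
        return "bimodal"
    run = left if left is not None else right
    assert run is not None
    if run[1] - run[0] + 1 > B // 3:
        return "other"
    return "anti_conservative" if left is not None else "conservative"


def classify_set(
    values,
    bins: int = DEFAULT_BINS,
    alpha: float = DEFAULT_ALPHA,
) -> HistogramReport:
    """Bin, threshold and classify a validated p-value set.

    Sets with fewer finite values than bins are reported as
    ``"unclassifiable"`` rather than classified from a histogram whose
    expected bin count is below one.
    """
    counts = bin_pvalues(values, bins=bins)
    m = int(counts.sum())
    c = qc_threshold(m, bins=bins, alpha=alpha)
    flagged = tuple(int(b) for b in np.flatnonzero(counts > c) + 1)
    klass = classify(counts, c) if m >= bins else UNCLASSIFIABLE
    return HistogramReport(
        counts=counts, m=m, bins=bins, alpha=alpha,
        qc_threshold=c, flagged_bins=flagged, klass=klass,
    )
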