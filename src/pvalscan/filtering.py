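"""Low-expression filtering and the "rescue" of malformed p-value sets.

Discrete tests on features with very few counts produce p-value atoms
(including exactly 1) that deform the histogram. Removing low-expression
features before classification often converts such malformed sets into the
theoretically expected anti-conservative shape. This module applies
metric-specific expression thresholds, re-classifies and re-estimates pi0,
and summarizes class transitions over a corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import histogram, pi0 as pi0mod
from .histogram import CLASSES, HistogramReport
from .mining import ProcessedTable

#: Metric-specific keep thresholds (feature kept iff expression >= threshold).
#: basemean: normalized mean counts; logcpm: log2 CPM; rpkm/fpkm: per-kb per
#: million; aveexpr: average log2 CPM; "value" columns are cuffdiff FPKM
#: values and use the fpkm-scale threshold.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "basemean": 10.0,
    "logcpm": 1.0,
    "rpkm": 1.0,
    "fpkm": 1.0,
    "aveexpr": 3.32,
    "value": 1.0,
}

#: Priority when a table carries several metric types; the governing metric
#: is the first present.
METRIC_PRIORITY = ("basemean", "logcpm", "aveexpr", "fpkm", "rpkm", "value")

#: Classes eligible for pi0 estimation.
PI0_ELIGIBLE = ("uniform", "anti_conservative")


class NotFilterableError(ValueError):
    """Table has no recognized expression column; excluded from rescue."""


@dataclass(frozen=True)
class RescueResult:
    """Per-set classification and pi0 before and after low-count filtering."""

    before_class: str
    after_class: str
    before_pi0: float | None
    after_pi0: float | None
    n_before: int
    n_after: int
    metric: str
    threshold: float
    before_report: HistogramReport | None = None
    after_report: HistogramReport | None = None

    @property
    def rescued(self) -> bool:
        """Malformed before filtering, well-behaved after."""
        return (self.before_class not in PI0_ELIGIBLE
                and self.after_class in PI0_ELIGIBLE)

    def to_dict(self) -> dict[str, Any]:
        return {
            "before": {"class": self.before_class, "pi0": self.before_pi0},
            "after": {"class": self.after_class, "pi0": self.after_pi0},
            "n_before": self.n_before, "n_after": self.n_after,
            "metric": self.metric, "threshold": self.threshold,
            "rescued": self.rescued,
        }


@dataclass(frozen=True)
class TransitionMatrix:
    """Counts of before-class -> after-class over a corpus of rescue results."""

    matrix: pd.DataFrame  # rows: before, cols: after
    before_proportions: pd.Series
    after_proportions: pd.Series

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())


def governing_metric(table: ProcessedTable) -> str:
    """The single metric that drives filtering for this table."""
    metrics = {r.metric for r in table.roles.values() if r.role == "expression"}
    for metric in METRIC_PRIORITY:
        if metric in metrics:
            return metric
    raise NotFilterableError(
        f"{table.source_path or 'table'}: no recognized expression column")


def filter_low_expression(
    table: ProcessedTable,
    thresholds: dict[str, float] | None = None,
) -> tuple[np.ndarray, int]:
    """Row positions kept under the governing metric's threshold.

    The per-feature expression value is the row mean across all columns
    sharing the governing metric (e.g., cuffdiff's value_1/value_2); the
    feature is kept iff that mean is >= the metric's threshold. NaN
    expression counts as below threshold. Returns (kept positions, number
    dropped); deterministic, no RNG.
    """
    thresholds = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    metric = governing_metric(table)
    cols = [c for c, r in table.roles.items()
            if r.role == "expression" and r.metric == metric]
    values = np.column_stack([table.numeric(c) for c in cols])
    all_nan = np.all(np.isnan(values), axis=1)
    row_mean = np.full(len(values), np.nan)
    if (~all_nan).any():
        row_mean[~all_nan] = np.nanmean(values[~all_nan], axis=1)
    keep = np.isfinite(row_mean) & (row_mean >= thresholds[metric])
    kept = np.flatnonzero(keep)
    return kept, int(table.n_rows - kept.size)


def _estimate_pi0(values: np.ndarray, klass: str) -> float | None:
    if klass not in PI0_ELIGIBLE:
        return None
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        return None
    return pi0mod.pi0_lfdr(finite).value


def rescue_set(
    table: ProcessedTable,
    bins: int = histogram.DEFAULT_BINS,
    alpha: float = histogram.DEFAULT_ALPHA,
    thresholds: dict[str, float] | None = None,
    pvalue_column: str | None = None,
) -> RescueResult:
    """Classify (and pi0-estimate) a set before and after low-count filtering.

    pi0 (rank-lfdr method) is reported only for classes where it is
    meaningful (uniform / anti-conservative). Deterministic given inputs.
    """
    pcols = table.columns_with_role("pvalue")
    if not pcols:
        raise ValueError("table has no p-value column")
    pcol = pvalue_column if pvalue_column is not None else pcols[0]
    if pcol not in pcols:
        raise ValueError(f"{pcol!r} is not a p-value column")
    thresholds = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    metric = governing_metric(table)

    p_all = table.numeric(pcol)
    before_report = histogram.classify_set(p_all, bins=bins, alpha=alpha)
    before_pi0 = _estimate_pi0(p_all, before_report.klass)

    kept, _dropped = filter_low_expression(table, thresholds)
    p_kept = p_all[kept]
    if np.isfinite(p_kept).any():
        after_report = histogram.classify_set(p_kept, bins=bins, alpha=alpha)
        after_class = after_report.klass
        after_pi0 = _estimate_pi0(p_kept, after_class)
    else:
        after_report, after_class, after_pi0 = None, histogram.UNCLASSIFIABLE, None

    return RescueResult(
        before_class=before_report.klass, after_class=after_class,
        before_pi0=before_pi0, after_pi0=after_pi0,
        n_before=table.n_rows, n_after=int(kept.size),
        metric=metric, threshold=thresholds[metric],
        before_report=before_report, after_report=after_report,
    )


def transition_summary(results: Iterable[RescueResult]) -> TransitionMatrix:
    """Exact counts of class transitions plus marginal class proportions.

    Sets that are unclassifiable on either side are excluded from the 5x5
    matrix. Row sums equal per-class before-counts by construction.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one rescue result")
    mat = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES), dtype=int)
    for r in results:
        if r.before_class in CLASSES and r.after_class in CLASSES:
            mat.loc[r.before_class, r.after_class] += 1
    total = mat.to_numpy().sum()
    before = mat.sum(axis=1) / max(total, 1)
    after = mat.sum(axis=0) / max(total, 1)
    return TransitionMatrix(matrix=mat, before_proportions=before,
                            after_proportions=after)
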