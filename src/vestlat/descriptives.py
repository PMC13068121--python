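"""Descriptive layer: side scoring, side correspondence, the concordant
"subset", and the asymmetry-size vs correspondence correlation.

All inputs are *canonical* asymmetry values (positive = right side
affected), so the binary side score is simply the sign of the value.
The "subset" of a metric is the subgroup of patients whose scored side
matches the MRI-given label; its mean absolute asymmetry is reported
next to the whole-group mean, for descriptive purposes only (it never
enters classification).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .asymmetry import METRICS

__all__ = [
    "MetricSummary",
    "side_score",
    "correspondence_percent",
    "subset_summary",
    "metric_correlation",
    "describe_cohort",
]


def side_score(value: float) -> float:
    """Binary side score of one canonical asymmetry value: -1 (left),
    +1 (right), NaN when the value is exactly zero or missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == 0:
        return math.nan
    return 1.0 if value > 0 else -1.0


def _scores(values: Sequence[float]) -> np.ndarray:
    return np.array([side_score(v) for v in np.asarray(values, dtype=float)])


def correspondence_percent(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Percentage of patients whose score matches the true label.

    Undefined scores (zero or missing values) count as mismatches; the
    denominator is the full cohort.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if scores.size == 0:
        raise ValueError("empty cohort")
    if np.isnan(truth).any():
        raise ValueError("a true label is missing")
    matches = np.nansum((scores == truth).astype(int))
    return 100.0 * matches / scores.size


@dataclass(frozen=True)
class MetricSummary:
    """Whole-group vs concordant-subset asymmetry summary of one metric."""

    metric: str
    mean_abs: float  # mean |asymmetry|, all patients with a value
    mean_signed: float
    mean_abs_subset: Optional[float]  # concordant subset; None if empty
    correspondence: float  # percent of matching side scores
    n: int
    n_subset: int


def subset_summary(
    values: Sequence[float], truth: Sequence[int], metric: str = ""
) -> MetricSummary:
    """Summarize one metric: whole-group and concordant-subset mean
    asymmetries plus the side-correspondence percentage."""
    values = np.asarray(values, dtype=float)
    truth = np.asarray(truth, dtype=float)
    scores = _scores(values)
    corr = correspondence_percent(scores, truth)
    observed = ~np.isnan(values)
    concordant = scores == truth  # NaN scores never match
    sub = values[concordant]
    return MetricSummary(
        metric=metric,
        mean_abs=float(np.mean(np.abs(values[observed]))) if observed.any() else math.nan,
        mean_signed=float(np.mean(values[observed])) if observed.any() else math.nan,
        mean_abs_subset=float(np.mean(np.abs(sub))) if sub.size else None,
        correspondence=corr,
        n=int(values.size),
        n_subset=int(sub.size),
    )


def metric_correlation(summaries: Sequence[MetricSummary]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between whole-group mean
    absolute asymmetry and side correspondence across metrics.

    Returns (NaN, NaN) when either vector is constant.
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 metric summaries")
    x = np.array([s.mean_abs for s in summaries], dtype=float)
    y = np.array([s.correspondence for s in summaries], dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def describe_cohort(
    features: pd.DataFrame, truth: Sequence[int]
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-metric summaries for a canonical feature table plus the
    asymmetry-size vs correspondence Pearson correlation.

    Returns a frame indexed by metric with columns
    ``mean_abs, mean_signed, mean_abs_subset, correspondence, n, n_subset``
    and the ``(r, p)`` pair.
    """
    summaries = [
        subset_summary(features[m].to_numpy(), truth, metric=m)
        for m in features.columns
    ]
    table = pd.DataFrame(
        {
            "mean_abs": [s.mean_abs for s in summaries],
            "mean_signed": [s.mean_signed for s in summaries],
            "mean_abs_subset": [
                math.nan if s.mean_abs_subset is None else s.mean_abs_subset
                for s in summaries
            ],
            "correspondence": [s.correspondence for s in summaries],
            "n": [s.n for s in summaries],
            "n_subset": [s.n_subset for s in summaries],
        },
        index=[s.metric for s in summaries],
    )
    return table, metric_correlation(summaries)
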