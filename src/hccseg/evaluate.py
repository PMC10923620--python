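"""Segmentation agreement metrics, aggregation, and model comparison.

Per case, predictions are scored volume-level (one confusion triple per
patient, not per slice) with

    DSC = 2 TP / (FP + 2 TP + FN),
    precision = TP / (TP + FP),
    recall = TP / (TP + FN).

Per-case values are summarized as mean +/- sample std, median, and range,
and models are compared with a two-sided paired t-test on their per-case
DSC vectors.

Conventions for cases the formulas leave undefined: if ground truth and
prediction are both empty the case counts as perfect agreement (1, 1, 1);
a ratio whose denominator alone is zero is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = ["ConfusionCounts", "SegMetrics", "MetricSummary", "confusion_counts",
           "seg_metrics", "evaluate_masks", "aggregate_metrics", "paired_t_test",
           "TTestResult", "make_report", "render_report_text"]

METRIC_NAMES = ("dsc", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts; TN is deliberately absent (unused by the metrics)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class SegMetrics:
    dsc: float
    precision: float
    recall: float


@dataclass(frozen=True)
class MetricSummary:
    """Mean +/- std, median and range of one metric over cases."""

    mean: float
    std: float
    median: float
    min: float
    max: float
    n: int


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Volume-level TP/FP/FN between two binary masks on one grid."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred > 0
    g = gt > 0
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def seg_metrics(c: ConfusionCounts) -> SegMetrics:
    """DSC / precision / recall from a confusion triple."""
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return SegMetrics(dsc=1.0, precision=1.0, recall=1.0)
    dsc = 2 * c.tp / (c.fp + 2 * c.tp + c.fn)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return SegMetrics(dsc=dsc, precision=precision, recall=recall)


def evaluate_masks(pred: np.ndarray, gt: np.ndarray) -> SegMetrics:
    return seg_metrics(confusion_counts(pred, gt))


def aggregate_metrics(values: list[SegMetrics]) -> dict[str, MetricSummary]:
    """Summarize per-case metrics; sample (n-1) std, 0 by convention at n=1."""
    if not values:
        raise ValueError("cannot aggregate an empty metric list")
    out = {}
    for name in METRIC_NAMES:
        v = np.array([getattr(m, name) for m in values], dtype=float)
        std = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        out[name] = MetricSummary(mean=float(v.mean()), std=std,
                                  median=float(np.median(v)),
                                  min=float(v.min()), max=float(v.max()),
                                  n=len(v))
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_t_test(a, b) -> TTestResult:
    """Two-sided paired t-test on per-case values.

    ``t = mean(d) / (sd(d) / sqrt(n))`` on the differences ``d = a - b``;
    the two-sided p-value comes from the Student t distribution with n-1
    degrees of freedom via the regularized incomplete beta function.  An
    all-zero difference vector is degenerate and reported as (t=0, p=1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0):
            return TTestResult(t=0.0, p=1.0, n=n, degenerate=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return TTestResult(t=float(t), p=0.0, n=n, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return TTestResult(t=t, p=p, n=n)


def make_report(summaries: dict[str, dict[str, MetricSummary]],
                tests: dict[str, TTestResult] | None = None) -> pd.DataFrame:
    """Assemble the per-model results table (one row per model).

    Columns follow the conventional layout: per metric a ``mean ± std``,
    median, and range column; a final p-value column is filled only for
    models that have a comparison baseline in ``tests``.
    """
    if not summaries:
        raise ValueError("report needs at least one model")
    tests = tests or {}
    rows = []
    for model, per_metric in summaries.items():
        row: dict[str, object] = {"model": model}
        for name in METRIC_NAMES:
            s = per_metric[name]
            row[f"{name}_mean"] = round(s.mean, 4)
            row[f"{name}_std"] = round(s.std, 4)
            row[f"{name}_median"] = round(s.median, 4)
            row[f"{name}_min"] = round(s.min, 4)
            row[f"{name}_max"] = round(s.max, 4)
        row["p_value"] = round(tests[model].p, 6) if model in tests else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def render_report_text(df: pd.DataFrame) -> str:
    """Aligned-text rendering of :func:`make_report` output."""
    lines = [f"{'Model':<10}" + " ".join(f"{m.upper():>32}" for m in METRIC_NAMES) + f"{'p':>8}"]
    for _, row in df.iterrows():
        cells = [f"{row['model']:<10}"]
        for m in METRIC_NAMES:
            cells.append(f"{row[f'{m}_mean']:.2f}±{row[f'{m}_std']:.2f} "
                         f"med {row[f'{m}_median']:.2f} "
                         f"[{row[f'{m}_min']:.2f}-{row[f'{m}_max']:.2f}]".rjust(32))
        p = row["p_value"]
        cells.append(("—" if pd.isna(p) else f"{p:.3f}").rjust(8))
        lines.append(" ".join(cells))
    return "\n".join(lines)
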