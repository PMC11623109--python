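"""Loss and evaluation suite for binary segmentation.

Pixel-wise binary cross-entropy for training; confusion-matrix metrics
(accuracy, sensitivity, specificity, precision, F1), the Dice overlap
coefficient (identical to F1 on binary masks), and ROC-AUC via the
Mann-Whitney pairwise-ranking statistic for evaluation.  Cross-validation
folds are pooled per fold and averaged unweighted across folds.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "bce_loss",
    "confusion",
    "basic_metrics",
    "dice",
    "roc_auc",
    "aggregate_folds",
    "write_report",
]

PROB_EPS = 1e-7  # clamp for probabilities before logs

METRIC_NAMES = ("acc", "sen", "spe", "pre", "f1", "dice", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricReport:
    """Metric values in [0,1], optionally carrying per-fold traces."""

    acc: float = math.nan
    sen: float = math.nan
    spe: float = math.nan
    pre: float = math.nan
    f1: float = math.nan
    dice: float = math.nan
    auc: float = math.nan
    n_folds: int = 1
    per_fold: dict[str, list[float]] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    def values(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _as_binary(mask: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{what} must contain only 0/1 values")
    return arr.astype(bool)


def bce_loss(truth: np.ndarray, probs: np.ndarray) -> float:
    """Mean binary cross-entropy over all pixels.

    Probabilities are clamped to [1e-7, 1 - 1e-7] before the logs so exact
    0/1 predictions stay finite.
    """
    y = _as_binary(truth, "truth").astype(np.float64)
    p = np.asarray(probs, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: truth {y.shape} vs probs {p.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion tallies between two binary masks."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def basic_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    Degenerate denominators: with no actual positives sensitivity is 1
    (nothing to miss); with no predicted positives precision is 1 when
    there were also no missed positives, else 0; F1 of two empty masks is 1.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = c.total
    acc = (tp + tn) / total if total else 1.0
    sen = tp / (tp + fn) if (tp + fn) else 1.0
    spe = tn / (fp + tn) if (fp + tn) else 1.0
    if tp + fp:
        pre = tp / (tp + fp)
    else:
        pre = 1.0 if fn == 0 else 0.0
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 1.0
    return MetricReport(acc=acc, sen=sen, spe=spe, pre=pre, f1=f1,
                        dice=f1, n_folds=1)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1 when both masks are empty."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(p & t)) / denom


def roc_auc(probs: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney statistic.

    Equals the probability that a random foreground pixel scores above a
    random background pixel, ties counting one half — exact for finite
    samples, no threshold grid.
    """
    t = _as_binary(truth, "truth").ravel()
    p = np.asarray(probs, dtype=np.float64).ravel()
    if p.shape != t.shape:
        raise ValueError("shape mismatch between probs and truth")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes in the truth mask")
    ranks = rankdata(p)  # average ranks handle ties as 1/2
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aggregate_folds(reports: list[MetricReport]) -> MetricReport:
    """Unweighted mean and sample standard deviation across folds."""
    if not reports:
        raise ValueError("need at least one fold report")
    agg = MetricReport(n_folds=len(reports))
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports]
        if any(math.isnan(v) for v in vals):
            continue
        agg.per_fold[name] = [float(v) for v in vals]
        setattr(agg, name, float(np.mean(vals)))
        agg.std[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return agg


def write_report(report: MetricReport, path: str | Path,
                 fmt: str | None = None) -> None:
    """Write a report as JSON or CSV (per-fold rows plus a mean/std row)."""
    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".") or "json")
    if fmt == "json":
        payload = asdict(report)
        path.write_text(json.dumps(payload, indent=2))
        return
    if fmt != "csv":
        raise ValueError(f"unknown report format {fmt!r}")
    names = [n for n in METRIC_NAMES
             if not math.isnan(getattr(report, n))]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fold"] + names)
        if report.per_fold:
            for i in range(report.n_folds):
                writer.writerow(
                    [i] + [report.per_fold[n][i] for n in names])
        writer.writerow(["mean"] + [getattr(report, n) for n in names])
        writer.writerow(["std"] + [report.std.get(n, 0.0) for n in names])
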