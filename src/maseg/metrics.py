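"""Pixel-level segmentation evaluation against a reference mask.

Five metrics derived from the pixel confusion counts:

    Acc = (TP + TN) / (TP + FP + TN + FN)
    Se  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    PPV = TP / (TP + FP)
    IOU = TP / (TP + FP + FN)

A zero denominator (e.g., a reference with no lesion pixels) makes the
metric undefined; it is reported as ``None`` and excluded from batch
aggregation with a warning rather than silently inflating means. Batch
summaries report per-image mean and sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "report",
    "evaluate",
    "batch_report",
    "lesion_recall",
]

METRIC_NAMES = ("acc", "se", "sp", "ppv", "iou")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    acc: float | None
    se: float | None
    sp: float | None
    ppv: float | None
    iou: float | None

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "acc": self.acc,
            "se": self.se,
            "sp": self.sp,
            "ppv": self.ppv,
            "iou": self.iou,
        }


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between predicted and reference masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty masks")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def report(counts: ConfusionCounts) -> MetricsReport:
    """Derive the five metrics from confusion counts."""
    if counts.total <= 0:
        raise ValueError("confusion counts sum to zero")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    return MetricsReport(
        counts=counts,
        acc=(tp + tn) / counts.total,
        se=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        iou=_ratio(tp, tp + fp + fn),
    )


def evaluate(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Convenience: confusion counts and metrics in one call."""
    return report(confusion(pred, truth))


@dataclass
class BatchSummary:
    reports: list[MetricsReport]
    mean: dict[str, float | None]
    sd: dict[str, float | None]
    n_undefined: dict[str, int]

    def to_frame(self, names: list[str] | None = None):
        """One row per image plus a mean and sd row, metrics in percent."""
        import pandas as pd

        rows = []
        for i, rep in enumerate(self.reports):
            row = {"image": names[i] if names else f"image_{i}"}
            row.update(
                {
                    k: v
                    for k, v in rep.as_dict().items()
                    if k in ("tp", "fp", "tn", "fn")
                }
            )
            for m in METRIC_NAMES:
                v = getattr(rep, m)
                row[m + "_pct"] = round(100.0 * v, 2) if v is not None else None
            rows.append(row)
        for label, stats in (("mean", self.mean), ("sd", self.sd)):
            row = {"image": label}
            for m in METRIC_NAMES:
                v = stats[m]
                row[m + "_pct"] = round(100.0 * v, 2) if v is not None else None
            rows.append(row)
        return pd.DataFrame(rows)


def batch_report(pairs) -> BatchSummary:
    """Per-image metrics plus mean and sample standard deviation per metric.

    ``pairs`` is a sequence of (pred, truth) mask pairs. Undefined per-image
    values are excluded from the aggregates; the exclusion count is kept and
    warned about.
    """
    reports = [evaluate(p, t) for p, t in pairs]
    if not reports:
        raise ValueError("batch_report needs at least one mask pair")
    mean: dict[str, float | None] = {}
    sd: dict[str, float | None] = {}
    n_undef: dict[str, int] = {}
    for m in METRIC_NAMES:
        vals = [getattr(r, m) for r in reports]
        defined = [v for v in vals if v is not None]
        n_undef[m] = len(vals) - len(defined)
        if n_undef[m]:
            warnings.warn(
                f"{n_undef[m]} undefined {m} value(s) excluded from aggregation",
                stacklevel=2,
            )
        if defined:
            mean[m] = float(np.mean(defined))
            sd[m] = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        else:
            mean[m] = None
            sd[m] = None
    return BatchSummary(reports=reports, mean=mean, sd=sd, n_undefined=n_undef)


def lesion_recall(
    pred: np.ndarray, truth: np.ndarray, connectivity: int = 2
) -> tuple[int, int]:
    """Lesion-level detection count: (n_detected, n_truth_lesions).

    A reference lesion (connected component of the truth mask) counts as
    detected if at least one predicted pixel falls inside it.
    """
    from skimage import measure

    truth = np.asarray(truth, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    lab = measure.label(truth, connectivity=connectivity)
    n = int(lab.max())
    hit = np.unique(lab[pred])
    detected = int(np.count_nonzero(hit))
    return detected, n
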