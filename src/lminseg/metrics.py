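"""Segmentation evaluation: pixel confusion counts, Jaccard/Dice,
sensitivity/specificity/precision, region contrast and batch summaries.

Ground truth is the reference (``L_M``); the prediction is ``L_P``.
Metric conventions:

* Jaccard index ``JI = TP / (TP + FP + FN)``.
* Dice coefficient ``DSC = 2 TP / (2 TP + FP + FN)``; algebraically
  ``DSC = 2 JI / (1 + JI)``.
* When both masks are empty, JI and DSC are 1.0 by convention (with a
  warning) — the masks agree perfectly on every pixel.
* A ratio with a zero denominator is *undefined* (``None``), not zero,
  and is excluded from batch means (the excluded count is reported);
  zero-filling would bias the averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyMaskError, ParameterError

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "confusion",
    "jaccard",
    "dice",
    "sens_spec_prec",
    "evaluate_masks",
    "region_contrast",
    "batch_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsRecord:
    """Per-mask-pair similarity measures; ``None`` marks an undefined ratio."""

    ji: float | None
    dsc: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None

    def to_dict(self) -> dict:
        return {
            "ji": self.ji,
            "dsc": self.dsc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts with ``truth`` as the reference."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ParameterError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def jaccard(c: ConfusionCounts) -> float:
    """Jaccard index TP / (TP + FP + FN); 1.0 (with warning) when both
    masks are empty."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("both masks empty; Jaccard defined as 1.0", stacklevel=2)
        return 1.0
    return c.tp / denom


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient 2 TP / (2 TP + FP + FN); 1.0 (with warning) when
    both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2 * c.tp / denom


def sens_spec_prec(
    c: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, precision); ``None`` where the
    denominator is zero."""
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else None
    prec = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    return sens, spec, prec


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricsRecord:
    """All five similarity measures for one predicted/reference mask pair."""
    c = confusion(pred, truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ji, dsc = jaccard(c), dice(c)
    sens, spec, prec = sens_spec_prec(c)
    return MetricsRecord(
        ji=ji, dsc=dsc, sensitivity=sens, specificity=spec, precision=prec
    )


def region_contrast(
    image: np.ndarray, nucleus: np.ndarray, cytoplasm: np.ndarray
) -> float:
    """Absolute difference between the mean intensity over the nucleus and
    over the cytoplasm."""
    image = np.asarray(image, dtype=np.float64)
    nucleus = np.asarray(nucleus, dtype=bool)
    cytoplasm = np.asarray(cytoplasm, dtype=bool)
    if not nucleus.any() or not cytoplasm.any():
        raise EmptyMaskError("region_contrast requires non-empty regions")
    return abs(float(image[nucleus].mean()) - float(image[cytoplasm].mean()))


def batch_summary(records: list[dict], class_key: str = "cell_class") -> dict:
    """Aggregate per-image result records into per-class means plus
    predicted-vs-truth size correlations.

    Each record is a flat dict of numbers (thresholds, metrics, region
    sizes, ...), optionally carrying a ``cell_class`` label.  Undefined
    (``None``/NaN) entries are excluded from the means; the count of
    values actually averaged accompanies each mean.

    Returns a dict with:

    * ``"per_class"`` — DataFrame of means indexed by class (single index
      ``"all"`` when no class labels are present);
    * ``"n_used"`` — DataFrame of the per-mean sample counts;
    * ``"correlations"`` — Pearson r of (predicted size, truth size) for
      every ``<name>_pred_size`` / ``<name>_true_size`` column pair.
    """
    if not records:
        raise ParameterError("batch_summary requires at least one record")
    df = pd.DataFrame.from_records(records)
    if class_key not in df.columns:
        df[class_key] = "all"
    numeric = df.select_dtypes(include="number").columns.tolist()
    grouped = df.groupby(class_key)[numeric]
    means = grouped.mean()
    n_used = grouped.count()

    correlations: dict[str, float] = {}
    for col in numeric:
        if col.endswith("_pred_size"):
            mate = col.replace("_pred_size", "_true_size")
            if mate in df.columns and len(df) >= 2:
                x = df[col].astype(float)
                y = df[mate].astype(float)
                if x.std() > 0 and y.std() > 0:
                    correlations[col.replace("_pred_size", "")] = float(
                        x.corr(y)
                    )
                else:
                    correlations[col.replace("_pred_size", "")] = 1.0 if (
                        x == y
                    ).all() else float("nan")
    return {"per_class": means, "n_used": n_used, "correlations": correlations}
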