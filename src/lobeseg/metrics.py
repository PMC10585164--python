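"""Overlap and distance metrics for crisp binary segmentations.

Implements the five-metric evaluation suite standard in medical-image
segmentation: Dice similarity coefficient (DSC), Jaccard similarity
coefficient (JSC), positive predictive value (PPV), sensitivity (SE) and
the symmetric Hausdorff distance (HD), plus per-slice -> cohort
aggregation as mean +/- sample standard deviation.

Degenerate slices are governed by an explicit policy rather than NaN:
when prediction and reference are both empty the overlap metrics default
to 1 ("both-empty-is-perfect"); the Hausdorff distance is undefined on an
empty mask and raises, and such slices are excluded from HD aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "dsc",
    "jsc",
    "ppv",
    "sensitivity",
    "hausdorff",
    "hausdorff_bruteforce",
    "evaluate_pair",
    "aggregate",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("dsc", "jsc", "ppv", "se", "hd")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_masks(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be crisp (only 0/1 entries)")
    return pred.astype(bool), truth.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Exact pixelwise confusion counts between two crisp masks."""
    pred, truth = _check_masks(pred, truth)
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(pred, truth, both_empty_value: float = 1.0) -> float:
    """Dice coefficient 2|X∩Y| / (|X|+|Y|)."""
    c = confusion(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return both_empty_value
    return 2.0 * c.tp / denom


def jsc(pred, truth, both_empty_value: float = 1.0) -> float:
    """Jaccard coefficient |X∩Y| / |X∪Y|."""
    c = confusion(pred, truth)
    union = c.tp + c.fp + c.fn
    if union == 0:
        return both_empty_value
    return c.tp / union


def ppv(pred, truth, empty_value: float = 1.0) -> float:
    """Positive predictive value TP / (TP+FP); ``empty_value`` when the
    prediction is empty."""
    c = confusion(pred, truth)
    if c.tp + c.fp == 0:
        return empty_value
    return c.tp / (c.tp + c.fp)


def sensitivity(pred, truth, empty_value: float = 1.0) -> float:
    """Sensitivity (recall) TP / (TP+FN); ``empty_value`` when the
    reference is empty."""
    c = confusion(pred, truth)
    if c.tp + c.fn == 0:
        return empty_value
    return c.tp / (c.tp + c.fn)


def _coords(mask: np.ndarray, spacing, boundary_only: bool) -> np.ndarray:
    if boundary_only:
        from scipy.ndimage import binary_erosion

        mask = mask & ~binary_erosion(mask)
    pts = np.argwhere(mask).astype(np.float64)
    return pts * np.asarray(spacing, dtype=np.float64)


def hausdorff(
    pred,
    truth,
    spacing: tuple[float, float] = (1.0, 1.0),
    boundary_only: bool = False,
) -> float:
    """Symmetric Hausdorff distance max(h(X,Y), h(Y,X)) with
    h(X,Y) = max_x min_y ||x - y||2 over foreground pixel coordinates.

    Coordinates are scaled by ``spacing`` (row mm, col mm), so the result
    is in physical units when spacing is supplied and pixel units
    otherwise. Uses a KD-tree; ``boundary_only`` restricts both sets to
    their morphological boundary.
    """
    pred, truth = _check_masks(pred, truth)
    if not pred.any():
        raise ValueError("Hausdorff distance undefined: predicted mask is empty")
    if not truth.any():
        raise ValueError("Hausdorff distance undefined: reference mask is empty")
    a = _coords(pred, spacing, boundary_only)
    b = _coords(truth, spacing, boundary_only)
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


def hausdorff_bruteforce(
    pred, truth, spacing: tuple[float, float] = (1.0, 1.0)
) -> float:
    """O(|X||Y|) all-pairs evaluation of the Hausdorff distance; the
    independent reference the fast implementation must match exactly."""
    pred, truth = _check_masks(pred, truth)
    if not pred.any() or not truth.any():
        raise ValueError("Hausdorff distance undefined on an empty mask")
    a = _coords(pred, spacing, False)
    b = _coords(truth, spacing, False)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def evaluate_pair(
    pred,
    truth,
    spacing: tuple[float, float] = (1.0, 1.0),
    both_empty_value: float = 1.0,
) -> dict:
    """All five metrics for one slice; ``hd`` is NaN when either mask is
    empty (flagged by ``hd_defined``)."""
    rec = {
        "dsc": dsc(pred, truth, both_empty_value),
        "jsc": jsc(pred, truth, both_empty_value),
        "ppv": ppv(pred, truth, both_empty_value),
        "se": sensitivity(pred, truth, both_empty_value),
    }
    pred_b, truth_b = _check_masks(pred, truth)
    if pred_b.any() and truth_b.any():
        rec["hd"] = hausdorff(pred, truth, spacing)
        rec["hd_defined"] = True
    else:
        rec["hd"] = float("nan")
        rec["hd_defined"] = False
    return rec


@dataclass
class MetricReport:
    """Per-slice metric records plus their mean and sample SD.

    ``per_slice`` keeps one row per slice (the box-plot data); slices on
    which HD is undefined carry NaN there and are excluded from the HD
    mean/SD.
    """

    per_slice: pd.DataFrame
    mean: dict
    sd: dict

    def summary_row(self, decimals: int = 2) -> dict:
        return {
            m: f"{self.mean[m]:.{decimals}f} ± {self.sd[m]:.{decimals}f}"
            for m in METRIC_COLUMNS
        }

    def to_csv(self, path) -> None:
        self.per_slice.to_csv(path, index=False)


def aggregate(records: list[dict]) -> MetricReport:
    """Aggregate per-slice records into mean +/- sample SD (ddof=1; SD is
    0 for a single slice)."""
    if not records:
        raise ValueError("cannot aggregate an empty list of records")
    df = pd.DataFrame.from_records(records)
    mean, sd = {}, {}
    for m in METRIC_COLUMNS:
        vals = df[m].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            mean[m], sd[m] = float("nan"), float("nan")
        else:
            mean[m] = float(vals.mean())
            sd[m] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return MetricReport(per_slice=df, mean=mean, sd=sd)
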