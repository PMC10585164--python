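"""Synthetic head-phantom generator with paired temporal-lobe-like masks.

Real planning-CT data of this kind is private, so the generator emulates
the *statistical* structure the losses and metrics are designed for rather
than CT physics: a bright elliptical skull ring, a textured brain
interior, and two small lateral "lobe" regions (randomly rotated
superellipses) whose pixels are mildly intensity-shifted against the
brain. Severe class imbalance is built in — the foreground occupies well
under 5% of the cohort's pixels by default — and a configurable fraction
of slices are "pole" slices whose foreground is only a few pixels, the
hardest case for a segmentation loss.

Everything is deterministic given the spec's seed: slice content derives
from ``(seed, subject, slice)`` so any slice can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import gamma as _gamma

__all__ = ["PhantomSpec", "Cohort", "generate_slice", "generate_cohort", "split_subjects"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study-condition knobs of the synthetic cohort.

    Defaults are the desk-scale conditions: 128x128 slices, 20 subjects of
    12 slices, mid-lobe foreground fraction 0.5-3% per slice, 15% pole
    slices of at most 8 foreground pixels.
    """

    image_size: tuple[int, int] = (128, 128)
    n_subjects: int = 20
    slices_per_subject: int = 12
    foreground_fraction_range: tuple[float, float] = (0.005, 0.03)
    pole_fraction: float = 0.15
    pole_area_px: int = 8
    noise_sd: float = 0.03
    lobe_contrast: float = 0.18
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.foreground_fraction_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("foreground_fraction_range must satisfy 0 < lo <= hi < 0.5")
        if self.pole_area_px < 1:
            raise ValueError("pole_area_px must be >= 1")
        if not (0 <= self.pole_fraction <= 1):
            raise ValueError("pole_fraction must lie in [0, 1]")
        if self.image_size[0] < 32 or self.image_size[1] < 32:
            raise ValueError("image_size must be at least 32x32")


def _superellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    m: float,
    theta: float,
) -> np.ndarray:
    """Filled superellipse |u/a|^m + |v/b|^m <= 1 rotated by theta."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - center[0]
    dx = xx - center[1]
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    return (np.abs(u / a) ** m + np.abs(v / b) ** m) <= 1.0


def _superellipse_area(a: float, b: float, m: float) -> float:
    return 4.0 * a * b * _gamma(1 + 1 / m) ** 2 / _gamma(1 + 2 / m)


def _lobe_region(
    shape: tuple[int, int],
    center: tuple[float, float],
    target_px: float,
    rng: np.random.Generator,
    interior: np.ndarray,
) -> np.ndarray:
    """One lobe as a superellipse scaled so its pixel count is close to
    ``target_px``, clipped to the skull interior."""
    m = rng.uniform(1.5, 3.0)
    aspect = rng.uniform(1.2, 2.2)
    theta = rng.uniform(0, np.pi)
    # solve a*b from the continuous area, then refine the scale discretely
    ab = target_px / (4.0 * _gamma(1 + 1 / m) ** 2 / _gamma(1 + 2 / m))
    b0 = np.sqrt(ab / aspect)
    a0 = aspect * b0
    scale = 1.0
    mask = None
    for _ in range(12):
        mask = _superellipse_mask(shape, center, a0 * scale, b0 * scale, m, theta) & interior
        got = mask.sum()
        if got == 0:
            scale *= 1.4
            continue
        ratio = target_px / got
        if 0.8 <= ratio <= 1.25:
            break
        scale *= np.sqrt(np.clip(ratio, 0.5, 2.0))
    return mask


def _tiny_cluster(
    shape: tuple[int, int], center: tuple[int, int], n_px: int
) -> np.ndarray:
    """The ``n_px`` lattice pixels nearest to ``center`` (a pole remnant)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    order = np.argsort(d.ravel(), kind="stable")[:n_px]
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[order] = True
    return mask


def _head_geometry(shape: tuple[int, int]):
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.46 * h, 0.42 * w
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    skull = (r2 <= 1.0) & (r2 >= 0.88)
    interior = r2 < 0.88
    return skull, interior


def generate_slice(
    spec: PhantomSpec, subject_idx: int, slice_idx: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One (image, mask, is_pole) triple; image float64 in [0,1], mask uint8.

    Deterministic in ``(spec.seed, subject_idx, slice_idx)``.
    """
    if not (0 <= subject_idx < spec.n_subjects):
        raise ValueError("subject index out of range")
    if not (0 <= slice_idx < spec.slices_per_subject):
        raise ValueError("slice index out of range")
    h, w = spec.image_size
    skull, interior = _head_geometry(spec.image_size)

    # per-subject stream decides which slices are poles
    srng = np.random.default_rng([spec.seed, subject_idx])
    n_pole = int(round(spec.pole_fraction * spec.slices_per_subject))
    pole_slices = set(
        srng.choice(spec.slices_per_subject, size=n_pole, replace=False).tolist()
    )
    is_pole = slice_idx in pole_slices

    rng = np.random.default_rng([spec.seed, subject_idx, slice_idx])
    lo, hi = spec.foreground_fraction_range

    mask = np.zeros((h, w), dtype=bool)
    centers = [
        (rng.uniform(0.45, 0.60) * h, rng.uniform(0.26, 0.36) * w),
        (rng.uniform(0.45, 0.60) * h, rng.uniform(0.64, 0.74) * w),
    ]
    if is_pole:
        total = int(rng.integers(1, spec.pole_area_px + 1))
        n_left = total if total == 1 else int(rng.integers(1, total))
        for c, n_px in zip(centers, (n_left, total - n_left)):
            if n_px > 0:
                mask |= _tiny_cluster((h, w), (int(c[0]), int(c[1])), n_px)
    else:
        target_frac = rng.uniform(lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo))
        per_lobe = target_frac * h * w / 2.0
        for c in centers:
            region = _lobe_region((h, w), c, per_lobe, rng, interior)
            if region is None or not region.any():
                raise ValueError("infeasible lobe geometry for the requested fraction")
            mask |= region
        mask &= interior  # lobes never extend past the skull interior
        frac = mask.sum() / (h * w)
        if not (lo <= frac <= hi):
            # discretisation pushed us outside the contract: trim pixels
            # farthest from the lobes, or grow along the lobes' boundary
            target_px = int(round(np.clip(frac, lo * 1.05, hi * 0.95) * h * w))
            if mask.sum() > target_px:
                idx = np.argwhere(mask)
                centroid = idx.mean(axis=0)
                d = ((idx - centroid) ** 2).sum(axis=1)
                keep = idx[np.argsort(d, kind="stable")[:target_px]]
                mask = np.zeros((h, w), dtype=bool)
                mask[keep[:, 0], keep[:, 1]] = True
            elif mask.sum() < target_px:
                from scipy.ndimage import distance_transform_edt

                d = distance_transform_edt(~mask).ravel()
                d[~interior.ravel()] = np.inf
                d[mask.ravel()] = np.inf
                grow = np.argsort(d, kind="stable")[: target_px - mask.sum()]
                mask.ravel()[grow] = True

    # image: dark background, bright skull, textured brain, shifted lobes
    img = np.full((h, w), 0.05)
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
    texture /= max(np.abs(texture).max(), 1e-9)
    img[interior] = 0.40 + 0.05 * texture[interior]
    img[skull] = 0.92
    img[mask] += spec.lobe_contrast
    img += spec.noise_sd * rng.standard_normal((h, w))
    np.clip(img, 0.0, 1.0, out=img)
    return img, mask.astype(np.uint8), bool(is_pole)


def split_subjects(
    n_subjects: int, seed: int, ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
) -> dict[int, str]:
    """Random subject-level train/val/test split at ``ratios`` (default 7:1:2).

    Sizes are round(0.7 n) / round(0.1 n) / remainder; every subject lands
    in exactly one partition. 70 subjects give the canonical 49/7/14.
    """
    if n_subjects < 10:
        raise ValueError("need at least 10 subjects to populate all three partitions")
    n_train = int(round(ratios[0] * n_subjects))
    n_val = int(round(ratios[1] * n_subjects))
    n_test = n_subjects - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("split ratios leave an empty partition")
    order = np.random.default_rng([seed, 7, 1, 2]).permutation(n_subjects)
    labels = {}
    for i, s in enumerate(order):
        if i < n_train:
            labels[int(s)] = "train"
        elif i < n_train + n_val:
            labels[int(s)] = "val"
        else:
            labels[int(s)] = "test"
    return labels


@dataclass
class Cohort:
    """A generated cohort: stacked slices plus a manifest DataFrame with
    columns subject, slice, partition, is_pole."""

    spec: PhantomSpec
    images: np.ndarray  # (n, H, W) float64 in [0,1]
    masks: np.ndarray  # (n, H, W) uint8
    manifest: pd.DataFrame

    def subset(self, partition: str) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        sel = self.manifest["partition"] == partition
        idx = self.manifest.index[sel].to_numpy()
        return self.images[idx], self.masks[idx], self.manifest.loc[sel].reset_index(drop=True)

    @property
    def foreground_fraction(self) -> float:
        return float(self.masks.sum() / self.masks.size)


def generate_cohort(spec: PhantomSpec) -> Cohort:
    """Generate all slices of all subjects and attach the 7:1:2 subject split."""
    labels = split_subjects(spec.n_subjects, spec.seed)
    h, w = spec.image_size
    n = spec.n_subjects * spec.slices_per_subject
    images = np.empty((n, h, w))
    masks = np.empty((n, h, w), dtype=np.uint8)
    rows = []
    k = 0
    for s in range(spec.n_subjects):
        for z in range(spec.slices_per_subject):
            img, msk, pole = generate_slice(spec, s, z)
            images[k] = img
            masks[k] = msk
            rows.append(
                {"subject": s, "slice": z, "partition": labels[s], "is_pole": pole}
            )
            k += 1
    return Cohort(spec, images, masks, pd.DataFrame(rows))
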