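"""CT slice preparation and paired augmentation.

The preparation chain for a raw planning-CT slice is

    raw -> HU (rescale slope/intercept) -> window (WW 160 / WL 80)
        -> CLAHE -> min-max normalization to [0, 1]

mirroring the soft-tissue brain window used when delineating the temporal
lobe. Augmentation applies one random affine transform (rotation, flip,
zoom, shear) identically to image and mask, with bilinear interpolation
for the image and nearest-neighbour for the mask so labels stay crisp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

__all__ = [
    "CTSlice",
    "AugmentSpec",
    "Stage",
    "to_hu",
    "window",
    "adaptive_equalize",
    "normalize01",
    "preprocess_chain",
    "augment_pair",
    "affine_params_for",
]


Stage = ("raw", "hu", "windowed", "equalized", "normalized")


@dataclass(frozen=True)
class CTSlice:
    """One 2-D grayscale slice at a known processing stage.

    ``rescale`` is the (slope, intercept) pair from the scanner header and
    is required only at stage "raw".
    """

    pixels: np.ndarray
    stage: str = "normalized"
    spacing: tuple[float, float] = (1.0, 1.0)
    rescale: tuple[float, float] | None = None

    def __post_init__(self):
        if self.stage not in Stage:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=np.float64))
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")


@dataclass(frozen=True)
class AugmentSpec:
    """Ranges for the random paired affine augmentation.

    Angles in degrees; ``zoom`` is an isotropic scale factor range around
    1. The seed fixes the whole sampled transform sequence.
    """

    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    flip_horizontal: bool = True
    zoom: tuple[float, float] = (0.9, 1.1)
    shear_deg: tuple[float, float] = (-8.0, 8.0)
    seed: int = 0

    def __post_init__(self):
        for rng in (self.rotation_deg, self.zoom, self.shear_deg):
            if not (np.isfinite(rng[0]) and np.isfinite(rng[1]) and rng[0] <= rng[1]):
                raise ValueError(f"invalid range {rng}")


# --------------------------------------------------------------------------
# the chain
# --------------------------------------------------------------------------


def to_hu(ct: CTSlice) -> CTSlice:
    """Convert raw scanner integers to Hounsfield units: HU = raw*slope + intercept."""
    if ct.stage != "raw":
        raise ValueError(f"to_hu expects stage 'raw', got {ct.stage!r}")
    if ct.rescale is None:
        raise ValueError("raw slice is missing rescale (slope, intercept) metadata")
    slope, intercept = ct.rescale
    return CTSlice(ct.pixels * slope + intercept, "hu", ct.spacing, None)


def window(ct: CTSlice, width: float = 160.0, level: float = 80.0) -> CTSlice:
    """Clip HU to [level - width/2, level + width/2], then map linearly to [0, 1].

    The defaults (WW 160, WL 80) are the soft-tissue brain window used for
    the temporal lobe; HU at the level maps to 0.5.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if ct.stage != "hu":
        raise ValueError(f"window expects stage 'hu', got {ct.stage!r}")
    lo = level - width / 2.0
    out = (np.clip(ct.pixels, lo, lo + width) - lo) / width
    return CTSlice(out, "windowed", ct.spacing, None)


def adaptive_equalize(
    ct: CTSlice, clip_limit: float = 0.01, tile_grid: tuple[int, int] = (8, 8)
) -> CTSlice:
    """Contrast-limited adaptive histogram equalization (CLAHE) on [0,1] pixels."""
    if not np.isfinite(ct.pixels).all():
        raise ValueError("non-finite pixel values")
    if ct.pixels.min() < 0 or ct.pixels.max() > 1:
        raise ValueError("adaptive_equalize expects pixels in [0, 1]")
    if ct.pixels.max() == ct.pixels.min():
        # no contrast to redistribute
        return CTSlice(ct.pixels.copy(), "equalized", ct.spacing, None)
    h, w = ct.pixels.shape
    kernel = (max(1, h // tile_grid[0]), max(1, w // tile_grid[1]))
    out = exposure.equalize_adapthist(ct.pixels, kernel_size=kernel, clip_limit=clip_limit)
    return CTSlice(np.clip(out, 0.0, 1.0), "equalized", ct.spacing, None)


def normalize01(ct: CTSlice) -> CTSlice:
    """Min-max scale to [0, 1]; a constant image maps to all zeros."""
    if not np.isfinite(ct.pixels).all():
        raise ValueError("non-finite pixel values")
    lo, hi = ct.pixels.min(), ct.pixels.max()
    if hi == lo:
        out = np.zeros_like(ct.pixels)
    else:
        out = (ct.pixels - lo) / (hi - lo)
    return CTSlice(out, "normalized", ct.spacing, None)


def preprocess_chain(
    ct: CTSlice,
    width: float = 160.0,
    level: float = 80.0,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> CTSlice:
    """Run the full chain from whatever stage ``ct`` is at down to "normalized"."""
    if ct.stage == "raw":
        ct = to_hu(ct)
    if ct.stage == "hu":
        ct = window(ct, width, level)
    if ct.stage == "windowed":
        ct = adaptive_equalize(ct, clip_limit, tile_grid)
    if ct.stage == "equalized":
        ct = normalize01(ct)
    return ct


# --------------------------------------------------------------------------
# paired augmentation
# --------------------------------------------------------------------------


def affine_params_for(spec: AugmentSpec, n: int) -> list[dict]:
    """The deterministic sequence of sampled transform parameters for ``n``
    augmented copies under ``spec`` (exposed so tests can reproduce the
    exact coordinate mapping)."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(n):
        out.append(
            {
                "rotation_deg": float(rng.uniform(*spec.rotation_deg)),
                "zoom": float(rng.uniform(*spec.zoom)),
                "shear_deg": float(rng.uniform(*spec.shear_deg)),
                "flip": bool(spec.flip_horizontal and rng.random() < 0.5),
            }
        )
    return out


def _center_affine(shape: tuple[int, int], p: dict) -> transform.AffineTransform:
    """Affine transform about the image centre built from sampled params."""
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    t = transform.AffineTransform(
        rotation=np.deg2rad(p["rotation_deg"]),
        shear=np.deg2rad(p["shear_deg"]),
        scale=(p["zoom"], p["zoom"]),
    )
    shift = transform.AffineTransform(translation=-center)
    unshift = transform.AffineTransform(translation=center)
    m = unshift.params @ t.params @ shift.params
    if p["flip"]:
        flip = np.array([[-1.0, 0.0, w - 1.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        m = m @ flip
    return transform.AffineTransform(matrix=m)


def _is_identity(p: dict) -> bool:
    return (
        p["rotation_deg"] == 0.0
        and p["shear_deg"] == 0.0
        and p["zoom"] == 1.0
        and not p["flip"]
    )


def apply_affine_pair(
    image: np.ndarray, mask: np.ndarray, p: dict
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one sampled transform to an image (bilinear) and its mask
    (nearest-neighbour, stays crisp)."""
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if _is_identity(p):
        return image.copy(), mask.copy()
    tf = _center_affine(image.shape, p)
    img_out = transform.warp(
        image.astype(np.float64), tf.inverse, order=1, mode="constant", cval=0.0
    )
    mask_out = transform.warp(
        mask.astype(np.float64), tf.inverse, order=0, mode="constant", cval=0.0
    )
    return img_out, (mask_out > 0.5).astype(mask.dtype)


def augment_pair(
    image: CTSlice | np.ndarray, mask: np.ndarray, spec: AugmentSpec, n: int = 1
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``n`` augmented (image, mask) copies; the sequence is reproducible
    from ``spec.seed``."""
    pixels = image.pixels if isinstance(image, CTSlice) else np.asarray(image)
    mask = np.asarray(mask)
    if pixels.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    return [apply_affine_pair(pixels, mask, p) for p in affine_params_for(spec, n)]
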