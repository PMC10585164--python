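"""Imbalance-aware losses for binary segmentation.

The centrepiece is the focal generalized Dice + binary cross-entropy
compound loss (FGD-BCEL),

    L = (GDL)**alpha + beta * BCE,

where GDL is the two-class generalized Dice term with per-class weights
``w_l = 1 / (sum_n r_ln)**2``, ``alpha`` (default 0.75) modulates the Dice
term focally and ``beta`` (default 0.7) mixes in a weighted binary
cross-entropy that stabilises training on severely imbalanced masks.
The four standard comparison losses — Dice loss (DL), generalized Dice
loss (GDL), Tversky loss (TL) and focal Tversky loss (FTL) — are provided
with the same conventions.

Every loss exists in two numerically identical forms:

* a plain-``numpy`` scalar function operating on a probability map and a
  binary mask (the reference used throughout the tests), and
* a :class:`~lobeseg.nn.Tensor` form (``*_t``) that participates in the
  autodiff graph and serves as the training objective.

Class sums run over all pixels passed in (a whole batch when the arrays
are stacked); per-image averaging is available via ``per_image=True`` on
the batch helpers in :mod:`lobeseg.model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lobeseg.nn import Tensor

__all__ = [
    "ClassWeights",
    "FGDBCELParams",
    "TverskyParams",
    "LossSpec",
    "LOSS_NAMES",
    "gdl_weights",
    "generalized_dice_term",
    "weighted_bce",
    "fgd_bcel",
    "dice_loss",
    "tversky_loss",
    "focal_tversky_loss",
    "evaluate_loss",
    "batch_loss",
    "make_training_loss",
]


# --------------------------------------------------------------------------
# parameter blocks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassWeights:
    """Per-class weights ``w_l`` of the generalized Dice term."""

    w_foreground: float
    w_background: float

    def __post_init__(self):
        if self.w_foreground < 0 or self.w_background < 0:
            raise ValueError("class weights must be non-negative")
        if self.w_foreground == 0 and self.w_background == 0:
            raise ValueError("class weights cannot both be zero")


@dataclass(frozen=True)
class FGDBCELParams:
    """Hyperparameters of the compound loss.

    alpha : focal exponent on the generalized Dice term (study value 0.75)
    beta  : mixing weight of the BCE term (study value 0.7)
    eps   : smoothing added to numerator and denominator of the Dice ratio
    clip_eps : probability clipping bound for the logarithms in BCE
    """

    alpha: float = 0.75
    beta: float = 0.7
    eps: float = 1e-6
    clip_eps: float = 1e-7
    bce_weights: ClassWeights | None = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.eps <= 0 or self.clip_eps <= 0 or self.clip_eps >= 0.5:
            raise ValueError("eps must be > 0 and clip_eps in (0, 0.5)")


@dataclass(frozen=True)
class TverskyParams:
    """False-positive/false-negative trade-off weights; ``gamma`` is the
    focal exponent used by the focal Tversky loss only."""

    fp_weight: float = 0.3
    fn_weight: float = 0.7
    gamma: float = 0.75
    eps: float = 1e-6

    def __post_init__(self):
        if not (0 <= self.fp_weight <= 1 and 0 <= self.fn_weight <= 1):
            raise ValueError("fp_weight and fn_weight must lie in [0, 1]")
        if abs(self.fp_weight + self.fn_weight - 1.0) > 1e-9:
            raise ValueError("fp_weight + fn_weight must equal 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


LOSS_NAMES = ("fgd_bcel", "dl", "gdl", "tl", "ftl", "bce")


@dataclass(frozen=True)
class LossSpec:
    """A loss selected by name plus its parameter block.

    ``params`` is an :class:`FGDBCELParams` for ``fgd_bcel``/``gdl``/``bce``,
    a :class:`TverskyParams` for ``tl``/``ftl`` and ignored (eps only) for
    ``dl``.
    """

    name: str = "fgd_bcel"
    params: FGDBCELParams | TverskyParams | None = None
    eps: float = 1e-6

    def __post_init__(self):
        if self.name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.name!r}; choose from {LOSS_NAMES}")

    def resolved_params(self):
        if self.params is not None:
            return self.params
        if self.name in ("tl", "ftl"):
            return TverskyParams()
        return FGDBCELParams()


# --------------------------------------------------------------------------
# validation helpers
# --------------------------------------------------------------------------


def _check_pair(prob: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    prob = np.asarray(prob, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if prob.shape != mask.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs mask {mask.shape}")
    if prob.size == 0:
        raise ValueError("empty arrays")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(mask, (0.0, 1.0)).all():
        raise ValueError("mask must contain only 0 and 1")
    return prob, mask


# --------------------------------------------------------------------------
# plain-array reference implementations
# --------------------------------------------------------------------------


def gdl_weights(mask: np.ndarray, eps: float = 1e-6) -> ClassWeights:
    """Generalized-Dice class weights ``w_l = 1 / (sum_n r_ln + eps)**2``.

    The inverse-squared class volume upweights the scarce foreground; the
    additive ``eps`` keeps the weight finite when a class is absent.
    """
    mask = np.asarray(mask, dtype=np.float64)
    if not np.isin(mask, (0.0, 1.0)).all():
        raise ValueError("mask must contain only 0 and 1")
    n_fg = mask.sum()
    n_bg = mask.size - n_fg
    return ClassWeights(1.0 / (n_fg + eps) ** 2, 1.0 / (n_bg + eps) ** 2)


def generalized_dice_term(
    prob: np.ndarray,
    mask: np.ndarray,
    weights: ClassWeights | None = None,
    eps: float = 1e-6,
) -> float:
    """Two-class generalized Dice term ``1 - 2 * sum_l w_l sum_n r p /
    sum_l w_l sum_n (r + p)`` with ``eps`` smoothing both the ratio's
    numerator and denominator."""
    prob, mask = _check_pair(prob, mask)
    if weights is None:
        weights = gdl_weights(mask, eps)
    w_fg, w_bg = weights.w_foreground, weights.w_background
    inter = w_fg * (mask * prob).sum() + w_bg * ((1 - mask) * (1 - prob)).sum()
    total = w_fg * (mask + prob).sum() + w_bg * ((1 - mask) + (1 - prob)).sum()
    return float(1.0 - (2.0 * inter + eps) / (total + eps))


def weighted_bce(
    prob: np.ndarray,
    mask: np.ndarray,
    clip_eps: float = 1e-7,
    class_weights: ClassWeights | None = None,
) -> float:
    """Pixel-mean binary cross-entropy with optional per-class weights.

    Probabilities are clipped to ``[clip_eps, 1 - clip_eps]`` before the
    logarithms. Default weights are 1/1 — in the compound loss the mixing
    coefficient beta alone carries the weighting.
    """
    prob, mask = _check_pair(prob, mask)
    w_fg = w_bg = 1.0
    if class_weights is not None:
        w_fg, w_bg = class_weights.w_foreground, class_weights.w_background
    p = np.clip(prob, clip_eps, 1.0 - clip_eps)
    ll = w_fg * mask * np.log(p) + w_bg * (1.0 - mask) * np.log(1.0 - p)
    return float(-ll.mean())


def fgd_bcel(
    prob: np.ndarray, mask: np.ndarray, params: FGDBCELParams | None = None
) -> float:
    """The compound loss ``(GDL term)**alpha + beta * BCE``."""
    if params is None:
        params = FGDBCELParams()
    gdl = generalized_dice_term(prob, mask, eps=params.eps)
    bce = weighted_bce(prob, mask, params.clip_eps, params.bce_weights)
    return float(max(gdl, 0.0) ** params.alpha + params.beta * bce)


def dice_loss(prob: np.ndarray, mask: np.ndarray, eps: float = 1e-6) -> float:
    """Soft Dice loss on the foreground class only."""
    prob, mask = _check_pair(prob, mask)
    inter = (mask * prob).sum()
    return float(1.0 - (2.0 * inter + eps) / (mask.sum() + prob.sum() + eps))


def tversky_loss(
    prob: np.ndarray, mask: np.ndarray, params: TverskyParams | None = None
) -> float:
    """Tversky loss: Dice with asymmetric false-positive/false-negative
    weights (0.5/0.5 recovers the Dice loss)."""
    if params is None:
        params = TverskyParams()
    prob, mask = _check_pair(prob, mask)
    tp = (mask * prob).sum()
    fn = (mask * (1.0 - prob)).sum()
    fp = ((1.0 - mask) * prob).sum()
    denom = tp + params.fn_weight * fn + params.fp_weight * fp
    return float(1.0 - (tp + params.eps) / (denom + params.eps))


def focal_tversky_loss(
    prob: np.ndarray, mask: np.ndarray, params: TverskyParams | None = None
) -> float:
    """Tversky loss raised to the focal exponent gamma."""
    if params is None:
        params = TverskyParams()
    return float(max(tversky_loss(prob, mask, params), 0.0) ** params.gamma)


def batch_loss(
    spec: "LossSpec", probs: np.ndarray, masks: np.ndarray, per_image: bool = False
) -> float:
    """Loss over an (n, H, W) stack.

    Default batch semantics pool the class sums over all pixels of the
    stack; ``per_image=True`` evaluates each slice separately and averages,
    which changes the generalized-Dice class weights on heterogeneous
    batches.
    """
    probs = np.asarray(probs)
    masks = np.asarray(masks)
    if probs.shape != masks.shape or probs.ndim != 3:
        raise ValueError("probs and masks must be matching (n, H, W) stacks")
    if not per_image:
        return evaluate_loss(spec, probs, masks)
    return float(np.mean([evaluate_loss(spec, p, m) for p, m in zip(probs, masks)]))


def evaluate_loss(spec: LossSpec, prob: np.ndarray, mask: np.ndarray) -> float:
    """Evaluate the loss selected by ``spec`` with the plain-array path."""
    p = spec.resolved_params()
    if spec.name == "fgd_bcel":
        return fgd_bcel(prob, mask, p)
    if spec.name == "dl":
        return dice_loss(prob, mask, spec.eps)
    if spec.name == "gdl":
        return generalized_dice_term(prob, mask, eps=p.eps)
    if spec.name == "tl":
        return tversky_loss(prob, mask, p)
    if spec.name == "ftl":
        return focal_tversky_loss(prob, mask, p)
    if spec.name == "bce":
        return weighted_bce(prob, mask, p.clip_eps, p.bce_weights)
    raise AssertionError(spec.name)


# --------------------------------------------------------------------------
# autodiff (training) implementations — numerics mirror the references
# --------------------------------------------------------------------------


def generalized_dice_term_t(
    prob: Tensor, mask: np.ndarray, weights: ClassWeights | None = None, eps: float = 1e-6
) -> Tensor:
    mask = np.asarray(mask, dtype=np.float64)
    if weights is None:
        weights = gdl_weights(mask, eps)
    w_fg, w_bg = weights.w_foreground, weights.w_background
    inter = (prob * mask).sum() * w_fg + ((1.0 - prob) * (1.0 - mask)).sum() * w_bg
    total = (prob + mask).sum() * w_fg + ((1.0 - prob) + (1.0 - mask)).sum() * w_bg
    return (total + eps - (inter * 2.0 + eps)) / (total + eps)


def weighted_bce_t(
    prob: Tensor,
    mask: np.ndarray,
    clip_eps: float = 1e-7,
    class_weights: ClassWeights | None = None,
) -> Tensor:
    mask = np.asarray(mask, dtype=np.float64)
    w_fg = w_bg = 1.0
    if class_weights is not None:
        w_fg, w_bg = class_weights.w_foreground, class_weights.w_background
    p = prob.clip(clip_eps, 1.0 - clip_eps)
    ll = p.log() * mask * w_fg + (1.0 - p).log() * (1.0 - mask) * w_bg
    return -(ll.mean())


def fgd_bcel_t(prob: Tensor, mask: np.ndarray, params: FGDBCELParams | None = None) -> Tensor:
    if params is None:
        params = FGDBCELParams()
    gdl = generalized_dice_term_t(prob, mask, eps=params.eps)
    bce = weighted_bce_t(prob, mask, params.clip_eps, params.bce_weights)
    return gdl ** params.alpha + bce * params.beta


def dice_loss_t(prob: Tensor, mask: np.ndarray, eps: float = 1e-6) -> Tensor:
    mask = np.asarray(mask, dtype=np.float64)
    inter = (prob * mask).sum()
    total = prob.sum() + float(mask.sum())
    return (total + eps - (inter * 2.0 + eps)) / (total + eps)


def tversky_loss_t(prob: Tensor, mask: np.ndarray, params: TverskyParams | None = None) -> Tensor:
    if params is None:
        params = TverskyParams()
    mask = np.asarray(mask, dtype=np.float64)
    tp = (prob * mask).sum()
    fn = ((1.0 - prob) * mask).sum()
    fp = (prob * (1.0 - mask)).sum()
    denom = tp + fn * params.fn_weight + fp * params.fp_weight
    return (denom + params.eps - (tp + params.eps)) / (denom + params.eps)


def focal_tversky_loss_t(
    prob: Tensor, mask: np.ndarray, params: TverskyParams | None = None
) -> Tensor:
    if params is None:
        params = TverskyParams()
    return tversky_loss_t(prob, mask, params) ** params.gamma


def make_training_loss(spec: LossSpec):
    """Return ``f(prob_tensor, mask_array) -> scalar Tensor`` for ``spec``."""
    p = spec.resolved_params()
    if spec.name == "fgd_bcel":
        return lambda prob, mask: fgd_bcel_t(prob, mask, p)
    if spec.name == "dl":
        return lambda prob, mask: dice_loss_t(prob, mask, spec.eps)
    if spec.name == "gdl":
        return lambda prob, mask: generalized_dice_term_t(prob, mask, eps=p.eps)
    if spec.name == "tl":
        return lambda prob, mask: tversky_loss_t(prob, mask, p)
    if spec.name == "ftl":
        return lambda prob, mask: focal_tversky_loss_t(prob, mask, p)
    if spec.name == "bce":
        return lambda prob, mask: weighted_bce_t(prob, mask, p.clip_eps, p.bce_weights)
    raise AssertionError(spec.name)
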