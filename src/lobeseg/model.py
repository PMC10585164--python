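"""Compact encoder/decoder segmentation network and its training loop.

The network is the classic 4-level U-Net: encoder blocks of two 3x3
convolutions (ReLU) followed by 2x2 max pooling, a two-convolution
bottleneck, and decoder blocks of a stride-2 3x3 transposed convolution
(zero-insertion upsampling + 3x3 convolution), skip concatenation, and two
3x3 convolutions. All convolutions use same padding, so skip tensors
concatenate without cropping and the output shape equals the input shape;
a final 1x1 convolution with a sigmoid yields per-pixel foreground
probabilities. ``base_filters`` scales the channel widths (64 at full
scale, 8 for desk-scale runs), doubling at each level.

Training uses Adam with a continuously (non-staircase by default)
exponentially decayed learning rate, ``lr = lr0 * rate**(step/steps)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from lobeseg import nn
from lobeseg.losses import LossSpec, make_training_loss
from lobeseg.nn import Tensor

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "UNet",
    "build_unet",
    "unet_parameter_count",
    "lr_schedule",
    "train",
    "predict",
    "binarize",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class UNetConfig:
    """``head_bias_prior`` initialises the final 1x1 convolution's bias to
    the logit of the expected foreground fraction, so the initial output
    probability matches the class prior instead of 0.5. On severely
    imbalanced masks this prevents the first epochs from driving every
    logit strongly negative, the collapse mode in which clipped
    cross-entropy and Dice-type gradients both vanish."""

    input_size: tuple[int, int, int] = (512, 512, 1)
    depth: int = 4
    base_filters: int = 64
    head_bias_prior: float | None = 0.01

    def __post_init__(self):
        h, w, c = self.input_size
        if c != 1:
            raise ValueError("single-channel input expected")
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(
                f"input {h}x{w} must be divisible by 2**depth = {f} so that "
                f"{self.depth} pooling stages and their upsampling stages "
                "return to the original size"
            )
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are the full-scale settings of the
    compound-loss arm (batch 2, 120 epochs, lr 5e-4 decayed by 0.96 every
    600 steps)."""

    batch_size: int = 2
    epochs: int = 120
    initial_lr: float = 5e-4
    decay_steps: int = 600
    decay_rate: float = 0.96
    loss: LossSpec = field(default_factory=LossSpec)
    seed: int = 0
    staircase: bool = False
    warmup_steps: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.decay_steps) < 1:
            raise ValueError("batch_size, epochs and decay_steps must be positive")
        if self.initial_lr <= 0 or not (0 < self.decay_rate <= 1):
            raise ValueError("initial_lr must be > 0 and decay_rate in (0, 1]")


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Exponentially decayed learning rate at an optimizer step, with an
    optional linear warmup over the first ``warmup_steps`` steps (damps the
    large effective size of early Adam updates, whose moment estimates are
    still uncalibrated)."""
    if step < 0:
        raise ValueError("step must be non-negative")
    exponent = step / config.decay_steps
    if config.staircase:
        exponent = np.floor(exponent)
    lr = float(config.initial_lr * config.decay_rate**exponent)
    if config.warmup_steps and step < config.warmup_steps:
        lr *= (step + 1) / config.warmup_steps
    return lr


class UNet:
    """Parameter container + forward pass. Weights are He-normal initialised
    from ``seed``; no batch normalisation."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng([seed, 4242])
        self.params: dict[str, Tensor] = {}
        d, bf = config.depth, config.base_filters
        chans = [bf * 2**i for i in range(d + 1)]

        def conv_param(name, cin, cout, k=3):
            std = np.sqrt(2.0 / (cin * k * k))
            self.params[f"{name}.w"] = Tensor(
                rng.normal(0.0, std, (cout, cin, k, k)), requires_grad=True
            )
            self.params[f"{name}.b"] = Tensor(np.zeros(cout), requires_grad=True)

        cin = 1
        for lvl in range(d):
            conv_param(f"enc{lvl}.c1", cin, chans[lvl])
            conv_param(f"enc{lvl}.c2", chans[lvl], chans[lvl])
            cin = chans[lvl]
        conv_param("bott.c1", chans[d - 1], chans[d])
        conv_param("bott.c2", chans[d], chans[d])
        for lvl in reversed(range(d)):
            conv_param(f"dec{lvl}.up", chans[lvl + 1], chans[lvl])
            conv_param(f"dec{lvl}.c1", 2 * chans[lvl], chans[lvl])
            conv_param(f"dec{lvl}.c2", chans[lvl], chans[lvl])
        conv_param("head", chans[0], 1, k=1)
        if config.head_bias_prior is not None:
            pi = config.head_bias_prior
            self.params["head.b"].data[:] = np.log(pi / (1.0 - pi))

    def _block(self, x, name):
        x = nn.relu(nn.conv2d(x, self.params[f"{name}.c1.w"], self.params[f"{name}.c1.b"]))
        return nn.relu(nn.conv2d(x, self.params[f"{name}.c2.w"], self.params[f"{name}.c2.b"]))

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """(N, 1, H, W) image batch -> (N, 1, H, W) probability batch."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h, w = self.config.input_size[:2]
        if x.data.ndim != 4 or x.data.shape[1] != 1 or x.data.shape[2:] != (h, w):
            raise ValueError(
                f"expected batch of shape (N, 1, {h}, {w}), got {x.data.shape}"
            )
        d = self.config.depth
        skips = []
        for lvl in range(d):
            x = self._block(x, f"enc{lvl}")
            skips.append(x)
            x = nn.maxpool2x2(x)
        x = self._block(x, "bott")
        for lvl in reversed(range(d)):
            up = nn.conv2d(
                nn.zero_upsample2(x),
                self.params[f"dec{lvl}.up.w"],
                self.params[f"dec{lvl}.up.b"],
            )
            x = nn.concat([nn.relu(up), skips[lvl]], axis=1)
            x = self._block(x, f"dec{lvl}")
        logits = nn.conv2d(x, self.params["head.w"], self.params["head.b"])
        return nn.sigmoid(logits)

    def parameter_count(self) -> int:
        return sum(int(p.data.size) for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            if k not in state:
                raise KeyError(f"checkpoint is missing parameter {k!r}")
            if state[k].shape != p.data.shape:
                raise ValueError(
                    f"checkpoint/{k}: shape {state[k].shape} does not match "
                    f"model shape {p.data.shape} (input-size or width mismatch)"
                )
            p.data = state[k].astype(np.float64).copy()


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    return UNet(config, seed)


def unet_parameter_count(depth: int, base_filters: int) -> int:
    """Closed-form parameter count (3x3 kernels + biases, 1x1 head) for
    cross-checking a built network."""
    chans = [base_filters * 2**i for i in range(depth + 1)]
    total = 0

    def conv(cin, cout, k=3):
        return cin * cout * k * k + cout

    cin = 1
    for lvl in range(depth):
        total += conv(cin, chans[lvl]) + conv(chans[lvl], chans[lvl])
        cin = chans[lvl]
    total += conv(chans[depth - 1], chans[depth]) + conv(chans[depth], chans[depth])
    for lvl in range(depth):
        total += conv(chans[lvl + 1], chans[lvl])
        total += conv(2 * chans[lvl], chans[lvl]) + conv(chans[lvl], chans[lvl])
    total += conv(chans[0], 1, k=1)
    return total


class Adam:
    def __init__(self, params: dict[str, Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _batch_loss(model, loss_fn, images, masks):
    # class sums inside the loss run over the whole batch (default batch
    # semantics; see lobeseg.losses.batch_loss for the per-image variant)
    prob = model.forward(images[:, None, :, :])
    return loss_fn(prob, masks[:, None, :, :].astype(np.float64))


def train(
    model: UNet,
    train_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    val_data: tuple[np.ndarray, np.ndarray] | None = None,
    verbose: bool = False,
) -> dict:
    """Optimize ``model`` in place; returns the loss history.

    ``train_data``/``val_data`` are ``(images (n,H,W), masks (n,H,W))``.
    The best-validation parameter set is restored at the end (when
    validation data is given). Raises :class:`TrainingDiverged`, naming the
    epoch and batch, if the loss becomes non-finite.
    """
    images, masks = train_data
    if images.shape != masks.shape or images.ndim != 3:
        raise ValueError("train_data must be matching (n, H, W) image/mask stacks")
    loss_fn = make_training_loss(config.loss)
    opt = Adam(model.params)
    rng = np.random.default_rng([config.seed, 1337])
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val, best_state = np.inf, None
    step = 0
    for epoch in range(config.epochs):
        epoch_losses = []
        for batch in _as_batches(len(images), config.batch_size, rng):
            opt.zero_grad()
            loss = _batch_loss(model, loss_fn, images[batch], masks[batch])
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite {config.loss.name} loss at epoch {epoch}, "
                    f"batch with slice indices {batch.tolist()}"
                )
            loss.backward()
            opt.step(lr_schedule(step, config))
            history["lr"].append(lr_schedule(step, config))
            epoch_losses.append(value)
            step += 1
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_data is not None:
            vprob = predict_batch(model, val_data[0])
            vloss = float(
                loss_fn(Tensor(vprob[:, None]), val_data[1][:, None].astype(np.float64)).data
            )
            history["val_loss"].append(vloss)
            if vloss < best_val:
                best_val, best_state = vloss, model.state_dict()
        if verbose:  # pragma: no cover
            msg = f"epoch {epoch + 1}/{config.epochs} train {history['train_loss'][-1]:.4f}"
            if val_data is not None:
                msg += f" val {history['val_loss'][-1]:.4f}"
            print(msg)
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def predict(model: UNet, image: np.ndarray) -> np.ndarray:
    """Foreground probability map for one (H, W) image."""
    image = np.asarray(image, dtype=np.float64)
    h, w = model.config.input_size[:2]
    if image.shape != (h, w):
        raise ValueError(f"expected image of shape {(h, w)}, got {image.shape}")
    return model.forward(image[None, None]).data[0, 0]


def predict_batch(model: UNet, images: np.ndarray, chunk: int = 4) -> np.ndarray:
    """Probability maps for an (n, H, W) stack, evaluated in chunks."""
    out = []
    for i in range(0, len(images), chunk):
        out.append(model.forward(images[i : i + chunk, None]).data[:, 0])
    return np.concatenate(out, axis=0)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Crisp mask by ``p >= threshold``."""
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return (prob >= threshold).astype(np.uint8)


def save_model(model: UNet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"input_size": list(model.config.input_size), "depth": model.config.depth,
            "base_filters": model.config.base_filters}
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())


def load_model(path) -> UNet:
    with np.load(Path(path), allow_pickle=False) as f:
        meta = json.loads(str(f["__meta__"]))
        state = {k: f[k] for k in f.files if k != "__meta__"}
    cfg = UNetConfig(tuple(meta["input_size"]), meta["depth"], meta["base_filters"])
    model = UNet(cfg)
    model.load_state_dict(state)
    return model
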