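"""Tests of the autodiff engine, the U-Net contract, the learning-rate
schedule and the training loop."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from lobeseg import losses as L
from lobeseg import nn
from lobeseg.model import (
    TrainConfig,
    UNetConfig,
    binarize,
    build_unet,
    load_model,
    lr_schedule,
    predict,
    save_model,
    train,
    unet_parameter_count,
)
from lobeseg.model import TrainingDiverged
from lobeseg.nn import Tensor


class TestEngine:
    def test_conv2d_matches_scipy_correlate(self, rng):
        x = rng.standard_normal((2, 3, 9, 9))
        w = rng.standard_normal((4, 3, 3, 3))
        out = nn.conv2d(Tensor(x), Tensor(w)).data
        for n in range(2):
            for f in range(4):
                ref = sum(
                    correlate2d(x[n, c], w[f, c], mode="same") for c in range(3)
                )
                assert np.allclose(out[n, f], ref, atol=1e-12)

    def test_conv2d_rejects_even_kernel(self, rng):
        with pytest.raises(ValueError, match="odd"):
            nn.conv2d(Tensor(rng.standard_normal((1, 1, 4, 4))),
                      Tensor(rng.standard_normal((1, 1, 2, 2))))

    def test_maxpool_forward(self):
        x = np.arange(16.0).reshape(1, 1, 4, 4)
        out = nn.maxpool2x2(Tensor(x)).data
        assert np.array_equal(out[0, 0], [[5.0, 7.0], [13.0, 15.0]])

    def test_zero_upsample_places_values_on_even_lattice(self, rng):
        x = rng.standard_normal((1, 2, 3, 3))
        y = nn.zero_upsample2(Tensor(x)).data
        assert y.shape == (1, 2, 6, 6)
        assert np.array_equal(y[:, :, ::2, ::2], x)
        assert y[:, :, 1::2, :].sum() == 0.0

    def test_composite_gradient_matches_finite_differences(self, rng):
        """Backprop through conv -> relu -> pool -> upsample -> conv ->
        sigmoid agrees with central differences on sampled weights."""
        x = Tensor(rng.standard_normal((1, 1, 8, 8)))
        w1 = Tensor(rng.standard_normal((3, 1, 3, 3)) * 0.4, requires_grad=True)
        w2 = Tensor(rng.standard_normal((1, 3, 3, 3)) * 0.4, requires_grad=True)

        def forward(w1_, w2_):
            y = nn.relu(nn.conv2d(x, w1_))
            y = nn.maxpool2x2(y)
            y = nn.conv2d(nn.zero_upsample2(y), w2_)
            return nn.sigmoid(y).sum()

        forward(w1, w2).backward()
        h = 1e-5
        flat = [(w1, (0, 0, 1, 1)), (w1, (2, 0, 0, 2)), (w2, (0, 1, 2, 0))]
        for t, idx in flat:
            up, dn = t.data.copy(), t.data.copy()
            up[idx] += h
            dn[idx] -= h
            args_up = (Tensor(up), w2) if t is w1 else (w1, Tensor(up))
            args_dn = (Tensor(dn), w2) if t is w1 else (w1, Tensor(dn))
            num = (float(forward(*args_up).data) - float(forward(*args_dn).data)) / (2 * h)
            assert t.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_broadcast_add_gradient(self):
        a = Tensor(np.ones((2, 3)), requires_grad=True)
        b = Tensor(np.ones(3), requires_grad=True)
        (a + b).sum().backward()
        assert np.array_equal(b.grad, [2.0, 2.0, 2.0])

    def test_backward_requires_scalar(self):
        t = Tensor(np.ones(3), requires_grad=True)
        with pytest.raises(ValueError):
            t.backward()


class TestUNetContract:
    def test_output_shape_equals_input_shape(self, rng):
        net = build_unet(UNetConfig((64, 64, 1), base_filters=2), seed=0)
        out = net.forward(rng.uniform(0, 1, (2, 1, 64, 64)))
        assert out.data.shape == (2, 1, 64, 64)

    def test_output_is_probability(self, rng):
        net = build_unet(UNetConfig((32, 32, 1), base_filters=2), seed=0)
        out = net.forward(rng.uniform(0, 1, (1, 1, 32, 32))).data
        assert out.min() > 0.0 and out.max() < 1.0

    def test_indivisible_size_rejected_with_explanation(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetConfig((100, 100, 1))

    def test_parameter_count_closed_form(self):
        net = build_unet(UNetConfig((64, 64, 1), depth=4, base_filters=8), seed=0)
        assert net.parameter_count() == unet_parameter_count(4, 8)

    def test_doubling_filters_roughly_quadruples_parameters(self):
        small = unet_parameter_count(4, 8)
        big = unet_parameter_count(4, 16)
        assert 3.5 < big / small < 4.5

    def test_same_seed_same_init(self):
        a = build_unet(UNetConfig((32, 32, 1), base_filters=2), seed=7)
        b = build_unet(UNetConfig((32, 32, 1), base_filters=2), seed=7)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)


class TestLrSchedule:
    CFG = TrainConfig(initial_lr=5e-4, decay_steps=600, decay_rate=0.96)

    def test_initial_value(self):
        assert lr_schedule(0, self.CFG) == pytest.approx(5e-4)

    def test_one_decay_period(self):
        assert lr_schedule(600, self.CFG) == pytest.approx(5e-4 * 0.96)

    def test_strictly_decreasing(self):
        lrs = [lr_schedule(s, self.CFG) for s in range(0, 2000, 50)]
        assert all(a > b for a, b in zip(lrs, lrs[1:]))

    def test_staircase_holds_within_period(self):
        cfg = TrainConfig(initial_lr=1e-3, decay_steps=100, decay_rate=0.9,
                          staircase=True)
        assert lr_schedule(99, cfg) == pytest.approx(1e-3)
        assert lr_schedule(100, cfg) == pytest.approx(9e-4)


class TestPredictBinarize:
    def test_binarize_thresholds(self):
        assert binarize(np.full((2, 2), 0.4)).sum() == 0
        assert binarize(np.full((2, 2), 0.6)).sum() == 4
        assert binarize(np.full((2, 2), 0.2), threshold=0.0).sum() == 4

    def test_predict_shape_checked(self, rng):
        net = build_unet(UNetConfig((32, 32, 1), base_filters=2), seed=0)
        with pytest.raises(ValueError):
            predict(net, rng.uniform(0, 1, (16, 16)))
        assert predict(net, rng.uniform(0, 1, (32, 32))).shape == (32, 32)


def tiny_dataset(rng, n=4, size=32):
    images = rng.uniform(0, 1, (n, size, size))
    masks = np.zeros((n, size, size), dtype=np.uint8)
    for i in range(n):
        r, c = rng.integers(8, 20, 2)
        masks[i, r : r + 6, c : c + 6] = 1
        images[i][masks[i] == 1] += 0.3
    return np.clip(images, 0, 1), masks


class TestTraining:
    def test_smoke_one_epoch(self, rng):
        images, masks = tiny_dataset(rng)
        net = build_unet(UNetConfig((32, 32, 1), base_filters=2), seed=0)
        cfg = TrainConfig(batch_size=2, epochs=1, initial_lr=1e-3,
                          decay_steps=100, loss=L.LossSpec("fgd_bcel"), seed=0)
        hist = train(net, (images, masks), cfg)
        assert len(hist["train_loss"]) == 1
        assert np.isfinite(hist["train_loss"]).all()

    def test_loss_decreases_on_learnable_toy_set(self, rng):
        images, masks = tiny_dataset(rng, n=8)
        net = build_unet(UNetConfig((32, 32, 1), base_filters=4), seed=0)
        cfg = TrainConfig(batch_size=2, epochs=20, initial_lr=2e-3,
                          decay_steps=200, loss=L.LossSpec("fgd_bcel"), seed=0)
        hist = train(net, (images, masks), cfg)
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_fgd_bcel_alpha1_beta0_run_identical_to_gdl_run(self, rng):
        images, masks = tiny_dataset(rng)
        histories = []
        finals = []
        for spec in (
            L.LossSpec("fgd_bcel", L.FGDBCELParams(alpha=1.0, beta=0.0)),
            L.LossSpec("gdl"),
        ):
            net = build_unet(UNetConfig((32, 32, 1), base_filters=2), seed=3)
            cfg = TrainConfig(batch_size=2, epochs=2, initial_lr=1e-3,
                              decay_steps=100, loss=spec, seed=3)
            histories.append(train(net, (images, masks), cfg))
            finals.append(net.state_dict())
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        for k in finals[0]:
            assert np.array_equal(finals[0][k], finals[1][k])

    def test_divergence_reported_with_batch(self, rng, monkeypatch):
        images, masks = tiny_dataset(rng)
        net = build_unet(UNetConfig((32, 32, 1), base_filters=2), seed=0)
        cfg = TrainConfig(batch_size=2, epochs=1, initial_lr=1e-3,
                          decay_steps=100, loss=L.LossSpec("dl"), seed=0)
        monkeypatch.setattr(
            "lobeseg.model._batch_loss",
            lambda *a, **k: Tensor(np.array(np.nan)),
        )
        with pytest.raises(TrainingDiverged, match="epoch 0"):
            train(net, (images, masks), cfg)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net = build_unet(UNetConfig((32, 32, 1), base_filters=2), seed=1)
        save_model(net, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        x = rng.uniform(0, 1, (32, 32))
        assert np.array_equal(predict(net, x), predict(loaded, x))
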