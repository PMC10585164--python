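"""Tests of the five-metric suite: counting oracles, algebraic identities,
and exact agreement between the KD-tree Hausdorff and the all-pairs
brute force."""

import numpy as np
import pytest

from lobeseg import metrics as M


def random_mask(rng, shape=(12, 12), fg=0.3):
    return (rng.random(shape) < fg).astype(np.uint8)


class TestConfusion:
    def test_identical_masks(self):
        truth = np.zeros((4, 4), dtype=np.uint8)
        truth[:2, :2] = 1
        c = M.confusion(truth, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 12)

    def test_all_background_prediction(self, rng):
        truth = random_mask(rng)
        c = M.confusion(np.zeros_like(truth), truth)
        assert c.tp == 0 and c.fn == truth.sum()

    def test_partial_overlap_counts(self):
        pred = np.zeros((4, 4), dtype=np.uint8)
        truth = np.zeros((4, 4), dtype=np.uint8)
        pred[0, :4] = 1  # 4 px
        truth[0, 2:4] = truth[1, 0] = truth[1, 1] = 1  # 4 px, 2 shared
        c = M.confusion(pred, truth)
        assert (c.tp, c.fp, c.fn) == (2, 2, 2)
        assert c.total == 16

    def test_soft_mask_rejected(self):
        with pytest.raises(ValueError, match="crisp"):
            M.confusion(np.full((2, 2), 0.5), np.zeros((2, 2)))


class TestOverlapMetrics:
    def test_perfect_prediction(self, rng):
        truth = random_mask(rng)
        truth[0, 0] = 1
        for fn in (M.dsc, M.jsc, M.ppv, M.sensitivity):
            assert fn(truth, truth) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert M.dsc(a, b) == 0.0 and M.jsc(a, b) == 0.0

    def test_counting_oracle_case(self):
        # |X|=4, |Y|=4, |X∩Y|=2
        pred = np.zeros((4, 4), dtype=np.uint8)
        truth = np.zeros((4, 4), dtype=np.uint8)
        pred[0] = 1
        truth[0, 2:] = truth[1, :2] = 1
        assert M.dsc(pred, truth) == pytest.approx(0.5)
        assert M.jsc(pred, truth) == pytest.approx(1.0 / 3.0)
        assert M.ppv(pred, truth) == pytest.approx(0.5)
        assert M.sensitivity(pred, truth) == pytest.approx(0.5)

    def test_both_empty_policy(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        assert M.dsc(z, z) == 1.0
        assert M.dsc(z, z, both_empty_value=0.0) == 0.0
        assert M.jsc(z, z) == 1.0

    @pytest.mark.parametrize("n", [200])
    def test_algebraic_identities(self, rng, n):
        """DSC = 2 JSC/(1+JSC) and DSC = 2 PPV*SE/(PPV+SE) exactly."""
        checked = 0
        while checked < n:
            pred = random_mask(rng, fg=rng.uniform(0.1, 0.6))
            truth = random_mask(rng, fg=rng.uniform(0.1, 0.6))
            c = M.confusion(pred, truth)
            if c.tp == 0:  # identities degenerate without overlap
                continue
            d, j = M.dsc(pred, truth), M.jsc(pred, truth)
            p, s = M.ppv(pred, truth), M.sensitivity(pred, truth)
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
            assert d == pytest.approx(2 * p * s / (p + s), abs=1e-12)
            checked += 1

    def test_symmetry_and_ppv_se_duality(self, rng):
        for _ in range(50):
            a, b = random_mask(rng), random_mask(rng)
            assert M.dsc(a, b) == M.dsc(b, a)
            assert M.jsc(a, b) == M.jsc(b, a)
            assert M.ppv(a, b) == M.sensitivity(b, a)


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        m[0, 0] = 1
        assert M.hausdorff(m, m) == 0.0

    def test_single_pixel_pair_is_euclidean(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert M.hausdorff(a, b) == pytest.approx(5.0)
        assert M.hausdorff_bruteforce(a, b) == pytest.approx(5.0)

    def test_asymmetry_resolved_by_max(self):
        a = np.zeros((4, 8), dtype=np.uint8)
        b = np.zeros((4, 8), dtype=np.uint8)
        a[0, 0] = a[0, 3] = 1
        b[0, 0] = 1
        assert M.hausdorff(a, b) == pytest.approx(3.0)
        assert M.hausdorff(b, a) == pytest.approx(3.0)  # symmetric

    def test_spacing_scales_distances(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[0, 2] = 1
        assert M.hausdorff(a, b, spacing=(1.0, 0.5)) == pytest.approx(1.0)
        assert M.hausdorff(a, b, spacing=(2.0, 2.0)) == pytest.approx(4.0)

    def test_empty_mask_error_names_side(self):
        m = np.zeros((3, 3), dtype=np.uint8)
        full = np.ones((3, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="predicted"):
            M.hausdorff(m, full)
        with pytest.raises(ValueError, match="reference"):
            M.hausdorff(full, m)

    @pytest.mark.parametrize("n", [200])
    def test_fast_equals_bruteforce(self, rng, n):
        for _ in range(n):
            shape = (int(rng.integers(4, 12)), int(rng.integers(4, 12)))
            a = random_mask(rng, shape, fg=rng.uniform(0.1, 0.7))
            b = random_mask(rng, shape, fg=rng.uniform(0.1, 0.7))
            if not a.any() or not b.any():
                continue
            sp = (float(rng.uniform(0.5, 3)), float(rng.uniform(0.5, 3)))
            assert M.hausdorff(a, b, sp) == M.hausdorff_bruteforce(a, b, sp)

    def test_boundary_only_variant_runs(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[2:8, 2:8] = 1
        assert M.hausdorff(m, m, boundary_only=True) == 0.0


class TestTranslationInvariance:
    def test_all_metrics_shift_invariant(self, rng):
        a = np.zeros((16, 16), dtype=np.uint8)
        b = np.zeros((16, 16), dtype=np.uint8)
        a[4:7, 4:8] = 1
        b[5:8, 3:7] = 1
        shifted = lambda m: np.roll(m, (3, 2), axis=(0, 1))
        for fn in (M.dsc, M.jsc, M.ppv, M.sensitivity, M.hausdorff):
            assert fn(a, b) == pytest.approx(fn(shifted(a), shifted(b)))


class TestAggregation:
    def test_single_slice_sd_zero(self):
        rep = M.aggregate([{"dsc": 0.9, "jsc": 0.8, "ppv": 0.9, "se": 0.95, "hd": 2.0}])
        assert rep.sd["dsc"] == 0.0 and rep.mean["dsc"] == 0.9

    def test_two_values_mean(self):
        recs = [
            {"dsc": 0.8, "jsc": 0.7, "ppv": 0.8, "se": 0.8, "hd": 1.0},
            {"dsc": 0.9, "jsc": 0.8, "ppv": 0.9, "se": 0.9, "hd": 3.0},
        ]
        rep = M.aggregate(recs)
        assert rep.mean["dsc"] == pytest.approx(0.85)

    def test_matches_two_pass_oracle(self, rng):
        recs = []
        for _ in range(100):
            recs.append({m: float(rng.uniform(0, 1)) for m in M.METRIC_COLUMNS})
        rep = M.aggregate(recs)
        for m in M.METRIC_COLUMNS:
            vals = np.array([r[m] for r in recs])
            mean = vals.sum() / len(vals)
            sd = np.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1))
            assert rep.mean[m] == pytest.approx(mean, abs=1e-12)
            assert rep.sd[m] == pytest.approx(sd, abs=1e-12)

    def test_nan_hd_excluded_from_mean(self):
        recs = [
            {"dsc": 1, "jsc": 1, "ppv": 1, "se": 1, "hd": 2.0},
            {"dsc": 1, "jsc": 1, "ppv": 1, "se": 1, "hd": float("nan")},
        ]
        rep = M.aggregate(recs)
        assert rep.mean["hd"] == pytest.approx(2.0)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            M.aggregate([])


class TestEvaluatePair:
    def test_hd_flagged_undefined_on_empty_prediction(self, rng):
        truth = random_mask(rng)
        truth[0, 0] = 1
        rec = M.evaluate_pair(np.zeros_like(truth), truth)
        assert not rec["hd_defined"] and np.isnan(rec["hd"])
        assert rec["se"] == 0.0

    def test_summary_row_formatting(self):
        rep = M.aggregate(
            [
                {"dsc": 0.876543, "jsc": 0.7, "ppv": 0.9, "se": 0.9, "hd": 4.0},
                {"dsc": 0.876543 + 0.1, "jsc": 0.7, "ppv": 0.9, "se": 0.9, "hd": 4.2},
            ]
        )
        row = rep.summary_row()
        assert row["dsc"] == "0.93 ± 0.07"
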