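"""Overlap-index pipeline vs independent per-pixel and flood-fill oracles."""

import numpy as np
import pytest
from conftest import flood_fill_components

from mamquant.colocalization import (
    OverlapIndexResult,
    batch_otsu_threshold,
    binarize_and_filter,
    overlap_index,
    overlap_pixels,
    pearson_colocalization,
    preprocess_batch,
    preprocess_channel,
    triple_overlap,
)
from mamquant.datatypes import OverlapMeasurement


class TestPreprocess:
    def test_constant_image_stays_constant(self):
        out = preprocess_channel(np.full((16, 16), 7.0), stretch=(0, 100))
        assert np.ptp(out) == 0

    def test_two_valued_image_maps_to_endpoints(self):
        img = np.zeros((10, 10))
        img[::2] = 100.0
        out = preprocess_channel(img, stretch=(0, 100))
        assert set(np.unique(out)) == {0.0, 1.0}

    def test_random_image_spans_unit_interval(self, rng):
        out = preprocess_channel(rng.uniform(3, 9, (64, 64)), stretch=(0, 100))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ValueError):
            preprocess_channel(np.ones((4, 4)), stretch=(50, 40))

    def test_batch_refuses_non_uniform_parameters(self):
        imgs = [np.ones((8, 8)), np.ones((8, 8))]
        with pytest.raises(ValueError, match="identical"):
            preprocess_batch(imgs, per_image_params=[{"stretch": (0, 100)}, {"stretch": (1, 99)}])

    def test_batch_uniform_parameters_accepted(self):
        out = preprocess_batch([np.eye(8), np.eye(8)], stretch=(0, 100))
        assert len(out) == 2


class TestBinarizeAndFilter:
    def test_small_puncta_removal_boundary(self):
        # components of 5, 10 and 23 px: only 10 and 23 survive
        img = np.zeros((40, 40))
        img[1, 1:6] = 1.0            # 5 px -> removed
        img[10, 10:20] = 1.0         # 10 px -> kept (exactly at the limit)
        img[25:28, 25:33] = 1.0      # 24 px block
        img[25, 25] = 0.0            # ... minus 1 -> 23 px -> kept
        lm = binarize_and_filter(img, threshold=0.5, min_size=10)
        sizes = sorted(len(c) for c in flood_fill_components(lm.mask))
        assert sizes == [10, 23]
        assert lm.n_objects == 2

    def test_all_background_empty_mask(self):
        lm = binarize_and_filter(np.zeros((16, 16)), threshold=0.5)
        assert lm.n_objects == 0 and not lm.mask.any()

    def test_filter_matches_flood_fill_census(self, rng):
        for _ in range(20):
            img = (rng.random((64, 64)) < 0.25).astype(float)
            lm = binarize_and_filter(img, threshold=0.5, min_size=10)
            surviving = {
                frozenset(c) for c in flood_fill_components(img > 0.5) if len(c) >= 10
            }
            assert {frozenset(c) for c in flood_fill_components(lm.mask)} == surviving

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_and_filter(np.ones((8, 8)), threshold=1.5)

    def test_batch_otsu_separates_bimodal(self):
        imgs = [np.concatenate([np.zeros(500), np.ones(500)]).reshape(25, 40)] * 3
        thr = batch_otsu_threshold(imgs)
        assert 0.0 < thr <= 1.0


class TestOverlapPixels:
    def test_identical_masks(self):
        m = np.eye(8, dtype=bool)
        res = overlap_pixels(m, m)
        assert res.overlap_pixels == res.pixels_a == res.pixels_b == 8

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0], b[4] = True, True
        assert overlap_pixels(a, b).overlap_pixels == 0

    def test_matches_per_pixel_conjunction_oracle(self, rng):
        for _ in range(30):
            a = rng.random((64, 64)) < 0.3
            b = rng.random((64, 64)) < 0.3
            expected = sum(
                1 for r in range(64) for c in range(64) if a[r, c] and b[r, c]
            )
            assert overlap_pixels(a, b).overlap_pixels == expected

    def test_dilation_never_decreases_overlap(self, rng):
        for _ in range(10):
            a = rng.random((48, 48)) < 0.1
            b = rng.random((48, 48)) < 0.1
            base = overlap_pixels(a, b).overlap_pixels
            grown = overlap_pixels(a, b, dilate=1).overlap_pixels
            assert grown >= base

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_pixels(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestTripleOverlap:
    def test_full_third_mask_reduces_to_pairwise(self, rng):
        a = rng.random((32, 32)) < 0.4
        b = rng.random((32, 32)) < 0.4
        full = np.ones((32, 32), bool)
        assert triple_overlap(a, b, full).overlap_pixels == overlap_pixels(a, b).overlap_pixels

    def test_any_empty_mask_gives_zero(self, rng):
        a = rng.random((32, 32)) < 0.5
        empty = np.zeros((32, 32), bool)
        assert triple_overlap(a, a, empty).overlap_pixels == 0

    def test_matches_triple_conjunction_oracle(self, rng):
        for _ in range(10):
            masks = [rng.random((32, 32)) < 0.5 for _ in range(3)]
            expected = sum(
                1
                for r in range(32)
                for c in range(32)
                if masks[0][r, c] and masks[1][r, c] and masks[2][r, c]
            )
            assert triple_overlap(*masks).overlap_pixels == expected


class TestOverlapIndex:
    @staticmethod
    def _meas(sample, group, overlap):
        return OverlapMeasurement(
            pixels_a=overlap + 5, pixels_b=overlap + 9, overlap_pixels=overlap,
            sample_id=sample, group=group,
        )

    def test_identical_samples_all_index_one(self):
        meas = [self._meas(f"s{i}", "control", 40) for i in range(4)]
        res = overlap_index(meas, "control")
        assert all(v == 1.0 for v in res.indices.values())

    def test_fold_change_against_control_mean(self):
        meas = [
            self._meas("c1", "control", 10),
            self._meas("c2", "control", 20),
            self._meas("t1", "stress", 30),
        ]
        res = overlap_index(meas, "control")
        assert res.indices["t1"] == pytest.approx(2.0)   # 30 / mean(10, 20)

    def test_control_group_mean_is_one_exactly(self, rng):
        meas = [
            self._meas(f"c{i}", "control", int(v))
            for i, v in enumerate(rng.integers(5, 200, 7))
        ] + [self._meas("t", "stress", 77)]
        res = overlap_index(meas, "control")
        assert res.group_mean["control"] == pytest.approx(1.0, abs=1e-12)

    def test_singleton_group_sem_absent(self):
        res = overlap_index([self._meas("c", "control", 10)], "control")
        assert isinstance(res, OverlapIndexResult)
        assert res.group_sem["control"] is None

    def test_zero_control_mean_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            overlap_index([self._meas("c", "control", 0)], "control")

    def test_missing_control_group_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_index([self._meas("t", "stress", 5)], "control")


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        a = rng.random((32, 32))
        value, _ = pearson_colocalization(a, a)
        assert value == pytest.approx(1.0, abs=1e-12)

    def test_affine_negation_is_minus_one(self, rng):
        a = rng.random((32, 32))
        value, _ = pearson_colocalization(a, a.max() - a)
        assert value == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_formula_oracle(self, rng):
        for _ in range(20):
            a = rng.random((24, 24))
            b = rng.random((24, 24))
            x, y = a.ravel(), b.ravel()
            expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
            value, _ = pearson_colocalization(a, b)
            assert value == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_reported_absent(self):
        value, reason = pearson_colocalization(np.ones((8, 8)), np.eye(8))
        assert value is None and "variance" in reason

    def test_roi_restricts_computation(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        roi = np.zeros((16, 16), bool)
        roi[:4] = True
        value, _ = pearson_colocalization(a, b, roi=roi)
        expected, _ = pearson_colocalization(a[:4], b[:4])
        assert value == pytest.approx(expected, abs=1e-12)
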