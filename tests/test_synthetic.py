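"""Generator ground-truth consistency, determinism, and closed-form checks."""

import math

import numpy as np
import pytest

from mamquant.synthetic import (
    NoiseModel,
    ParameterError,
    PlateGroundTruth,
    generate_atp_plate,
    generate_calcium_traces,
    generate_capsule_image,
    generate_cell_image,
    generate_flow_populations,
    generate_gene_table,
    generate_reporter_image,
    round_half_away_from_zero,
)


class TestCellImage:
    def test_empty_scene_gives_blank_channels(self):
        img, truth = generate_cell_image(
            n_tubules=0, n_contact_capsules=0, n_free_capsules=0, n_puncta=0, seed=1
        )
        assert all(np.all(ch == 0) for ch in img.channels.values())
        assert not truth.er_mask.any() and not truth.mito_mask.any()
        assert not truth.contact_mask.any()

    def test_noiseless_foreground_equals_ground_truth_masks(self):
        img, truth = generate_cell_image(seed=3)
        np.testing.assert_array_equal(img.channels["er"] > 0, truth.er_mask)
        np.testing.assert_array_equal(img.channels["mito"] > 0, truth.mito_mask)
        # rendered at the stated intensities exactly
        assert set(np.unique(img.channels["er"])) <= {0.0, 0.8}

    def test_contact_mask_follows_dilation_rule(self):
        from skimage.morphology import dilation, disk

        img, truth = generate_cell_image(seed=5, contact_dilation=1)
        expected = dilation(truth.er_mask, disk(1)) & dilation(truth.mito_mask, disk(1))
        np.testing.assert_array_equal(truth.contact_mask, expected)

    def test_at_contact_puncta_lie_inside_contact_mask(self):
        _, truth = generate_cell_image(seed=7)
        at_contact = [p for p in truth.protein_puncta if p[3]]
        assert at_contact, "expected some contact-enriched puncta"
        for r, c, _rad, _ in at_contact:
            assert truth.contact_mask[r, c]

    def test_fixed_seed_is_bit_identical(self):
        a, _ = generate_cell_image(seed=42, noise_model=NoiseModel(gaussian_sd=0.1))
        b, _ = generate_cell_image(seed=42, noise_model=NoiseModel(gaussian_sd=0.1))
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_rejects_bad_parameters(self):
        with pytest.raises(ParameterError):
            generate_cell_image(shape=(32, 32))
        with pytest.raises(ParameterError):
            NoiseModel(gaussian_sd=-0.1)


class TestCapsuleImage:
    def test_single_horizontal_capsule_true_length(self):
        # 20 px endpoint separation at 0.1 um/px -> 2.0 um recorded
        img, truth = generate_capsule_image(
            n_capsules=1, length_um=np.array([2.0]), pixel_size=0.1, seed=1
        )
        assert truth.lengths_um[0] == pytest.approx(2.0, abs=0.15)
        r0, c0, r1, c1, _w, _l = truth.capsules[0]
        assert math.hypot(r1 - r0, c1 - c0) == pytest.approx(20, abs=1.5)

    def test_zero_capsules_blank_image(self):
        img, truth = generate_capsule_image(n_capsules=0, seed=1)
        assert not img.channels["mito"].any()
        assert truth.capsules == []

    def test_seed_reproducible_layout(self):
        a, ta = generate_capsule_image(n_capsules=10, seed=9)
        b, tb = generate_capsule_image(n_capsules=10, seed=9)
        np.testing.assert_array_equal(a.channels["mito"], b.channels["mito"])
        assert ta.capsules == tb.capsules

    def test_capsules_do_not_touch(self, ):
        from conftest import flood_fill_components

        img, truth = generate_capsule_image(n_capsules=15, shape=(400, 400), seed=2)
        comps = flood_fill_components(img.channels["mito"] > 0)
        assert len(comps) == 15

    def test_width_below_three_rejected(self):
        with pytest.raises(ParameterError):
            generate_capsule_image(width_px=2)


class TestReporterImage:
    @pytest.mark.parametrize(
        "n,f,expected", [(10, 0.3, 3), (10, 0.0, 0), (10, 1.0, 10), (7, 0.5, 4)]
    )
    def test_red_only_count_rounding_rule(self, n, f, expected):
        _, truth = generate_reporter_image(n_puncta=n, red_only_fraction=f, seed=4)
        assert sum(t[2] for t in truth) == expected

    def test_fraction_one_means_green_only_background(self):
        img, _ = generate_reporter_image(n_puncta=8, red_only_fraction=1.0, seed=4)
        assert np.all(img.channels["green"] == 0.05)

    def test_red_only_puncta_green_at_background(self):
        img, truth = generate_reporter_image(n_puncta=12, red_only_fraction=0.5, seed=6)
        for r, c, red_only in truth:
            if red_only:
                assert img.channels["green"][r, c] == 0.05
            else:
                assert img.channels["green"][r, c] > 0.05

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            generate_reporter_image(n_puncta=5, red_only_fraction=1.5)

    def test_round_half_away_from_zero(self):
        assert round_half_away_from_zero(2.5) == 3
        assert round_half_away_from_zero(3.5) == 4
        assert round_half_away_from_zero(2.4) == 2


class TestCalciumTraces:
    def test_rate_zero_gives_constant_indicator(self):
        pair = generate_calcium_traces(rate_constant=0.0, noise_sd=0.0, seed=1)
        assert np.ptp(pair.indicator) == 0

    def test_shared_bleach_cancels_in_ratio(self):
        pair = generate_calcium_traces(
            rate_constant=0.0, bleach_rate=0.02, noise_sd=0.0, seed=1
        )
        ratio = pair.indicator / pair.reference
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_efflux_closed_form_exp_minus_one(self):
        # k = 0.01 /s at t = 100 s: I(100)/I(0) = exp(-1)
        pair = generate_calcium_traces(
            direction="efflux", rate_constant=0.01, amplitude=100.0,
            n_timepoints=101, dt=1.0, noise_sd=0.0, seed=1,
        )
        assert pair.indicator[100] / pair.indicator[0] == pytest.approx(math.exp(-1), rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            generate_calcium_traces(rate_constant=-0.1)


class TestAtpPlate:
    def test_zero_dependence_all_means_equal_baseline(self):
        plate = generate_atp_plate(PlateGroundTruth(0.0, 0.0, 1000.0, cv=0.0))
        assert all(plate.condition_mean(c) == 1000.0 for c in plate.replicates)

    def test_dg_mean_matches_generative_rule(self):
        # glucose dependence 0.6, B = 1000, cv = 0 -> DG mean 400
        plate = generate_atp_plate(PlateGroundTruth(0.6, 0.3, 1000.0, cv=0.0))
        assert plate.condition_mean("DG") == pytest.approx(400.0)
        assert plate.condition_mean("DGOA") == pytest.approx(1000.0 * 0.4 * 0.7)

    def test_cv_zero_replicates_identical(self):
        plate = generate_atp_plate(PlateGroundTruth(0.4, 0.5, cv=0.0, n_replicates=4))
        for values in plate.replicates.values():
            assert np.ptp(values) == 0

    def test_noise_is_mean_preserving(self):
        truth = PlateGroundTruth(0.4, 0.5, 1000.0, cv=0.1, n_replicates=20000, seed=3)
        plate = generate_atp_plate(truth)
        assert plate.condition_mean("control") == pytest.approx(1000.0, rel=0.01)


class TestGeneTable:
    def test_row_count(self):
        table, _, truth = generate_gene_table(1000, 25, 15, seed=1)
        assert len(table) == 1040 and len(truth) == 1040

    def test_no_spikes_means_all_null(self):
        _, _, truth = generate_gene_table(50, 0, 0, n_mito_genes=10, seed=1)
        assert set(truth) == {"null"}

    def test_seed_reproducible(self):
        a, la, _ = generate_gene_table(seed=11)
        b, lb, _ = generate_gene_table(seed=11)
        assert a.equals(b) and la == lb

    def test_mito_list_larger_than_universe_rejected(self):
        with pytest.raises(ParameterError):
            generate_gene_table(10, 0, 0, n_mito_genes=11)


class TestFlowPopulations:
    def test_log_sd_zero_all_events_equal(self):
        events = generate_flow_populations(50, {"tmrm": 2.0}, 0.0, seed=1)
        np.testing.assert_allclose(events["tmrm"], math.exp(2.0))

    def test_row_count_and_determinism(self):
        a = generate_flow_populations(5, {"x": 1.0}, 0.5, seed=3)
        b = generate_flow_populations(5, {"x": 1.0}, 0.5, seed=3)
        assert len(a) == 5 and a.equals(b)

    def test_negative_log_sd_rejected(self):
        with pytest.raises(ParameterError):
            generate_flow_populations(5, {"x": 1.0}, -0.5)
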