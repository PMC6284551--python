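"""OD calibration, band quantification, exposure combination, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereoplacenta import (
    calibrate_od,
    combine_exposures,
    make_step_tablet,
    measure_region_od,
    normalize_expression,
    quantify_band,
    synth_blot_fixture,
)


class TestCalibration:
    def test_midpoint_interpolation(self):
        cal = calibrate_od([(255, 0.0), (128, 0.3), (64, 0.6)])
        assert cal(96) == pytest.approx(0.45, rel=1e-9)
        assert cal(255) == 0.0

    def test_anchors_round_trip_exactly(self):
        _, pairs = make_step_tablet()
        cal = calibrate_od(pairs)
        for g, od in pairs:
            assert cal(g) == pytest.approx(od, abs=1e-12)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            calibrate_od([(255, 0.0), (128, 0.3), (200, 0.4)])

    def test_out_of_range_clamps_with_warning(self):
        cal = calibrate_od([(100, 0.5), (200, 0.1)])
        with pytest.warns(UserWarning, match="clamp"):
            assert cal(250) == pytest.approx(0.1)

    def test_synthetic_tablet_recovery_within_interpolation_bound(self):
        img, pairs = make_step_tablet()
        cal = calibrate_od(pairs)
        # querying the tablet image itself reproduces the known step ODs
        for i, (g, od) in enumerate(pairs):
            band = img[i * 12:(i + 1) * 12, :]
            assert np.allclose(cal(band), od, atol=1e-9)


class TestRegionOD:
    def test_uniform_anchor_gray_exact(self, rng):
        _, pairs = make_step_tablet()
        cal = calibrate_od(pairs)
        g, od = pairs[4]
        img = np.full((64, 64), g, dtype=float)
        res = measure_region_od(img, cal, np.ones_like(img, dtype=bool),
                                rng=rng)
        assert res.mean_od == pytest.approx(od, abs=1e-12)
        assert len(res.field_ods) == 10

    def test_two_level_image_averages(self):
        cal = calibrate_od([(100, 0.4), (150, 0.2), (255, 0.0)])
        g_02 = 150.0
        g_04 = 100.0
        img = np.zeros((64, 64))
        img[:32] = g_02
        img[32:] = g_04
        means = []
        for seed in range(300):
            res = measure_region_od(img, cal, np.ones_like(img, dtype=bool),
                                    rng=np.random.default_rng(seed))
            means.append(res.mean_od)
        assert np.mean(means) == pytest.approx(0.30, abs=0.01)

    def test_empty_mask_rejected(self, rng):
        cal = calibrate_od([(0, 1.0), (255, 0.0)])
        img = np.zeros((16, 16))
        with pytest.raises(ValueError, match="empty"):
            measure_region_od(img, cal, np.zeros_like(img, dtype=bool),
                              rng=rng)

    def test_tiny_mask_falls_back_with_warning(self, rng):
        cal = calibrate_od([(0, 1.0), (255, 0.0)])
        img = np.zeros((16, 16))
        mask = np.zeros_like(img, dtype=bool)
        mask[3, 3] = True
        with pytest.warns(UserWarning, match="smaller"):
            res = measure_region_od(img, cal, mask, rng=rng)
        assert len(res.field_ods) == 1


class TestBandQuantification:
    def test_flat_zero_trace(self):
        assert quantify_band(np.zeros(50), (10, 20)) == 0.0

    def test_rectangular_pulse_height_times_width(self):
        prof = np.zeros(100)
        prof[40:50] = 3.0
        assert quantify_band(prof, (35, 55)) == pytest.approx(30.0)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="window"):
            quantify_band(np.zeros(10), (5, 20))

    def test_sloped_baseline_removed(self):
        x = np.arange(200, dtype=float)
        baseline = 0.05 * x + 10.0
        prof = baseline.copy()
        prof[90:110] += 7.0
        est = quantify_band(prof, (85, 115))
        assert est == pytest.approx(7.0 * 20, rel=0.15)

    def test_noisy_recovery_within_two_percent(self):
        # gaussian band over flat background, 1% multiplicative noise
        x = np.arange(200, dtype=float)
        band = 50.0 * np.exp(-0.5 * ((x - 100) / 6.0) ** 2)
        truth = band[80:120].sum()
        ratios = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            prof = 20.0 + band * (1 + rng.normal(0, 0.01, size=200))
            ratios.append(quantify_band(prof, (80, 120)) / truth)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)


class TestCombineExposures:
    def test_single_unsaturated_identity(self):
        out = combine_exposures(np.array([[42.0]]), np.array([[False]]))
        assert out[0] == pytest.approx(42.0)

    def test_known_gains_exact_reconciliation(self):
        out = combine_exposures(np.array([[20.0, 40.0]]),
                                np.array([[False, False]]),
                                gains=np.array([2.0, 4.0]))
        assert out[0] == pytest.approx(10.0, rel=1e-12)

    def test_saturated_exposure_excluded(self):
        # lane 0 clipped at high exposure; its estimate must come from the
        # clean exposures only and equal the unclipped value
        I = np.array([[100.0, 150.0], [10.0, 20.0]])
        sat = np.array([[False, True], [False, False]])
        out = combine_exposures(I, sat, gains=np.array([1.0, 2.0]))
        assert out[0] == pytest.approx(100.0)
        assert out[1] == pytest.approx(10.0)

    def test_all_saturated_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            combine_exposures(np.array([[5.0, 6.0]]),
                              np.array([[True, True]]))

    def test_unknown_gains_recovered_across_lanes(self):
        truth = np.array([10.0, 20.0, 5.0, 40.0])
        gains = np.array([1.0, 2.0, 4.0])
        I = truth[:, None] * gains[None, :]
        out = combine_exposures(I, I > 1e9)
        assert np.allclose(out, truth, rtol=1e-6)

    def test_reference_choice_only_rescales(self):
        truth = np.array([10.0, 20.0, 5.0])
        gains = np.array([1.0, 2.0])
        I = truth[:, None] * gains[None, :]
        sat = np.zeros_like(I, dtype=bool)
        a = combine_exposures(I, sat, reference=0)
        b = combine_exposures(I, sat, reference=1)
        assert np.allclose(b / a, 2.0, rtol=1e-6)

    def test_multi_exposure_noise_recovery(self):
        truth = np.array([100.0, 300.0, 50.0, 900.0, 450.0])
        gains = np.array([1.0, 2.0, 4.0])
        ratios = []
        for seed in range(200):
            df, _, _ = synth_blot_fixture(truth, gains, noise_sd=0.01,
                                          saturation_level=1e7, seed=seed)
            I = df.pivot(index="lane", columns="exposure",
                         values="intensity").to_numpy()
            sat = df.pivot(index="lane", columns="exposure",
                           values="saturated").to_numpy()
            out = combine_exposures(I, sat, gains=gains)
            ratios.append(out / truth)
        assert np.abs(np.mean(ratios) - 1.0) < 0.02


class TestNormalization:
    def test_uniform_control_ratio_relative_one(self):
        df = normalize_expression(np.array([4.0, 4.0, 8.0]),
                                  np.array([2.0, 2.0, 2.0]),
                                  ["N", "N", "H"])
        ctrl = df[df.group == "N"]["relative"]
        assert (ctrl == 1.0).all()
        assert df[df.group == "H"]["relative"].iloc[0] == pytest.approx(2.0)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=6,
                    max_size=24))
    def test_control_mean_exactly_one_for_any_input(self, targets):
        n = len(targets)
        groups = (["N"] * (n // 2)) + (["H"] * (n - n // 2))
        actin = np.linspace(1.0, 3.0, n)
        df = normalize_expression(np.array(targets), actin, groups)
        assert df[df.group == "N"]["relative"].mean() == \
            pytest.approx(1.0, rel=1e-12)

    def test_zero_actin_lane_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="actin"):
            df = normalize_expression(np.array([1.0, 2.0, 3.0]),
                                      np.array([1.0, 0.0, 1.0]),
                                      ["N", "N", "H"])
        assert len(df) == 2

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            normalize_expression(np.array([1.0]), np.array([1.0]), ["H"])
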