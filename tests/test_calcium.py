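import numpy as np
import pytest

from ciliaphys.calcium import (DynamicRangeError, HillFit, MaskWarning,
                               RatioTimeSeries, TwoChannelStack, calibrate,
                               correct_ratio, estimate_bleedthrough, fit_hill,
                               make_cilium_mask, mean_masked_ratio,
                               normalize_timeseries, quantify_basal_calcium,
                               ratio_image, ratio_to_calcium)
from ciliaphys.synthetic import (SimConfig, simulate_bleedthrough_observations,
                                 simulate_calibration_stack)

HILL_TRUTH = HillFit(R_min=0.05, R_max=1.2, EC50_nM=300.0, n_H=2.0)


def _stack(green, red, **kw):
    kw.setdefault("pixel_size_um", 0.1)
    kw.setdefault("frame_interval_s", 1.0)
    return TwoChannelStack(green=green, red=red, **kw)


class TestMask:
    def test_uniform_background_is_empty(self):
        frame = np.full((32, 32), 50.0)
        with pytest.warns(MaskWarning):
            mask = make_cilium_mask(frame, threshold=100.0, saturation_level=65535)
        assert not mask.any()

    def test_saturated_pixel_excluded(self):
        frame = np.full((8, 8), 500.0)
        frame[3, 3] = 65535.0
        mask = make_cilium_mask(frame, 100.0, 65535.0)
        assert not mask[3, 3] and mask.sum() == 63

    def test_matches_generator_footprint(self, cfg):
        stacks, truth = simulate_calibration_stack(HILL_TRUTH, alpha=0.0,
                                                   ca_levels_nm=(300.0,),
                                                   n_stacks_per_level=1,
                                                   cfg=cfg, noiseless=True)
        st = stacks[300.0][0]
        mask = make_cilium_mask(st.red[0], truth["mask_threshold"],
                                st.saturation_level)
        # every masked pixel carries real sensor signal above background
        assert mask.sum() > 100
        assert np.all(st.red[0][mask] >= truth["mask_threshold"])


class TestRatioImage:
    def test_simple_proportional_channels(self):
        red = np.full((1, 16, 16), 500.0)
        frames, dropped = ratio_image(_stack(2.0 * red, red),
                                      np.ones((16, 16), bool), 0.0, 0.0)
        assert dropped == 0
        assert np.allclose(frames, 2.0)

    def test_background_equal_to_signal_drops_all(self):
        red = np.full((1, 8, 8), 200.0)
        with pytest.warns(MaskWarning):
            frames, dropped = ratio_image(_stack(red.copy(), red),
                                          np.ones((8, 8), bool), 0.0, 200.0)
        assert dropped == 64
        assert np.all(np.isnan(frames))

    def test_mean_ratio_independent_of_background_level(self, cfg):
        # correct background estimation removes any offset dependence
        mask = np.ones((16, 16), bool)
        red_signal = np.full((1, 16, 16), 800.0)
        for bg in (0.0, 50.0, 300.0):
            stack = _stack(0.2 * red_signal + bg, red_signal + bg)
            frames, _ = ratio_image(stack, mask, bg, bg)
            assert mean_masked_ratio(frames) == pytest.approx(0.2, rel=1e-6)

    def test_generator_ratio_recovered(self, cfg):
        stacks, truth = simulate_calibration_stack(
            HILL_TRUTH, alpha=0.0, ca_levels_nm=(165.0,), n_stacks_per_level=1,
            cfg=cfg, scan_mode="sequential")
        st = stacks[165.0][0]
        mask = make_cilium_mask(st.red[0], truth["mask_threshold"],
                                st.saturation_level)
        frames, _ = ratio_image(st, mask, truth["background"],
                                truth["background"])
        expected = float(HILL_TRUTH.forward(165.0))
        assert mean_masked_ratio(frames) == pytest.approx(expected, rel=0.05)


class TestBleedthrough:
    def test_exact_line(self):
        g = np.linspace(100, 2000, 10)
        fit = estimate_bleedthrough(g, 0.05 * g)
        assert fit.alpha == pytest.approx(0.05)
        assert fit.r_squared == pytest.approx(1.0)

    def test_zero_leak(self):
        g = np.linspace(100, 2000, 10)
        fit = estimate_bleedthrough(g, np.zeros(10))
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)

    def test_recovery_at_24_points(self, cfg):
        green, leak, truth = simulate_bleedthrough_observations(
            alpha=0.03, n_points=24, cfg=cfg)
        fit = estimate_bleedthrough(green, leak)
        assert fit.n_points == 24
        assert fit.alpha == pytest.approx(0.03, rel=0.10)

    def test_constant_green_rejected(self):
        with pytest.raises(ValueError):
            estimate_bleedthrough(np.full(5, 100.0), np.zeros(5))

    @pytest.mark.parametrize("raw, alpha, expected", [
        (0.25, 0.05, 0.20),
        (0.25, 0.0, 0.25),
        (0.05, 0.05, 0.0),
    ])
    def test_correct_ratio(self, raw, alpha, expected):
        assert correct_ratio(raw, alpha) == pytest.approx(expected)

    def test_correction_commutes_with_averaging(self):
        raws = np.array([0.18, 0.22, 0.25, 0.19])
        assert np.mean(correct_ratio(raws, 0.03)) == pytest.approx(
            correct_ratio(raws.mean(), 0.03))


class TestHillFit:
    LEVELS = np.array([50.0, 100.0, 165.0, 300.0, 1000.0, 3000.0, 10_000.0])

    def test_noiseless_exact_recovery(self):
        y = HILL_TRUTH.forward(self.LEVELS)
        fit = fit_hill(self.LEVELS, y)
        assert fit.R_min == pytest.approx(0.05, abs=1e-4)
        assert fit.R_max == pytest.approx(1.2, abs=1e-4)
        assert fit.EC50_nM == pytest.approx(300.0, rel=1e-3)
        assert fit.n_H == pytest.approx(2.0, rel=1e-3)

    def test_midpoint_property(self):
        assert HILL_TRUTH.forward(300.0) == pytest.approx((0.05 + 1.2) / 2)

    def test_invariant_to_reordering_and_weight_scale(self):
        y = HILL_TRUTH.forward(self.LEVELS) + 0.01 * np.sin(self.LEVELS)
        w = np.array([1.0, 2, 1, 3, 1, 2, 1])
        a = fit_hill(self.LEVELS, y, w)
        perm = np.array([3, 0, 6, 2, 5, 1, 4])
        b = fit_hill(self.LEVELS[perm], y[perm], (10 * w)[perm])
        assert a.EC50_nM == pytest.approx(b.EC50_nM, rel=1e-6)
        assert a.n_H == pytest.approx(b.n_H, rel=1e-6)

    def test_flat_data_rejected(self):
        with pytest.raises(ValueError):
            fit_hill(self.LEVELS, np.full(7, 0.3))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([50, 300, 10_000], [0.1, 0.6, 1.1])


class TestInversion:
    def test_midpoint_maps_to_ec50(self):
        assert ratio_to_calcium((0.05 + 1.2) / 2, HILL_TRUTH) == pytest.approx(300.0)

    @pytest.mark.parametrize("ca", [60.0, 165.0, 300.0, 2000.0])
    def test_round_trip(self, ca):
        assert ratio_to_calcium(float(HILL_TRUTH.forward(ca)),
                                HILL_TRUTH) == pytest.approx(ca, rel=1e-9)

    def test_out_of_range_raises_with_bound(self):
        with pytest.raises(DynamicRangeError, match="floor"):
            ratio_to_calcium(0.04, HILL_TRUTH)
        with pytest.raises(DynamicRangeError, match="ceiling"):
            ratio_to_calcium(1.3, HILL_TRUTH)


class TestNormalize:
    def test_constant_series(self):
        s = RatioTimeSeries(time_s=np.arange(5.0), ratio=np.full(5, 0.2))
        assert np.allclose(normalize_timeseries(s).normalized, 1.0)

    def test_step_series(self):
        s = RatioTimeSeries(time_s=np.arange(4.0),
                            ratio=np.array([0.2, 0.2, 0.6, 0.6]))
        assert np.allclose(normalize_timeseries(s).normalized,
                           [1.0, 1.0, 3.0, 3.0])

    def test_baseline_window_mean_is_one(self):
        rng = np.random.default_rng(3)
        r = 0.2 + 0.01 * rng.normal(size=50)
        s = RatioTimeSeries(time_s=np.arange(50.0), ratio=r)
        out = normalize_timeseries(s, baseline_frames=5)
        assert out.normalized[:5].mean() == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_baseline_rejected(self):
        s = RatioTimeSeries(time_s=np.arange(3.0), ratio=np.zeros(3))
        with pytest.raises(ValueError):
            normalize_timeseries(s)


@pytest.fixture(scope="module")
def calibration():
    cfg = SimConfig(seed=2024)
    stacks, truth = simulate_calibration_stack(HILL_TRUTH, alpha=0.03, cfg=cfg)
    curve = calibrate(stacks, truth["mask_threshold"], truth["background"],
                      truth["background"], alpha=0.03)
    return curve, truth, cfg


class TestEndToEnd:
    """Full pipeline on synthetic stacks: calibration then quantification."""

    def test_sequential_mode_recovers_hill_truth(self):
        # immobilized cilia, no bleed-through: raw-ratio calibration is exact
        cfg = SimConfig(seed=11)
        stacks, truth = simulate_calibration_stack(
            HILL_TRUTH, alpha=0.0, cfg=cfg, scan_mode="sequential")
        curve = calibrate(stacks, truth["mask_threshold"], truth["background"],
                          truth["background"])
        assert curve.hill.EC50_nM == pytest.approx(300.0, rel=0.05)
        assert curve.hill.n_H == pytest.approx(2.0, rel=0.05)
        assert curve.hill.R_max == pytest.approx(1.2, rel=0.05)

    @pytest.mark.parametrize("ca", [100.0, 165.0, 300.0, 1000.0])
    def test_midrange_calcium_within_10pct(self, calibration, ca):
        curve, truth, cfg = calibration
        stacks, t2 = simulate_calibration_stack(HILL_TRUTH, alpha=0.03,
                                                ca_levels_nm=(ca,),
                                                n_stacks_per_level=2, cfg=cfg)
        for st in stacks[ca]:
            _, est = quantify_basal_calcium(st, curve, t2["mask_threshold"],
                                            t2["background"], t2["background"],
                                            alpha=0.03)
            assert est == pytest.approx(ca, rel=0.10)

    def test_low_edge_within_25pct(self, calibration):
        curve, truth, cfg = calibration
        stacks, t2 = simulate_calibration_stack(HILL_TRUTH, alpha=0.03,
                                                ca_levels_nm=(50.0,),
                                                n_stacks_per_level=1, cfg=cfg)
        _, est = quantify_basal_calcium(stacks[50.0][0], curve,
                                        t2["mask_threshold"], t2["background"],
                                        t2["background"], alpha=0.03)
        assert est == pytest.approx(50.0, rel=0.25)

    def test_saturating_level_identified_as_deep_saturation(self, calibration):
        # 10 µM sits within a noise width of R_max: the ratio pins to the
        # ceiling and the inversion either reports deep saturation
        # (well above EC50) or fails loudly out of dynamic range
        curve, truth, cfg = calibration
        stacks, t2 = simulate_calibration_stack(HILL_TRUTH, alpha=0.03,
                                                ca_levels_nm=(10_000.0,),
                                                n_stacks_per_level=1, cfg=cfg)
        try:
            a_c, est = quantify_basal_calcium(
                stacks[10_000.0][0], curve, t2["mask_threshold"],
                t2["background"], t2["background"], alpha=0.03)
        except DynamicRangeError:
            return
        assert a_c >= 0.95 * curve.hill.R_max
        assert est >= 10 * curve.hill.EC50_nM
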