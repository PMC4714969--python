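import numpy as np
import pytest

from ciliaphys import ephys, synthetic
from ciliaphys.circuit import EquivalentCircuit
from ciliaphys.ephys import (ProtocolError, StepProtocol, SweepSet,
                             amplitude_histogram, analyze_capacitive_transient,
                             build_iv, gaussian_noise_bandwidth_ratio,
                             offline_filter, open_point_threshold,
                             open_probability, subtract_leak)
from ciliaphys.synthetic import (CavActivationModel, GatingModel, SimConfig,
                                 simulate_cav_current, simulate_patch_recording,
                                 simulate_single_channel)


def _ladder(steps, t_on=0.02, t_off=0.12):
    return StepProtocol(holding_mV=-80.0, step_mV=tuple(steps), t_on=t_on,
                        t_off=t_off)


def _ohmic_sweepset(resistance_gohm, steps, fs=5000.0, duration=0.2):
    """Sweeps from a pure resistor (relative to holding), I = dV/R."""
    n = int(duration * fs)
    time = np.arange(n) / fs
    prot = _ladder(steps)
    sweeps = np.zeros((len(steps), n))
    inside = (time >= prot.t_on) & (time < prot.t_off)
    for j, dv in enumerate(steps):
        sweeps[j, inside] = dv / resistance_gohm * 1e-3 * 1e3  # mV/GΩ -> pA
    return SweepSet(time=time, sweeps=sweeps, sampling_rate=fs, protocol=prot)


class TestSubtractLeak:
    def test_scale_factor_arithmetic(self):
        # +20 mV test against three -20 mV pulses: scale 1/3, so three
        # identical unit responses cancel a unit test response exactly
        leak = -np.ones((3, 50))
        test = np.ones(50)
        corrected = subtract_leak(test, leak, 20.0, -20.0)
        assert np.allclose(corrected, 0.0)

    def test_linear_circuit_cancels_exactly(self, cfg):
        # any ohmic + capacitive circuit is linear in the step amplitude
        circ = EquivalentCircuit(C_m=20.0, R_series=18.0, R_m=120.0)
        act0 = CavActivationModel(g_max_ns=0.0)
        leak_p = StepProtocol(holding_mV=-80, step_mV=-20.0, t_on=0.02, t_off=0.12)
        test_p = StepProtocol(holding_mV=-80, step_mV=60.0, t_on=0.02, t_off=0.12)
        leak, _ = simulate_cav_current(circ, act0, leak_p, cfg=cfg,
                                       noiseless=True, sampling_rate=5000)
        test, _ = simulate_cav_current(circ, act0, test_p, cfg=cfg,
                                       noiseless=True, sampling_rate=5000)
        corrected = subtract_leak(test.sweeps[0], np.tile(leak.sweeps[0], (3, 1)),
                                  60.0, -20.0)
        assert np.max(np.abs(corrected)) < 1e-9

    def test_recovers_active_current(self, cfg):
        # leak + Cav current minus scaled leak pulses leaves the Cav current
        circ = EquivalentCircuit(C_m=20.0, R_series=0.001, R_m=120.0)
        act = CavActivationModel(g_max_ns=3.0)
        test_p = StepProtocol(holding_mV=-80, step_mV=80.0, t_on=0.02, t_off=0.12)
        leak_p = StepProtocol(holding_mV=-80, step_mV=-20.0, t_on=0.02, t_off=0.12)
        test, truth = simulate_cav_current(circ, act, test_p, cfg=cfg,
                                           noiseless=True, sampling_rate=5000)
        leak, _ = simulate_cav_current(circ, CavActivationModel(g_max_ns=0.0),
                                       leak_p, cfg=cfg, noiseless=True,
                                       sampling_rate=5000)
        corrected = subtract_leak(test.sweeps[0], np.tile(leak.sweeps[0], (3, 1)),
                                  80.0, -20.0)
        # compare with the pure active component: total minus its own leak
        leak_only, _ = simulate_cav_current(circ, CavActivationModel(g_max_ns=0.0),
                                            test_p, cfg=cfg, noiseless=True,
                                            sampling_rate=5000)
        active = test.sweeps[0] - leak_only.sweeps[0]
        assert np.allclose(corrected, active, atol=1e-6)

    def test_protocol_validation(self):
        with pytest.raises(ProtocolError):
            subtract_leak(np.zeros(10), np.zeros((3, 10)), 20.0, 20.0)
        with pytest.raises(ProtocolError):
            subtract_leak(np.zeros(10), np.zeros((2, 10)), 20.0, -20.0)
        with pytest.raises(ValueError):
            subtract_leak(np.zeros(10), np.zeros((3, 8)), 20.0, -20.0)


class TestCapacitiveTransient:
    def test_ideal_circuit_reference(self, cfg, cell_circuit, hyperpol_protocol):
        sweeps, _ = simulate_patch_recording(cell_circuit, hyperpol_protocol,
                                             n_sweeps=1, cfg=cfg, noiseless=True)
        res = analyze_capacitive_transient(sweeps)
        assert res.Q_pC == pytest.approx(0.4, rel=0.02)
        assert res.C_m_pF == pytest.approx(20.0, rel=0.02)
        assert res.tau_ms == pytest.approx(0.36, rel=0.02)
        assert res.R_series_MOhm == pytest.approx(18.0, rel=0.02)

    @pytest.mark.parametrize("c_m", [5.0, 18.5, 30.0])
    @pytest.mark.parametrize("r_s", [10.0, 100.0, 300.0])
    def test_noiseless_recovery_grid(self, cfg, hyperpol_protocol, c_m, r_s):
        circ = EquivalentCircuit(C_m=c_m, R_series=r_s)
        sweeps, _ = simulate_patch_recording(circ, hyperpol_protocol, n_sweeps=1,
                                             cfg=cfg, noiseless=True)
        res = analyze_capacitive_transient(sweeps)
        assert res.C_m_pF == pytest.approx(c_m, rel=0.02)
        assert res.R_series_MOhm == pytest.approx(r_s, rel=0.02)

    @pytest.mark.parametrize("c_m, r_s", [(5.0, 10.0), (18.5, 180.0),
                                          (30.0, 300.0)])
    def test_noisy_recovery(self, hyperpol_protocol, c_m, r_s):
        # default 1 pA RMS noise, averaged over 150 sweeps as in practice
        circ = EquivalentCircuit(C_m=c_m, R_series=r_s)
        sweeps, _ = simulate_patch_recording(circ, hyperpol_protocol,
                                             n_sweeps=150,
                                             cfg=SimConfig(seed=77))
        res = analyze_capacitive_transient(sweeps, n_average=150)
        assert res.C_m_pF == pytest.approx(c_m, rel=0.10)
        assert res.R_series_MOhm == pytest.approx(r_s, rel=0.10)

    def test_charge_equals_c_dv_via_ode_oracle(self, cfg, hyperpol_protocol):
        # brute-force integration of the circuit ODE gives the same charge
        circ = EquivalentCircuit(C_m=12.0, R_series=50.0)
        fs = 50_000.0
        n = int(0.1 * fs)
        time = np.arange(n) / fs
        trace = synthetic.integrate_circuit_ode(circ, hyperpol_protocol, time,
                                                -20.0, n_substeps=40)
        i_on = int(hyperpol_protocol.t_on * fs)
        i_off = int(hyperpol_protocol.t_off * fs)
        q = abs(np.trapezoid(trace[i_on:i_off], time[i_on:i_off]))
        assert q == pytest.approx(12.0 * 20.0 * 1e-3, rel=1e-3)  # C·ΔV in pC

    def test_zero_amplitude_flags_degenerate(self, hyperpol_protocol):
        fs = 50_000.0
        n = int(0.1 * fs)
        sweeps = SweepSet(time=np.arange(n) / fs, sweeps=np.zeros((1, n)),
                          sampling_rate=fs, protocol=hyperpol_protocol)
        res = analyze_capacitive_transient(sweeps)
        assert res.degenerate
        assert res.Q_pC == 0.0 and res.C_m_pF == 0.0


class TestIVCurve:
    def test_ohmic_line(self):
        steps = list(range(-20, 101, 20))  # command -100..+20 relative -80
        recs = [_ohmic_sweepset(10.0, steps)]  # 10 GΩ seal
        iv = build_iv(recs, mode="steady_state")
        slope = np.polyfit(iv.voltages_mV, iv.currents_pA, 1)[0]
        assert slope == pytest.approx(0.1, rel=1e-6)  # pA/mV through origin
        assert np.all(iv.sem_pA == 0.0) and iv.n == 1

    def test_peak_iv_minimum_at_conductance_peak(self, cfg):
        circ = EquivalentCircuit(C_m=20.0, R_series=0.001, R_m=1e6)
        act = CavActivationModel(g_max_ns=3.0, v_half_mv=-10.0, slope_mv=7.0,
                                 e_rev_mv=60.0)
        prot = _ladder(range(-40, 121, 10))
        sw, _ = simulate_cav_current(circ, act, prot, cfg=cfg, noiseless=True,
                                     sampling_rate=5000)
        iv = build_iv([sw], mode="peak")
        v_min = iv.voltages_mV[np.argmin(iv.currents_pA)]
        # analytic minimum of g_inf(V)(V - E_rev)
        v_grid = np.linspace(-120, 60, 1000)
        analytic = act.g_inf(v_grid) * (v_grid - act.e_rev_mv)
        assert abs(v_min - v_grid[np.argmin(analytic)]) <= 10.0  # ladder spacing

    def test_mismatched_ladders_rejected(self):
        a = _ohmic_sweepset(10.0, [-20, 0, 20])
        b = _ohmic_sweepset(10.0, [-20, 0, 40])
        with pytest.raises(ProtocolError):
            build_iv([a, b])


class TestOfflineFilter:
    def test_dc_gain_unity(self):
        x = np.full(2000, 3.7)
        assert np.allclose(offline_filter(x, 1000.0, 20_000.0), 3.7)

    def test_impulse_response_unit_area(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        y = offline_filter(x, 1000.0, 20_000.0)
        assert y.sum() == pytest.approx(1.0, rel=1e-6)
        assert y.max() < 1.0  # spread out

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200_000)
        y = offline_filter(x, 1000.0, 20_000.0)
        expected = gaussian_noise_bandwidth_ratio(1000.0, 20_000.0)
        assert y.var() == pytest.approx(expected, rel=0.05)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            offline_filter(np.zeros(100), 11_000.0, 20_000.0)


class TestAmplitudeHistogram:
    def test_open_point_threshold_convention(self):
        assert open_point_threshold(1.4, 0.9) == pytest.approx(1.26)

    def test_no_openings_gives_empty_open_histogram(self):
        trace = np.zeros(1000)
        h = amplitude_histogram(trace, mode="open_point", full_amplitude_pa=1.4)
        assert h.counts.sum() == 0

    def test_two_level_trace_is_bimodal(self, cfg):
        gating = GatingModel.from_p_open(0.3, i_single_pa=1.4)
        sweeps, _ = simulate_single_channel(gating, 400.0, 9, cfg)
        h = amplitude_histogram(sweeps.sweeps, bin_width_pa=0.05)
        centers, counts = h.bin_centers_pA, h.counts
        closed_mode = centers[np.argmax(counts * (centers < 0.7))]
        open_mode = centers[np.argmax(counts * (centers >= 0.7))]
        assert abs(closed_mode - 0.0) <= 0.1
        assert abs(open_mode - 1.4) <= 0.1

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            amplitude_histogram(np.zeros(10), bin_width_pa=0.0)


class TestOpenProbability:
    def test_constant_levels(self):
        fs = 20_000.0
        n = int(0.4 * fs)
        prot = StepProtocol(holding_mV=-80, step_mV=80.0, t_on=0.0, t_off=0.4)
        time = np.arange(n) / fs
        full = SweepSet(time=time, sweeps=np.full((1, n), 1.4),
                        sampling_rate=fs, protocol=prot)
        empty = SweepSet(time=time, sweeps=np.zeros((1, n)),
                         sampling_rate=fs, protocol=prot)
        assert open_probability(full, 1.4) == pytest.approx(1.0)
        assert open_probability(empty, 1.4) == 0.0

    def test_markov_recovery_nine_sweeps(self, cfg):
        gating = GatingModel.from_p_open(0.32)
        sweeps, _ = simulate_single_channel(gating, 400.0, 9, cfg)
        per_sweep = sweeps.sweeps.mean(axis=1) / 1.4
        se = per_sweep.std(ddof=1) / np.sqrt(len(per_sweep))
        p_o = open_probability(sweeps, 1.4)
        assert abs(p_o - 0.32) <= 3 * se

    def test_law_of_large_numbers(self):
        # many sweeps shrink the error far below the 9-sweep scatter
        gating = GatingModel.from_p_open(0.32)
        sweeps, _ = simulate_single_channel(gating, 400.0, 400,
                                            SimConfig(seed=9), noiseless=True)
        p_o = open_probability(sweeps, 1.4)
        assert p_o == pytest.approx(0.32, abs=0.02)
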