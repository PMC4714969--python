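"""Synthetic data generators with recorded ground truth.

Every input the analysis modules consume can be generated here with known
truth, so the whole pipeline is testable without raw recordings:

* patch-clamp sweeps from the series-R + parallel-RC equivalent circuit
  (exact piecewise-exponential solution),
* two-state Markov single-channel records,
* voltage-gated Ca²⁺ (Ca_V) current families with optional self-consistent
  series-resistance distortion,
* two-channel calibration image stacks governed by a Hill response with
  linear green→red bleed-through,
* beating-cilium stacks for kymograph beat-frequency analysis,
* Ca²⁺-front line scans (constant-velocity or diffusive),
* drifting-bead detection fields for flow velocimetry.

Determinism: every generator draws from a stream derived from the
:class:`SimConfig` seed, a stable per-generator label, and a per-label
call counter, so identical configs reproduce outputs bit-for-bit in the
same call order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .calcium import HillFit, TwoChannelStack
from .circuit import CiliumGeometry, EquivalentCircuit
from .ephys import StepProtocol, SweepSet
from .motility import ImageStack, Kymograph


class AliasingError(ValueError):
    """Requested beat frequency too high for the frame rate."""


class StabilityError(RuntimeError):
    """Self-consistent series-resistance solve failed (loss-of-clamp regime)."""


@dataclass
class SimConfig:
    """Shared simulation settings and the master seed.

    Noise defaults: additive Gaussian current noise of 1 pA RMS on
    whole-cell sweeps (0.2 pA on single-channel records, which stand in
    for 1 kHz-filtered data); images carry Poisson shot noise at
    ``image_gain`` counts/photon plus Gaussian read noise.
    """

    seed: int = 0
    current_noise_sd_pa: float = 1.0
    single_channel_noise_sd_pa: float = 0.2
    image_gain: float = 1.0
    read_noise_sd: float = 2.0
    geometry: CiliumGeometry = field(default_factory=CiliumGeometry)
    _counters: dict = field(default_factory=dict, repr=False, compare=False)

    def rng(self, label: str) -> np.random.Generator:
        """Independent stream for one generated artifact.

        Derived from (seed, crc32(label), call count for that label): a
        fresh config replays the identical stream sequence.
        """
        n = self._counters.get(label, 0)
        self._counters[label] = n + 1
        ss = np.random.SeedSequence(entropy=self.seed,
                                    spawn_key=(zlib.crc32(label.encode()), n))
        return np.random.default_rng(ss)


@dataclass(frozen=True)
class GatingModel:
    """Two-state (closed ⇌ open) channel gating.

    Stationary open probability P_o = open_rate / (open_rate + close_rate).
    """

    open_rate: float      # 1/s, closed -> open
    close_rate: float     # 1/s, open -> closed
    i_single_pa: float = 1.4
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.open_rate < 0 or self.close_rate < 0 \
                or self.open_rate + self.close_rate <= 0:
            raise ValueError("rates must be non-negative with a positive sum")

    @property
    def p_open(self) -> float:
        return self.open_rate / (self.open_rate + self.close_rate)

    @classmethod
    def from_p_open(cls, p_open: float, total_rate: float = 50.0,
                    i_single_pa: float = 1.4, n_channels: int = 1) -> "GatingModel":
        """Pick rates with the given stationary P_o and open+close rate sum."""
        return cls(open_rate=p_open * total_rate,
                   close_rate=(1.0 - p_open) * total_rate,
                   i_single_pa=i_single_pa, n_channels=n_channels)


@dataclass(frozen=True)
class CavActivationModel:
    """Boltzmann steady-state activation with first-order kinetics.

    Forward model standing in for the L-type Ca²⁺ currents of ependymal
    cells: g(V, t→∞) = g_max / (1 + exp(−(V−V_half)/slope)), driving an
    inward current g·(V − E_rev) below the reversal potential.
    """

    g_max_ns: float = 3.0
    v_half_mv: float = -10.0
    slope_mv: float = 7.0
    e_rev_mv: float = 60.0
    activation_tau_ms: float = 3.0

    def __post_init__(self) -> None:
        if self.slope_mv <= 0 or self.g_max_ns < 0:
            raise ValueError("slope must be > 0 and g_max >= 0")

    def g_inf(self, v_mv):
        return self.g_max_ns / (1.0 + np.exp(-(np.asarray(v_mv) - self.v_half_mv)
                                             / self.slope_mv))


# ---------------------------------------------------------------------------
# circuit forward model
# ---------------------------------------------------------------------------

def _circuit_segments(circuit: EquivalentCircuit, protocol: StepProtocol,
                      time: np.ndarray, step_mv: float) -> np.ndarray:
    """Exact piecewise-exponential pipette current (pA) for one sweep.

    State variable is the membrane (capacitor) voltage; each command
    segment relaxes exponentially toward its own steady state with
    τ = C_m (R_s ‖ R_m).
    """
    rs, rm, cm = circuit.R_series, circuit.R_m, circuit.C_m
    if math.isinf(rm):
        divider = 1.0
        tau_ms_ = rs * cm * 1e-3
    else:
        divider = rm / (rs + rm)
        tau_ms_ = (rs * rm / (rs + rm)) * cm * 1e-3
    tau_s = tau_ms_ * 1e-3

    v_hold = circuit.V_hold
    bounds = [(time[0], v_hold), (protocol.t_on, v_hold + step_mv),
              (protocol.t_off, v_hold)]
    current = np.empty_like(time)
    v_c = v_hold * divider  # start at the holding steady state
    for k, (t_start, v_p) in enumerate(bounds):
        t_end = bounds[k + 1][0] if k + 1 < len(bounds) else time[-1] + 1.0
        sel = (time >= t_start) & (time < t_end) if k + 1 < len(bounds) \
            else (time >= t_start)
        t_rel = time[sel] - t_start
        v_c_inf = v_p * divider
        v_c_t = v_c_inf + (v_c - v_c_inf) * np.exp(-t_rel / tau_s)
        current[sel] = 1e3 * (v_p - v_c_t) / rs  # mV/MΩ -> nA -> pA
        # carry the state to the next segment boundary
        dt_seg = t_end - t_start
        v_c = v_c_inf + (v_c - v_c_inf) * math.exp(-dt_seg / tau_s)
    return current


def simulate_patch_recording(circuit: EquivalentCircuit,
                             protocol: StepProtocol,
                             n_sweeps: int = 100,
                             cfg: SimConfig | None = None,
                             sampling_rate: float = 50_000.0,
                             duration_s: float | None = None,
                             noiseless: bool = False
                             ) -> tuple[SweepSet, dict]:
    """Capacitive-transient sweeps from the equivalent circuit.

    Returns the sweep set and a truth record with the circuit parameters
    and the analytic τ, peak current and transferred charge.
    """
    cfg = cfg or SimConfig()
    if duration_s is None:
        duration_s = protocol.t_off + (protocol.t_off - protocol.t_on)
    n = int(round(duration_s * sampling_rate))
    time = np.arange(n) / sampling_rate
    step = protocol.step_for(0)
    clean = _circuit_segments(circuit, protocol, time, step)

    rng = cfg.rng("patch_recording")
    sweeps = np.tile(clean, (n_sweeps, 1))
    if not noiseless and cfg.current_noise_sd_pa > 0:
        sweeps = sweeps + rng.normal(0.0, cfg.current_noise_sd_pa, sweeps.shape)

    rs, rm, cm = circuit.R_series, circuit.R_m, circuit.C_m
    tau = (rs if math.isinf(rm) else rs * rm / (rs + rm)) * cm * 1e-3
    truth = {
        "C_m_pF": cm, "R_series_MOhm": rs, "R_m_MOhm": rm,
        "tau_ms": tau,
        "peak_pA": 1e3 * step / rs * (1.0 if math.isinf(rm) else 1.0),
        "Q_pC": abs(cm * step) * 1e-3 * (1.0 if math.isinf(rm)
                                         else (rm / (rs + rm)) ** 2),
    }
    return SweepSet(time=time, sweeps=sweeps, sampling_rate=sampling_rate,
                    protocol=protocol), truth


def integrate_circuit_ode(circuit: EquivalentCircuit, protocol: StepProtocol,
                          time: np.ndarray, step_mv: float,
                          n_substeps: int = 40) -> np.ndarray:
    """Brute-force numerical integration of the same circuit (oracle).

    Small-step RK4 on dV_c/dt = ((V_p−V_c)/R_s − V_c/R_m)/C_m, kept
    deliberately independent of the closed-form path.  The command
    voltage is held constant within each output sample interval, so step
    edges land exactly on sample boundaries as in the closed form.
    """
    rs, rm, cm = circuit.R_series, circuit.R_m, circuit.C_m
    g_m = 0.0 if math.isinf(rm) else 1.0 / rm
    dt = (time[1] - time[0]) / n_substeps

    def dvdt(v_c: float, v_p: float) -> float:
        # mV/MΩ = nA; nA/pF = 1e6 mV/s
        return ((v_p - v_c) / rs - v_c * g_m) / cm * 1e6

    v_c = circuit.V_hold * (1.0 if math.isinf(rm) else rm / (rs + rm))
    out = np.empty_like(time)
    for i, t in enumerate(time):
        if protocol.t_on <= t < protocol.t_off:
            v_p = circuit.V_hold + step_mv
        else:
            v_p = circuit.V_hold
        out[i] = 1e3 * (v_p - v_c) / rs
        for _ in range(n_substeps):
            k1 = dvdt(v_c, v_p)
            k2 = dvdt(v_c + 0.5 * dt * k1, v_p)
            k3 = dvdt(v_c + 0.5 * dt * k2, v_p)
            k4 = dvdt(v_c + dt * k3, v_p)
            v_c += dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    return out


# ---------------------------------------------------------------------------
# single channels
# ---------------------------------------------------------------------------

def simulate_single_channel(gating: GatingModel,
                            pulse_ms: float = 400.0,
                            n_sweeps: int = 9,
                            cfg: SimConfig | None = None,
                            sampling_rate: float = 20_000.0,
                            noiseless: bool = False
                            ) -> tuple[SweepSet, dict]:
    """Two-state Markov single-channel sweeps.

    Each channel follows an exact continuous-time two-state trajectory
    (exponential dwell times, stationary initial state); channels sum,
    scaled by the unitary current.  Mean dwell times must span at least
    5 samples at the chosen rate.
    """
    cfg = cfg or SimConfig()
    max_rate = max(gating.open_rate, gating.close_rate)
    if max_rate > 0 and sampling_rate / max_rate < 5:
        raise ValueError("gating rates unresolvable at this sampling rate")
    rng = cfg.rng("single_channel")

    duration = pulse_ms * 1e-3
    n = int(round(duration * sampling_rate))
    time = np.arange(n) / sampling_rate
    sweeps = np.zeros((n_sweeps, n))
    for s in range(n_sweeps):
        for _ in range(gating.n_channels):
            state = rng.random() < gating.p_open
            t = 0.0
            while t < duration:
                rate = gating.close_rate if state else gating.open_rate
                # a zero rate makes the current state absorbing
                dwell = rng.exponential(1.0 / rate) if rate > 0 else duration
                if state:
                    i0 = int(t * sampling_rate)
                    i1 = min(int((t + dwell) * sampling_rate) + 1, n)
                    # mark fully-open samples
                    sweeps[s, i0:i1] += gating.i_single_pa
                t += dwell
                state = not state
    if not noiseless and cfg.single_channel_noise_sd_pa > 0:
        sweeps += rng.normal(0.0, cfg.single_channel_noise_sd_pa, sweeps.shape)

    protocol = StepProtocol(holding_mV=-80.0, step_mV=80.0, t_on=0.0,
                            t_off=duration)
    truth = {"p_open": gating.p_open, "i_single_pA": gating.i_single_pa,
             "n_channels": gating.n_channels}
    return SweepSet(time=time, sweeps=sweeps, sampling_rate=sampling_rate,
                    protocol=protocol), truth


# ---------------------------------------------------------------------------
# Ca_V currents with series-resistance distortion
# ---------------------------------------------------------------------------

def _solve_vm(v_cmd: float, m: float, circuit: EquivalentCircuit,
              act: CavActivationModel, tol_mv: float = 1e-3,
              max_iter: int = 100, damping: float = 0.5) -> float:
    """Damped fixed-point solve of V_m = V_cmd − I(V_m)·R_s (quasi-static)."""
    rs = circuit.R_series
    g_leak = 0.0 if math.isinf(circuit.R_m) else 1e3 / circuit.R_m  # pA/mV
    v = v_cmd
    for _ in range(max_iter):
        i_total = act.g_max_ns * m * (v - act.e_rev_mv) + g_leak * v  # pA
        v_new = v_cmd - i_total * rs * 1e-3
        if abs(v_new - v) < tol_mv:
            return v_new
        v = v + damping * (v_new - v)
    raise StabilityError(
        "series-resistance fixed point did not converge "
        "(transient loss of voltage clamp at this g_max·R_series)")


def simulate_cav_current(circuit: EquivalentCircuit,
                         act: CavActivationModel,
                         protocol: StepProtocol,
                         apply_rs_error: bool = False,
                         cfg: SimConfig | None = None,
                         sampling_rate: float = 20_000.0,
                         duration_s: float | None = None,
                         noiseless: bool = False
                         ) -> tuple[SweepSet, dict]:
    """Ca_V current family over a voltage-step ladder.

    Activation follows first-order kinetics toward the Boltzmann steady
    state; with ``apply_rs_error`` the membrane voltage is solved
    self-consistently per time step from V_m = V_cmd − I·R_series
    (quasi-static: the capacitive transient is not part of this model).
    Ohmic leak through R_m is included.  Sweeps are emitted relative to
    the holding-current baseline (amplifier-zeroed).  The truth record
    stores the undistorted (V_m ≡ V_cmd) current family.
    """
    cfg = cfg or SimConfig()
    if duration_s is None:
        duration_s = protocol.t_off + (protocol.t_off - protocol.t_on) / 2
    n = int(round(duration_s * sampling_rate))
    time = np.arange(n) / sampling_rate
    dt_ms = 1e3 / sampling_rate
    steps = protocol.steps
    g_leak = 0.0 if math.isinf(circuit.R_m) else 1e3 / circuit.R_m  # pA/mV

    def run(step_mv: float, with_rs: bool) -> np.ndarray:
        out = np.empty(n)
        # fractional activation state, 0..1, starting at the holding steady state
        m = 1.0 / (1.0 + math.exp(-(circuit.V_hold - act.v_half_mv) / act.slope_mv))
        baseline = None
        for i, t in enumerate(time):
            v_cmd = circuit.V_hold + (step_mv if protocol.t_on <= t < protocol.t_off
                                      else 0.0)
            if with_rs and circuit.R_series > 0:
                v_m = _solve_vm(v_cmd, m, circuit, act)
            else:
                v_m = v_cmd
            i_ca = act.g_max_ns * m * (v_m - act.e_rev_mv)
            i_leak = g_leak * v_m
            out[i] = i_ca + i_leak
            if baseline is None:
                baseline = out[i]
            m_inf = 1.0 / (1.0 + math.exp(-(v_m - act.v_half_mv) / act.slope_mv))
            m += (m_inf - m) * (1.0 - math.exp(-dt_ms / act.activation_tau_ms))
        return out - baseline

    sweeps = np.stack([run(s, apply_rs_error) for s in steps])
    undistorted = np.stack([run(s, False) for s in steps])
    rng = cfg.rng("cav_current")
    if not noiseless and cfg.current_noise_sd_pa > 0:
        sweeps = sweeps + rng.normal(0.0, cfg.current_noise_sd_pa, sweeps.shape)

    truth = {"undistorted_sweeps": undistorted, "steps_mV": steps,
             "g_max_nS": act.g_max_ns, "v_half_mV": act.v_half_mv,
             "e_rev_mV": act.e_rev_mv}
    return SweepSet(time=time, sweeps=sweeps, sampling_rate=sampling_rate,
                    protocol=protocol), truth


# ---------------------------------------------------------------------------
# imaging generators
# ---------------------------------------------------------------------------

def _paint_curve(img: np.ndarray, pts: np.ndarray, amplitude: float,
                 sigma_px: float = 1.0) -> None:
    """Deposit a Gaussian-profile curve onto ``img`` (in place)."""
    h, w = img.shape
    half = max(int(math.ceil(3 * sigma_px)), 2)
    for x, y in pts:
        xi, yi = int(round(x)), int(round(y))
        x0, x1 = max(xi - half, 0), min(xi + half + 1, w)
        y0, y1 = max(yi - half, 0), min(yi + half + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = np.exp(-0.5 * ((xs - x) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((ys - y) / sigma_px) ** 2)
        img[y0:y1, x0:x1] = np.maximum(img[y0:y1, x0:x1],
                                       amplitude * gy[:, None] * gx[None, :])


def _cilium_points(rng: np.random.Generator, shape: tuple[int, int],
                   length_px: float, step_px: float = 0.5) -> np.ndarray:
    """Gently curved cilium centreline inside the frame."""
    h, w = shape
    margin = 6
    x_hi = max(margin + 1.0, w - margin - length_px * 0.8)
    x0 = rng.uniform(margin, x_hi)
    y_lo = min(margin + length_px * 0.3, h * 0.35)
    y0 = rng.uniform(y_lo, max(h - y_lo, y_lo + 1.0))
    theta = rng.uniform(-0.4, 0.4)
    curv = rng.uniform(-0.004, 0.004)
    n = int(length_px / step_px)
    s = np.arange(n) * step_px
    ang = theta + curv * s
    pts = np.stack([x0 + np.cumsum(step_px * np.cos(ang)),
                    y0 + np.cumsum(step_px * np.sin(ang))], axis=1)
    pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
    return pts


def _image_noise(clean: np.ndarray, rng: np.random.Generator,
                 cfg: SimConfig, bit_depth: int) -> np.ndarray:
    photons = np.maximum(clean / cfg.image_gain, 0.0)
    noisy = rng.poisson(photons).astype(float) * cfg.image_gain
    noisy += rng.normal(0.0, cfg.read_noise_sd, clean.shape)
    return np.clip(noisy, 0.0, 2 ** bit_depth - 1)


# Default calibration truth for simulated sensor stacks.  EC50 is pinned so
# that the basal operating point matches ependymal motile cilia: a corrected
# ratio of 0.2 at 165 nM free Ca²⁺ ((165/426)² / (1 + (165/426)²) · 1.15
# + 0.05 = 0.200).  GCaMP6s-like cooperativity n_H = 2.
DEFAULT_HILL = HillFit(R_min=0.05, R_max=1.2, EC50_nM=426.0, n_H=2.0)


def simulate_calibration_stack(hill: HillFit, alpha: float,
                               ca_levels_nm=(50, 100, 165, 300, 1000, 3000, 10_000),
                               cfg: SimConfig | None = None,
                               n_stacks_per_level: int = 5,
                               n_cilia: int = 3,
                               frame_shape: tuple[int, int] = (128, 128),
                               pixel_size_um: float = 0.1,
                               expression: float = 2000.0,
                               background: float = 100.0,
                               scan_mode: str = "non_sequential",
                               bit_depth: int = 16,
                               noiseless: bool = False
                               ) -> tuple[dict[float, list[TwoChannelStack]], dict]:
    """Two-channel calibration stacks at defined free [Ca²⁺].

    Cilia are painted as Gaussian-profile curves; the red channel carries
    the expression level, the green channel is red × Hill([Ca²⁺]).  Under
    non-sequential scanning a fraction ``alpha`` of the green signal
    leaks into the red channel.  Returns {level: [stacks]} (the shape
    :func:`ciliaphys.calcium.calibrate` consumes) plus a truth record.
    """
    cfg = cfg or SimConfig()
    rng = cfg.rng("calibration_stack")
    length_px = cfg.geometry.length / pixel_size_um
    stacks: dict[float, list[TwoChannelStack]] = {}
    for ca in ca_levels_nm:
        ratio = float(hill.forward(ca))
        level_stacks = []
        for _ in range(n_stacks_per_level):
            red = np.zeros(frame_shape)
            for _ in range(n_cilia):
                pts = _cilium_points(rng, frame_shape, length_px)
                _paint_curve(red, pts, expression * rng.uniform(0.7, 1.3))
            green = red * ratio
            red_obs = red + (alpha * green if scan_mode == "non_sequential" else 0.0)
            green_obs = green + background
            red_obs = red_obs + background
            if not noiseless:
                green_obs = _image_noise(green_obs, rng, cfg, bit_depth)
                red_obs = _image_noise(red_obs, rng, cfg, bit_depth)
            level_stacks.append(TwoChannelStack(
                green=green_obs[None], red=red_obs[None],
                pixel_size_um=pixel_size_um, frame_interval_s=1.0,
                bit_depth=bit_depth, scan_mode=scan_mode))
        stacks[float(ca)] = level_stacks
    truth = {
        "hill": {"R_min": hill.R_min, "R_max": hill.R_max,
                 "EC50_nM": hill.EC50_nM, "n_H": hill.n_H},
        "alpha": alpha, "expression": expression, "background": background,
        "mask_threshold": background + 0.25 * expression,
        "scan_mode": scan_mode,
    }
    return stacks, truth


def simulate_bleedthrough_observations(alpha: float = 0.03,
                                       n_points: int = 24,
                                       cfg: SimConfig | None = None,
                                       intensity_range=(200.0, 4000.0),
                                       noise_sd: float = 5.0
                                       ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Paired (green, leak) ROI means from a green-only specimen.

    Emulates imaging cells expressing only the green indicator with the
    calibration acquisition settings: the red channel reads pure
    bleed-through α·green plus noise.
    """
    cfg = cfg or SimConfig()
    rng = cfg.rng("bleedthrough")
    green = rng.uniform(*intensity_range, n_points)
    leak = alpha * green + rng.normal(0.0, noise_sd, n_points)
    return green, leak, {"alpha": alpha, "n_points": n_points}


def simulate_beating_stack(frequency_hz: float,
                           fps: float = 200.0,
                           duration_s: float = 2.0,
                           cfg: SimConfig | None = None,
                           frame_shape: tuple[int, int] = (64, 64),
                           pixel_size_um: float = 0.25,
                           amplitude_px: float = 10.0,
                           frequency_schedule: list[tuple[float, float]] | None = None,
                           noiseless: bool = False,
                           bit_depth: int = 16
                           ) -> tuple[ImageStack, dict]:
    """Beating-cilium movie plus the analysis line for kymograph CBF.

    The cilium is anchored at a base point and bends sinusoidally at the
    requested frequency; the truth record carries an analysis line placed
    at the extreme of the stroke near the tip, where the line-integrated
    intensity peaks exactly once per beat cycle.  ``frequency_schedule``
    ([(switch_time_s, new_frequency_hz), ...]) changes the frequency
    mid-record, e.g. to mimic a solution exchange.

    The frame rate must resolve the beat (fps ≥ 4 × frequency).
    """
    cfg = cfg or SimConfig()
    freqs = [frequency_hz] + ([f for _, f in frequency_schedule]
                              if frequency_schedule else [])
    if any(fps < 4 * f for f in freqs if f > 0):
        raise AliasingError("frame rate below 4× the beat frequency")
    rng = cfg.rng("beating_stack")

    n_frames = int(round(duration_s * fps))
    dt = 1.0 / fps
    h, w = frame_shape
    base = np.array([8.0, h / 2.0])
    length_px = min(cfg.geometry.length / pixel_size_um, w - base[0] - 4)

    # phase accumulator honouring the schedule
    switch = sorted(frequency_schedule or [])
    phases = np.empty(n_frames)
    phase, f_now, si = 0.0, frequency_hz, 0
    for i in range(n_frames):
        t = i * dt
        while si < len(switch) and t >= switch[si][0]:
            f_now = switch[si][1]
            si += 1
        phases[i] = phase
        phase += 2 * math.pi * f_now * dt

    s = np.arange(0, length_px, 0.5)
    bend = (s / length_px) ** 2
    frames = np.zeros((n_frames, h, w))
    for i in range(n_frames):
        defl = amplitude_px * math.sin(phases[i])
        pts = np.stack([base[0] + s, base[1] + bend * defl], axis=1)
        _paint_curve(frames[i], pts, 1000.0, sigma_px=2.0)
    if not noiseless:
        for i in range(n_frames):
            frames[i] = _image_noise(frames[i] + 50.0, rng, cfg, bit_depth)

    # analysis line: horizontal, at the tip's extreme deflection
    x_line = base[0] + 0.9 * length_px
    y_line = base[1] + 0.81 * amplitude_px
    line = np.array([[base[0] + 0.7 * length_px, y_line],
                     [min(base[0] + length_px, w - 1), y_line]])
    truth = {"frequency_hz": frequency_hz,
             "frequency_schedule": frequency_schedule,
             "analysis_line": line}
    return ImageStack(frames=frames, frame_interval_s=dt,
                      pixel_size_um=pixel_size_um), truth


_ERFC_HALF = 0.47693627620446987  # z with erfc(z) = 1/2


def _diffusion_grid(pos: np.ndarray, t: np.ndarray, t_stim: float,
                    d_um2_s: float) -> np.ndarray:
    """FTCS solve of ∂C/∂t = D ∂²C/∂x² on the cilium grid.

    Base (x = 0) clamped to 1 after the stimulus, tip reflecting.
    Returns C at the requested sample times, shape (n_pos, n_t).
    """
    dx = pos[1] - pos[0]
    dt_stable = 0.4 * dx * dx / d_um2_s
    frame_dt = t[1] - t[0]
    n_sub = max(int(math.ceil(frame_dt / dt_stable)), 1)
    dt = frame_dt / n_sub
    lam = d_um2_s * dt / (dx * dx)

    c = np.zeros(pos.size)
    out = np.zeros((pos.size, t.size))
    for j, tj in enumerate(t):
        out[:, j] = c
        for _ in range(n_sub):
            if tj >= t_stim:
                c[0] = 1.0
            lap = np.empty_like(c)
            lap[1:-1] = c[2:] - 2 * c[1:-1] + c[:-2]
            lap[0] = 0.0
            lap[-1] = 2 * (c[-2] - c[-1])  # reflecting tip
            c = c + lam * lap
            if tj >= t_stim:
                c[0] = 1.0
    return out


def simulate_front_linescan(velocity_um_s: float | None = None,
                            diffusion_um2_s: float | None = None,
                            cfg: SimConfig | None = None,
                            fps: float = 500.0,
                            duration_s: float = 1.5,
                            stimulus_time_s: float = 0.2,
                            dx_um: float = 0.1,
                            rise_ms: float = 5.0,
                            indicator_tau_ms: float = 0.0,
                            amplitude: float = 1000.0,
                            baseline: float = 100.0,
                            noise_sd: float = 5.0,
                            noiseless: bool = False
                            ) -> tuple[Kymograph, dict]:
    """Line-scan kymograph of a Ca²⁺ front entering a cilium at its base.

    Exactly one of ``velocity_um_s`` / ``diffusion_um2_s`` must be given.
    Constant-velocity mode: each position x crosses half-amplitude at
    stimulus + x/v (symmetric sigmoidal rise, so the 50 % crossing is
    exact).  Diffusion mode: 1-D diffusion solved on a grid with the
    base clamped to the reservoir concentration and a sealed (reflecting)
    tip; before the reflection is felt the 50 % crossing time grows as
    x², and the profile equilibrates to the reservoir level so that
    per-position plateaus are well defined.  Indicator kinetics can be
    layered on as a first-order low-pass.

    Truth ``time_to_tip_s`` is measured from the stimulus, matching
    :func:`ciliaphys.motility.front_velocity`.
    """
    if (velocity_um_s is None) == (diffusion_um2_s is None):
        raise ValueError("give exactly one of velocity or diffusion coefficient")
    cfg = cfg or SimConfig()
    rng = cfg.rng("front_linescan")
    length = cfg.geometry.length
    pos = np.arange(0.0, length + dx_um / 2, dx_um)
    t = np.arange(int(round(duration_s * fps))) / fps
    tp = t[None, :] - stimulus_time_s

    if velocity_um_s is not None:
        if math.isinf(velocity_um_s):
            drive = (tp >= 0).astype(float) * np.ones((pos.size, 1))
        else:
            arrival = pos[:, None] / velocity_um_s
            drive = 1.0 / (1.0 + np.exp(-(tp - arrival) / (rise_ms * 1e-3)))
            drive[:, tp[0] < 0] = 0.0
        truth_v = velocity_um_s
        ttt = length / velocity_um_s if not math.isinf(velocity_um_s) else 0.0
    else:
        drive = _diffusion_grid(pos, t, stimulus_time_s, diffusion_um2_s)
        truth_v = None
        # time for the clean field to reach half the reservoir level at the tip
        tip = drive[-1]
        above = np.nonzero(tip >= 0.5)[0]
        ttt = float(t[above[0]] - stimulus_time_s) if above.size else float("nan")

    if indicator_tau_ms > 0:
        a = 1.0 - math.exp(-(1e3 / fps) / indicator_tau_ms)
        filt = np.empty_like(drive)
        acc = np.zeros(pos.size)
        for j in range(drive.shape[1]):
            acc += a * (drive[:, j] - acc)
            filt[:, j] = acc
        drive = filt

    data = baseline + amplitude * drive
    if not noiseless and noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)

    line = np.array([[0.0, 0.0], [length / dx_um, 0.0]])
    truth = {"velocity_um_s": truth_v, "diffusion_um2_s": diffusion_um2_s,
             "stimulus_time_s": stimulus_time_s, "time_to_tip_s": ttt,
             "length_um": length}
    return Kymograph(data=data, line=line, pixel_size_um=dx_um,
                     frame_interval_s=1.0 / fps), truth


def simulate_bead_field(mean_velocity_um_s: float = 86.0,
                        n_beads: int = 12,
                        jitter_sd_um: float = 0.05,
                        fps: float = 100.0,
                        duration_s: float = 4.0,
                        cfg: SimConfig | None = None,
                        pixel_size_um: float = 0.2,
                        fov_px: tuple[int, int] = (256, 256),
                        velocity_cv: float = 0.15
                        ) -> tuple[list[np.ndarray], dict]:
    """Per-frame bead detections drifting with the cilia-driven flow.

    Beads drift along +x at per-bead speeds drawn around
    ``mean_velocity_um_s`` (coefficient of variation ``velocity_cv``),
    with isotropic Gaussian localization jitter.  Beads enter at random
    times/positions and leave when they exit the field, so short-lived
    beads (< 4 frames) occur naturally.  Returns the per-frame (x, y)
    detection arrays and a truth record with per-bead speeds.
    """
    cfg = cfg or SimConfig()
    rng = cfg.rng("bead_field")
    n_frames = int(round(duration_s * fps))
    dt = 1.0 / fps
    w, h = fov_px
    speeds = rng.normal(mean_velocity_um_s, velocity_cv * mean_velocity_um_s,
                        n_beads)
    speeds = np.maximum(speeds, 0.1 * mean_velocity_um_s)
    t_enter = rng.uniform(0.0, duration_s * 0.8, n_beads)
    x0 = rng.uniform(0.0, w * 0.6, n_beads)
    y0 = rng.uniform(5.0, h - 5.0, n_beads)

    detections: list[np.ndarray] = []
    visible_frames = np.zeros(n_beads, dtype=int)
    for i in range(n_frames):
        t = i * dt
        pts = []
        for b in range(n_beads):
            if t < t_enter[b]:
                continue
            x = x0[b] + speeds[b] * (t - t_enter[b]) / pixel_size_um
            if x > w - 1:
                continue
            jitter = rng.normal(0.0, jitter_sd_um / pixel_size_um, 2)
            pts.append([x + jitter[0], y0[b] + jitter[1]])
            visible_frames[b] += 1
        detections.append(np.asarray(pts) if pts else np.empty((0, 2)))
    truth = {"speeds_um_s": speeds, "visible_frames": visible_frames,
             "mean_velocity_um_s": float(speeds[visible_frames >= 4].mean())
             if (visible_frames >= 4).any() else float("nan"),
             "jitter_sd_um": jitter_sd_um}
    return detections, truth
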