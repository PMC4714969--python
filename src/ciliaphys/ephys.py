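"""Analysis of voltage-clamp current sweeps.

Implements the standard workflow for whole-cell / whole-cilium recordings:

* P/N-style leak subtraction from three hyperpolarizing control pulses,
* capacitive-transient analysis (charge Q, C_m = Q/ΔV, τ from a single
  exponential fit, R_series = τ/C_m),
* current–voltage curves (steady-state or peak) with SEM across recordings,
* zero-phase Gaussian low-pass filtering,
* all-point / open-point amplitude histograms,
* time-averaged open probability P_o from single-channel sweeps.

Sweeps travel in a :class:`SweepSet`: a (n_sweeps, n_samples) current
array in pA, a shared time base in s, and a :class:`StepProtocol`
describing the command waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize


class ProtocolError(ValueError):
    """Command-voltage protocol inconsistent with the requested analysis."""


class FitError(RuntimeError):
    """Curve fit failed; carries residuals when available."""

    def __init__(self, msg: str, residuals: np.ndarray | None = None):
        super().__init__(msg)
        self.residuals = residuals


@dataclass(frozen=True)
class StepProtocol:
    """Rectangular voltage-step protocol shared by the sweeps of a SweepSet.

    ``step_mV`` is the step amplitude relative to holding; scalar when all
    sweeps share one step, or one value per sweep for a ladder.
    """

    holding_mV: float
    step_mV: float | tuple
    t_on: float
    t_off: float

    def step_for(self, sweep_index: int) -> float:
        if np.isscalar(self.step_mV):
            return float(self.step_mV)
        return float(self.step_mV[sweep_index])

    @property
    def steps(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.step_mV, dtype=float))


@dataclass
class SweepSet:
    """A set of current sweeps sharing one time base and protocol."""

    time: np.ndarray                 # s
    sweeps: np.ndarray               # (n_sweeps, n_samples) pA
    sampling_rate: float             # Hz
    protocol: StepProtocol
    filter_applied: float | None = None  # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sweeps.shape[1] != self.time.size:
            raise ValueError("sweeps and time base disagree in length")
        dt = 1.0 / self.sampling_rate
        if abs((self.time[1] - self.time[0]) - dt) > 1e-9:
            raise ValueError("time base spacing does not match sampling_rate")
        p = self.protocol
        if not (self.time[0] <= p.t_on < p.t_off <= self.time[-1] + dt + 1e-12):
            raise ProtocolError("protocol step lies outside the trace window")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    def sample_index(self, t: float) -> int:
        return int(round((t - self.time[0]) * self.sampling_rate))


@dataclass(frozen=True)
class TransientFitResult:
    Q_pC: float
    C_m_pF: float
    tau_ms: float
    R_series_MOhm: float
    steady_state_pA: float
    fit_rmse_pA: float
    degenerate: bool = False


@dataclass(frozen=True)
class IVCurve:
    voltages_mV: np.ndarray
    currents_pA: np.ndarray
    sem_pA: np.ndarray
    mode: str
    n: int


@dataclass(frozen=True)
class AmplitudeHistogram:
    bin_centers_pA: np.ndarray
    counts: np.ndarray
    mode: str
    full_amplitude_pA: float | None = None
    fraction_threshold: float | None = None


# ---------------------------------------------------------------------------
# leak subtraction
# ---------------------------------------------------------------------------

def subtract_leak(test_sweep: np.ndarray, leak_sweeps: np.ndarray,
                  dv_test: float, dv_leak: float,
                  baseline_samples: int | None = None) -> np.ndarray:
    """Remove linear (leak + capacitive) components with scaled control pulses.

    Three consecutive responses to a small hyperpolarizing step are summed,
    inverted, scaled by dV_test / (3·|dV_leak|) and subtracted from the
    test response.  Any purely linear circuit cancels exactly; what
    survives is the voltage-dependent (active) current.

    Parameters
    ----------
    test_sweep : (n,) array, pA — response to the depolarizing test step.
    leak_sweeps : (3, n) array, pA — responses to the hyperpolarizing step,
        aligned to the same step onset as the test sweep.
    dv_test, dv_leak : step amplitudes in mV, opposite signs
        (dv_leak < 0 < dv_test).
    baseline_samples : when given, each trace first has the mean of its
        first ``baseline_samples`` samples removed (pre-step zeroing);
        otherwise traces are assumed already baseline-subtracted.
    """
    test_sweep = np.asarray(test_sweep, dtype=float)
    leak_sweeps = np.atleast_2d(np.asarray(leak_sweeps, dtype=float))
    if baseline_samples is not None:
        if baseline_samples < 1:
            raise ValueError("baseline_samples must be >= 1")
        test_sweep = test_sweep - test_sweep[:baseline_samples].mean()
        leak_sweeps = leak_sweeps - leak_sweeps[:, :baseline_samples].mean(
            axis=1, keepdims=True)
    if leak_sweeps.shape[0] != 3:
        raise ProtocolError("exactly three leak sweeps are expected")
    if leak_sweeps.shape[1] != test_sweep.size:
        raise ValueError("leak sweeps and test sweep differ in length")
    if not (dv_leak < 0 < dv_test):
        raise ProtocolError("leak step must be hyperpolarizing and test step depolarizing")
    scale = dv_test / (3.0 * abs(dv_leak))
    inverted_sum = -leak_sweeps.sum(axis=0)
    return test_sweep - scale * inverted_sum


# ---------------------------------------------------------------------------
# capacitive transients
# ---------------------------------------------------------------------------

def _exp_decay(t, a, tau):
    return a * np.exp(-t / tau)


def _exp_decay_offset(t, a, tau, c):
    # clip the exponent so wild optimizer excursions cannot overflow
    return a * np.exp(np.clip(-t / tau, -700.0, 700.0)) + c


def analyze_capacitive_transient(sweeps: SweepSet, dv_mv: float | None = None,
                                 n_average: int | None = None,
                                 steady_state_fraction: float = 0.2
                                 ) -> TransientFitResult:
    """Estimate Q, C_m, τ and R_series from a capacitive current transient.

    The sweeps (typically 100–200 repeats of a small hyperpolarizing step)
    are averaged; the steady-state current is first estimated over the
    final ``steady_state_fraction`` of the step and then refined as the
    asymptote of a single-exponential-plus-offset fit from the transient
    extremum to the step end (a raw tail mean is biased when τ is a
    sizable fraction of the step); the steady-state-subtracted transient
    is integrated (trapezoid) for the transferred charge Q.  Then
    C_m = Q/|ΔV| and R_series = τ/C_m.
    """
    p = sweeps.protocol
    if dv_mv is None:
        dv_mv = p.step_for(0)
    if dv_mv == 0:
        raise ProtocolError("step amplitude must be nonzero")
    n_average = n_average or sweeps.n_sweeps
    if n_average > sweeps.n_sweeps:
        raise ValueError("n_average exceeds available sweeps")

    avg = sweeps.sweeps[:n_average].mean(axis=0)
    i_on, i_off = sweeps.sample_index(p.t_on), sweeps.sample_index(p.t_off)
    i_off = min(i_off, avg.size)

    step_len = i_off - i_on
    ss_start = i_off - max(1, int(round(steady_state_fraction * step_len)))
    ss0 = float(avg[ss_start:i_off].mean())

    seg0 = avg[i_on:i_off] - ss0
    t_seg = sweeps.time[i_on:i_off] - sweeps.time[i_on]

    if dv_mv > 0:
        peak_idx = int(np.argmax(seg0))
    else:
        peak_idx = int(np.argmin(seg0))
    peak_val = seg0[peak_idx]

    if abs(peak_val) < 1e-12:
        return TransientFitResult(0.0, 0.0, 0.0, 0.0, ss0, 0.0,
                                  degenerate=True)
    if np.sign(peak_val) != np.sign(dv_mv):
        warnings.warn("transient polarity opposes the voltage step", stacklevel=2)

    t_fit = t_seg[peak_idx:] - t_seg[peak_idx]
    y_fit = avg[i_on + peak_idx:i_off]
    tau0 = max(t_seg[-1] / 10.0, 2.0 / sweeps.sampling_rate)
    try:
        popt, _ = optimize.curve_fit(_exp_decay_offset, t_fit, y_fit,
                                     p0=(peak_val, tau0, ss0), maxfev=5000)
    except RuntimeError as err:  # pragma: no cover - pathological input
        raise FitError(f"exponential fit failed: {err}", residuals=y_fit) from err
    tau_s = abs(popt[1])
    steady_state = float(popt[2])
    rmse = float(np.sqrt(np.mean((y_fit - _exp_decay_offset(t_fit, *popt)) ** 2)))

    # charge moved onto the membrane during the step; pA·s ≡ pC
    seg = avg[i_on:i_off] - steady_state
    q_pC = float(np.trapezoid(seg, t_seg))
    if abs(q_pC) < 1e-15:
        return TransientFitResult(0.0, 0.0, 0.0, 0.0, steady_state, rmse,
                                  degenerate=True)

    c_m = abs(q_pC) / abs(dv_mv) * 1e3      # pC/mV = nF -> pF
    tau_ms = tau_s * 1e3
    r_series = 1e3 * tau_ms / c_m           # ms/pF -> MΩ
    return TransientFitResult(Q_pC=abs(q_pC), C_m_pF=c_m, tau_ms=tau_ms,
                              R_series_MOhm=r_series,
                              steady_state_pA=steady_state, fit_rmse_pA=rmse)


# ---------------------------------------------------------------------------
# IV curves
# ---------------------------------------------------------------------------

def _window_measure(trace: np.ndarray, i_on: int, i_off: int, mode: str,
                    steady_state_fraction: float = 0.2) -> float:
    seg = trace[i_on:i_off]
    if mode == "steady_state":
        start = len(seg) - max(1, int(round(steady_state_fraction * len(seg))))
        return float(seg[start:].mean())
    if mode == "peak":
        # signed extremum within the step
        return float(seg[np.argmax(np.abs(seg))])
    raise ValueError(f"unknown mode {mode!r}")


def build_iv(recordings: list[SweepSet], mode: str = "steady_state") -> IVCurve:
    """Per-voltage mean ± SEM current over a list of recordings.

    Every recording must use the same voltage-step ladder (one sweep per
    step).  ``mode`` selects the steady-state current (final 20 % of the
    step) or the signed-extremum peak current.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    ladder = recordings[0].protocol.steps
    for rec in recordings[1:]:
        if not np.allclose(rec.protocol.steps, ladder):
            raise ProtocolError("recordings do not share a voltage ladder")
    volts = recordings[0].protocol.holding_mV + ladder
    order = np.argsort(volts)

    per_rec = np.empty((len(recordings), ladder.size))
    for k, rec in enumerate(recordings):
        i_on = rec.sample_index(rec.protocol.t_on)
        i_off = rec.sample_index(rec.protocol.t_off)
        for j in range(ladder.size):
            per_rec[k, j] = _window_measure(rec.sweeps[j], i_on, i_off, mode)

    mean = per_rec.mean(axis=0)
    n = len(recordings)
    sem = per_rec.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(ladder.size)
    return IVCurve(voltages_mV=volts[order], currents_pA=mean[order],
                   sem_pA=sem[order], mode=mode, n=n)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def offline_filter(trace: np.ndarray, cutoff_hz: float,
                   sampling_rate: float) -> np.ndarray:
    """Zero-phase Gaussian low-pass with unity DC gain.

    The kernel σ is set so the −3 dB point falls at ``cutoff_hz``
    (σ_t = √(ln 2)/(2π f_c)).  Gaussian filtering is the software analogue
    of the Bessel filters used on acquisition hardware: no ringing, and
    symmetric, so no phase delay.
    """
    if cutoff_hz >= sampling_rate / 2.0:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sigma_samples = np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff_hz) * sampling_rate
    return ndimage.gaussian_filter1d(np.asarray(trace, dtype=float),
                                     sigma_samples, mode="nearest")


def gaussian_noise_bandwidth_ratio(cutoff_hz: float, sampling_rate: float) -> float:
    """Expected white-noise variance ratio out/in for :func:`offline_filter`.

    For a discrete Gaussian kernel of σ samples the output variance of
    white noise is 1/(2σ√π) of the input variance.
    """
    sigma = np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff_hz) * sampling_rate
    return 1.0 / (2.0 * sigma * np.sqrt(np.pi))


# ---------------------------------------------------------------------------
# single-channel statistics
# ---------------------------------------------------------------------------

def amplitude_histogram(traces: np.ndarray, mode: str = "all_point",
                        bin_width_pa: float = 0.05,
                        full_amplitude_pa: float | None = None,
                        fraction: float = 0.9,
                        baseline_pa: float = 0.0) -> AmplitudeHistogram:
    """All-point or open-point amplitude histogram of current samples.

    ``all_point`` bins every sample.  ``open_point`` keeps only samples
    whose deviation from baseline exceeds ``fraction`` × full amplitude in
    the direction of the full amplitude (the conventional 0.9 fractional
    amplitude criterion for open events).
    """
    if bin_width_pa <= 0:
        raise ValueError("bin width must be positive")
    data = np.asarray(traces, dtype=float).ravel()
    if mode == "open_point":
        if full_amplitude_pa is None:
            raise ValueError("open_point mode requires full_amplitude_pa")
        threshold = fraction * full_amplitude_pa
        dev = data - baseline_pa
        if full_amplitude_pa >= 0:
            data = data[dev >= threshold]
        else:
            data = data[dev <= threshold]
    elif mode != "all_point":
        raise ValueError(f"unknown mode {mode!r}")

    if data.size == 0:
        return AmplitudeHistogram(np.array([]), np.array([], dtype=int), mode,
                                  full_amplitude_pa, fraction)
    lo = np.floor(data.min() / bin_width_pa) * bin_width_pa
    hi = np.ceil(data.max() / bin_width_pa) * bin_width_pa + bin_width_pa
    edges = np.arange(lo, hi + bin_width_pa / 2, bin_width_pa)
    counts, edges = np.histogram(data, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AmplitudeHistogram(centers, counts, mode, full_amplitude_pa, fraction)


def open_point_threshold(full_amplitude_pa: float, fraction: float = 0.9) -> float:
    """Deviation from baseline above which a sample counts as an open point."""
    return fraction * full_amplitude_pa


def open_probability(sweeps: SweepSet, i_single_pa: float,
                     window: tuple[float, float] | None = None) -> float:
    """Time-averaged open probability P_o = ⟨I⟩ / i_single.

    Sweeps must be baseline-subtracted and leak-free.  The mean current
    over the window (default: the protocol step) across all sweeps is
    divided by the unitary current.  Estimates outside [0, 1] (e.g. a
    multi-channel patch) are clamped with a warning.
    """
    if i_single_pa == 0:
        raise ZeroDivisionError("i_single must be nonzero")
    if window is None:
        window = (sweeps.protocol.t_on, sweeps.protocol.t_off)
    i0, i1 = sweeps.sample_index(window[0]), sweeps.sample_index(window[1])
    if not (0 <= i0 < i1 <= sweeps.time.size):
        raise ValueError("window lies outside the trace")
    p_o = float(sweeps.sweeps[:, i0:i1].mean() / i_single_pa)
    if not 0.0 <= p_o <= 1.0:
        warnings.warn(f"P_o estimate {p_o:.3f} outside [0, 1]; clamping "
                      "(multi-channel patch?)", stacklevel=2)
        p_o = min(max(p_o, 0.0), 1.0)
    return p_o
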