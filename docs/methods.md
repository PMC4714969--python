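# Methods

This note documents the models behind `ciliaphys`, the parameter choices
that matter, what the synthetic-data generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Equivalent circuit of whole-cilium access

The cell is modelled as a membrane capacitance C_m in parallel with a
membrane (leak) resistance R_m, reached through a lumped series
resistance R_series (pipette plus ciliary cable). The cilium itself is a
cylinder (defaults: length 11.5 µm, radius 0.125 µm), giving

* surface area A = 2πr(r + h) ≈ 9.13 µm² (end caps included; negligible),
* capacitance C = A·c_m ≈ 0.0913 pF at c_m = 1 µF/cm²,
* axial resistance R = ρl/(πr²) ≈ 351 MΩ at ρ = 150 Ω·cm.

The internal resistivity of a cilium is not experimentally known; ρ
defaults to the cytoplasmic value and stays a free parameter. The cilium
is treated as a lumped access resistor, not a distributed cable: its
membrane area (≈0.5 % of the cell) contributes negligibly to C_m, which
is what justifies the two-element reduction.

Clamp dynamics: τ = C_m·(R_series ‖ R_m), reducing to R_series·C_m for an
ideal seal. Voltage error: V_m = V_cmd − I·R_series with inward current
negative, so inward current depolarizes V_m past the command.

Channel-count arithmetic: N = I_m/(P_o·i) is the only dimensionally
consistent reading of a mean current divided by open probability times
unitary current; per-cilium counts scale N by the capacitance ratio
C_cilium/C_cell, which equals the area ratio at fixed specific
capacitance. Both the capacitance-ratio and area-ratio routes agree to
three significant figures.

Unit handling: public interfaces speak pA/pF/MΩ/mV/ms/µm/nM; all
conversions live in `ciliaphys.units` (e.g. 1 MΩ·pF = 1 µs). RT/F for
Nernst potentials is evaluated from scipy's physical constants at a
default 22 °C (room-temperature recordings); the default pipette K⁺ is
130.5 mM (121.5 K-methanesulfonate + 9 KCl, ignoring the KOH titration).

## Capacitive-transient analysis

Sweeps are averaged (typically 100–200), the steady-state current is
estimated from the final 20 % of the step and then refined as the
asymptote of a single-exponential-plus-offset least-squares fit starting
at the transient extremum — the raw tail mean is biased high when τ is a
sizeable fraction of the step, and the three-parameter fit removes that
bias (relevant above ~200 MΩ·30 pF). The transferred charge Q is the
trapezoidal integral of the steady-state-subtracted current over the
step; C_m = Q/|ΔV|, R_series = τ/C_m. τ comes from the fit, not a 1/e
reading. The truncation error from ending the integral at the step end
is e^(−T/τ), < 0.5 % for all supported regimes.

A population-level caveat: computing R_series from the *means* of τ and
C_m is not the same as averaging per-recording R_series (169 vs ~180 MΩ
for typical whole-cilium values); the package always reports
per-recording estimates and leaves population averaging to the caller.

## Leak subtraction

Three consecutive responses to a hyperpolarizing control step are
summed, inverted, scaled by ΔV_test/(3|ΔV_leak|) and subtracted.
Linearity makes this exact for any passive circuit, which is the
invariant the tests assert (to the 1 µV tolerance of the simulator's
series-resistance solver, ≲0.01 pA). Traces may optionally be pre-step
baseline-zeroed inside `subtract_leak` (`baseline_samples`); the
generators emit amplifier-zeroed traces so the default is no re-zeroing.

## Single channels

Gating is a two-state (closed ⇌ open) continuous-time Markov chain with
stationary P_o = k_open/(k_open + k_close). Rates are free parameters;
`GatingModel.from_p_open(p, total_rate=50.0)` picks them at a default
50 s⁻¹ rate sum (mean cycle ~90 ms), consistent with the long
potentiated openings seen with BayK8644-class agonists. A zero rate
makes the corresponding state absorbing. P_o is estimated as the
time-averaged current divided by the unitary amplitude; with nine 400 ms
pulses the sampling SE of this estimate is ~0.05, so recovery is asserted
within 3 SE rather than a fixed percentage. Open-point histograms use
the conventional 0.9 fractional-amplitude criterion (1.26 pA threshold
for a 1.4 pA channel).

Amplitude histogram bins default to 0.05 pA (≈ unitary amplitude / 28).
Single-channel records carry 0.2 pA RMS noise by default, standing for
1 kHz-filtered data; whole-cell sweeps carry 1 pA RMS. Neither value is
a measured property — both are configurable and chosen to visually match
published traces.

## Ca_V current simulation and series-resistance distortion

Activation is a Boltzmann steady state, g_inf(V) = g_max/(1 +
exp(−(V−V_half)/s)), with first-order kinetics (default τ_act 3 ms,
V_half −10 mV, s 7 mV, E_rev +60 mV — generic L-type-like values; the
model exists as a forward model for the analysis, not as a fitted
channel model). With series-resistance distortion enabled, V_m is solved
quasi-statically at each time step from V_m = V_cmd − I(V_m)·R_series by
damped fixed-point iteration (damping 0.5, tolerance 1 µV, 100
iterations max); non-convergence raises a stability error, which is the
loss-of-clamp regime at extreme g_max·R_series. The capacitive transient
is deliberately not part of this generator (the RC generator owns it).
The truth record stores the undistorted (V_m ≡ V_cmd) family, so tests
can assert the hyperpolarized shift of the apparent IV peak.

## Ratiometric calibration and bleed-through

Pipeline order: saturation mask → background subtraction → ratio →
low-signal mask. The mask comes from the red (Ca²⁺-insensitive) channel:
threshold ≤ red < saturation. Ratios are per-pixel (G−bg)/(R−bg) with a
denominator floor of 1 % of the red channel's background-subtracted
maximum; pixels at or below the floor are dropped and counted. The
per-cell ratio averages all masked pixels of all cilia, not per-cilium
means.

Under non-sequential (simultaneous) scanning a fraction α of the green
emission leaks into the red detector. α is estimated by ordinary least
squares of red-channel signal vs green signal in a specimen expressing
only the green indicator, and the correction applied is the subtractive
A_c = R − α. This is a first-order correction: with physical green→red
leak the exact raw ratio is r/(1 + αr), so A_c carries a bias of order
αr² plus the curvature mismatch. Because calibration and measurement
pass through the same transform, the bias largely cancels on inversion:
end-to-end [Ca²⁺] recovery stays within a few percent at mid-range,
while the *Hill parameters* fitted from non-sequential data are shifted
by ~α. Sequential-mode calibrations (immobilized cilia, no bleed) use
raw ratios and recover the generator's Hill truth exactly; parameter-
recovery tests therefore run in sequential mode.

The Hill fit is bounded least squares (R_min ≥ 0, n_H ∈ (0.3, 6)) over
at least five concentration levels; inversion is analytic,
[Ca] = EC50·((A_c−R_min)/(R_max−A_c))^(1/n_H), and refuses ratios outside
(R_min, R_max) with an explicit out-of-dynamic-range error. Near the
asymptotes the inversion is ill-conditioned by construction — at 10 µM
on a 300 nM-EC50 curve the ratio sits within one noise width of R_max,
so the pipeline reports "deep saturation" (a value far above EC50) or
fails loudly; tests assert exactly that, not a percentage.

The default generator truth pins the basal operating point of ependymal
cilia: R_min 0.05, R_max 1.2, n_H 2, EC50 426 nM, so that 165 nM free
Ca²⁺ maps to a corrected ratio of 0.200. Calibration stacks span
50 nM–10 µM with 5 stacks per level and 3 cilia per stack, painted as
anti-aliased Gaussian-profile curves (σ ≈ 1 px) at 0.1 µm/px with
Poisson shot noise plus Gaussian read noise (SD 2 counts).

## Kymographs and beat frequency

Kymographs are built by bilinear interpolation along a polyline
(pixel-center, 0-based coordinates), optionally averaged across a
perpendicular width. Beat frequency counts peaks of the line-integrated
intensity trace per window: prominence ≥ 25 % of the window amplitude,
minimum spacing from a 25 Hz ceiling. Counting quantizes to 1 peak per
window — ±0.5 Hz resolution over a 2 s window, ±1 Hz over 1 s — and the
tolerances in the tests are set by that quantization. Halted cilia are
detected against a noise floor estimated robustly from first differences
(MAD); the gate adapts to window length as 2√(2 ln n)+2 SDs, since the
expected peak-to-peak excursion of pure noise grows with n.

The beating-stack generator renders a base-anchored cilium whose bend
oscillates sinusoidally; the analysis line in its truth record lies at
the stroke extreme near the tip, so line intensity peaks exactly once
per cycle. A frequency schedule supports mid-record changes (solution
exchanges). Frame rates below 4× the beat frequency are refused.

## Ca²⁺ front propagation

Line-scan analysis: per-position crossing time is the first frame where
ΔF exceeds 50 % of that position's plateau ΔF (plateau = mean of the
final 20 % of the record); the stimulus time defaults to the maximum
temporal derivative at the base. The apparent velocity is the
least-squares slope of position vs crossing time over the distal half of
the span (the fraction is configurable; distal analysis avoids the mixed
kinetics near the base). If all positions cross within one frame the
wave is unresolved and the span/frame-interval lower bound is reported
with a flag.

The generator has two modes. Constant velocity: a symmetric sigmoidal
rise whose 50 % crossing is exactly at x/v after the stimulus, so
recovery is exact up to frame quantization. Diffusion: ∂C/∂t = D∂²C/∂x²
solved by sub-stepped FTCS (λ ≤ 0.4) with the base clamped to the
reservoir and a sealed (reflecting) tip — the physically correct
finite-cilium boundary, which also makes per-position plateaus converge
to the reservoir level. Crossing times then follow the semi-infinite
t ∝ x² law until the tip's image contribution is felt; the quadratic
exponent holds cleanly for x ≲ 0.4·L, which is the span the tests fit
(1.5–4.5 µm of an 11.5 µm cilium). D defaults to 250 µm²/s, which
carries a half-maximum front to the tip in ~0.6 s, the observed
timescale for cytoplasm-to-tip equilibration. Indicator kinetics can be
layered on as a single configurable low-pass stage; they are not fitted,
because indicator-dependent rise times are exactly what precludes onset
comparisons in real data.

## Bead velocimetry

Detections are linked frame-to-frame by greedy nearest neighbour
(shortest distance first, gate distance configurable); global assignment
is unnecessary for sparse, fast, unidirectional bead fields, and the
gate prevents identity swaps at crossings. Tracks shorter than 4 frames
are discarded and counted. Speed is pathwise (total path length over
elapsed time), matching what manual frame-by-frame tracking reports; the
displacement-based alternative is exposed. Pathwise speed is biased
upward for jittery near-stationary beads by the expected step length of
2-D Gaussian noise (σ√(2)·√(π/2) per frame interval) — documented, and
asserted as the jitter floor in the tests. At jitter ≤ 10 % of the
per-frame displacement the relative bias is ≲1 %, well inside the 5 %
recovery tolerance.

The generator drifts beads along one direction at per-bead speeds drawn
with 15 % coefficient of variation around the condition mean (default
86 µm/s), with staggered entry and exit so short-lived beads occur
naturally; localization jitter is isotropic Gaussian.

## Determinism

Every generator draws from a stream derived from (master seed,
crc32(generator label), per-label call counter) via numpy
`SeedSequence`, so a fresh `SimConfig` with the same seed replays
byte-identical outputs regardless of which other generators ran. Truth
records accompany every artifact; analysis tests compare against truth
records, not embedded constants.

## Problem sizes

The shipped tests and the acceptance script run everything at the
study's own scales: 150-sweep transient averages, nine 400 ms
single-channel pulses (the acceptance script averages eight such
simulated patches to reduce Monte-Carlo scatter of the short protocol),
35 calibration stacks over seven [Ca²⁺] levels, 2 s of 200 fps beating
video, 1.5 s line scans at 500–1000 Hz, and ~20 beads over 4 s at
100 fps.

## Known limitations

* The cilium is lumped, not a distributed cable; intra-ciliary voltage
  gradients are outside the model.
* The subtractive bleed-through correction is first-order (see above);
  spectral unmixing would be exact but is not what the measurement
  convention uses.
* No motion correction or registration: the simulated stacks do not
  emulate beating-induced channel offsets, which real non-sequential
  scanning exists to avoid.
* Bead detection from raw video is out of scope; the tracker consumes
  detections (from the generator or an external detector).
* No hydrodynamics: flow is measured, not modelled, and metachronal
  coordination between cilia is not simulated.
* Synthetic noise magnitudes are plausible defaults, not measured
  values; passing recovery tests demonstrates correctness of the
  estimators under the stated noise models, not performance on any
  particular microscope or amplifier.
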