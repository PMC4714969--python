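# ciliaphys

Quantitative analysis of motile-cilia electrophysiology, ciliary Ca²⁺
imaging and cilia-driven flow, for ependymal cells and similar
multiciliated epithelia.

Motile cilia of brain ependymal cells beat at ~5–20 Hz and drive
cerebrospinal-fluid flow. Patch clamping a single motile cilium
("whole-cilium" access: break-in at the ciliary tip) reaches the cell
interior through the cilium, which acts as a thin series cable; ciliary
Ca²⁺ can be read out with a cilia-targeted ratiometric sensor
(GCaMP6s/mCherry); beating and flow are measured from high-speed movies.
`ciliaphys` implements the complete measurement chain for these
experiments, together with forward models that generate every input with
known ground truth, so each analysis stage is testable without raw
recordings.

## What it computes

**Equivalent-circuit model** (`ciliaphys.circuit`). The cilium is a
cylinder of radius r and length h: membrane area A = 2πr(r + h),
capacitance C = A·c_m (c_m ≈ 1 µF/cm²), axial cable resistance
R = ρl/(πr²). Whole-cilium clamp dynamics follow τ = R_series·C_m and
the command-voltage error V_m = V_cmd − I·R_series. Channel counts from
whole-cell current and single-channel properties: N = I_m/(P_o·i), scaled
to the cilium by the capacitance (area) ratio. Nernst potentials
(RT/zF)·ln([out]/[in]) for ion-substitution experiments.

**Sweep analysis** (`ciliaphys.ephys`). P/3-style leak subtraction from
three hyperpolarizing control pulses; capacitive-transient analysis
(charge Q by integration, C_m = Q/ΔV, τ by exponential fit,
R_series = τ/C_m); steady-state and peak IV curves; zero-phase Gaussian
low-pass filtering; all-point/open-point amplitude histograms (0.9
fractional-amplitude criterion); open probability P_o = ⟨I⟩/i.

**Ratiometric Ca²⁺** (`ciliaphys.calcium`). Cilium masks from the red
reference channel, background-subtracted ratio images, green→red
bleed-through correction A_c = R − α (α from a linear fit on a red-free
specimen), Hill calibration
A_c = R_min + (R_max−R_min)[Ca]ⁿ/(EC50ⁿ + [Ca]ⁿ) against buffers of known
free [Ca²⁺], and its analytic inversion to report ciliary [Ca²⁺] in nM.

**Motility and flow** (`ciliaphys.motility`). Kymograph reslicing along
a user line, beat frequency by peak counting per time window, Ca²⁺-front
velocity from line-scan crossing times (distal-span fit), and bead
velocimetry with greedy nearest-neighbour track linking (tracks < 4
frames rejected).

**Synthetic data** (`ciliaphys.synthetic`). Exact RC-circuit sweeps (with
an independent ODE oracle), two-state Markov single-channel records,
Ca_V current families with self-consistent series-resistance distortion,
two-channel calibration stacks, beating movies, diffusive/constant-speed
front line scans, and drifting-bead fields — all seeded and
bit-reproducible, each with a machine-readable truth record.

## Worked example

```python
from ciliaphys import circuit, ephys, synthetic

# the standard ependymal cilium
geom = circuit.CiliumGeometry(length=11.5, radius=0.125)     # µm
area = circuit.cylinder_surface_area(geom)                   # 9.13 µm²
c_cil = circuit.membrane_capacitance_from_area(area)         # 0.0913 pF
r_cable = circuit.cable_resistance(geom)                     # 351.4 MΩ

# how many Ca_V channels would a cilium hold at uniform density?
n_cell = circuit.channels_per_cell(
    circuit.ChannelCountInputs(I_m=297.8, P_o=0.32, i_single=1.4))  # 664.7
n_cil = circuit.channels_per_cilium(n_cell, c_cil, 18.5)            # ~3.3

# recover circuit parameters from simulated capacitive transients
circ = circuit.EquivalentCircuit(C_m=18.5, R_series=180.0)
protocol = ephys.StepProtocol(holding_mV=-80, step_mV=-20, t_on=0.01, t_off=0.06)
sweeps, _ = synthetic.simulate_patch_recording(circ, protocol, n_sweeps=150,
                                               cfg=synthetic.SimConfig(seed=1))
fit = ephys.analyze_capacitive_transient(sweeps)
print(f"C_m={fit.C_m_pF:.1f} pF  tau={fit.tau_ms:.2f} ms  "
      f"R_s={fit.R_series_MOhm:.0f} MΩ")
```

prints

```
C_m=18.5 pF  tau=3.33 ms  R_s=180 MΩ
```

i.e. an 18.5 pF cell reached through a 180 MΩ ciliary access resistor
charges with a 3.3 ms lag — an order of magnitude slower than direct
whole-cell access, which is the electrical signature of recording through
a motile cilium.

A thin CLI mirrors the library: `ciliaphys circuit derive`,
`ciliaphys calcium bleedthrough|calibrate|quantify`,
`ciliaphys motility cbf|front|beads`, `ciliaphys sim patch|beating`.

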