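"""Equivalent-circuit model of an ependymal cell accessed through a motile cilium.

A motile cilium is a thin (~0.25 µm diameter, ~11.5 µm long) membrane
cylinder.  When the whole-cell configuration is established by rupturing
the membrane at the ciliary tip ("whole-cilium" access), the cilium acts
as a lumped series resistor between pipette and cell: clamp speed slows to
τ = R_series·C_m and the command voltage carries an error I·R_series.
This module collects the closed-form quantities derived from that picture:
cilium surface area and capacitance, cable (axial) resistance, channel
counts from whole-cell current and single-channel properties, the clamp
time constant, the series-resistance voltage error, and Nernst potentials.

All functions are deterministic and vectorize over numpy arrays where the
formula permits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units


class InvalidGeometryError(ValueError):
    """Raised for non-physical cilium dimensions."""


@dataclass(frozen=True)
class CiliumGeometry:
    """Cylinder idealization of a motile cilium.

    Parameters
    ----------
    length : float
        Cilium length in µm (default 11.5, the average for ependymal
        motile cilia).
    radius : float
        Cilium radius in µm (default 0.125, i.e. 0.25 µm diameter).
    """

    length: float = 11.5
    radius: float = 0.125

    def __post_init__(self) -> None:
        if self.length <= 0 or self.radius <= 0:
            raise InvalidGeometryError(
                f"length and radius must be positive, got {self.length}, {self.radius}"
            )
        if self.radius >= self.length:
            raise InvalidGeometryError("radius must be smaller than length")


@dataclass(frozen=True)
class MembraneConstants:
    """Membrane and cytoplasm constants.

    specific_capacitance in µF/cm² (≈1 for biological membranes),
    axial_resistivity in Ω·cm (≈150, cytoplasmic value; the true internal
    resistivity of a cilium is unknown and stays a free parameter),
    temperature in °C (room temperature by default).
    """

    specific_capacitance: float = 1.0
    axial_resistivity: float = 150.0
    temperature: float = 22.0

    def __post_init__(self) -> None:
        if min(self.specific_capacitance, self.axial_resistivity) <= 0:
            raise ValueError("membrane constants must be strictly positive")
        if units.celsius_to_kelvin(self.temperature) <= 0:
            raise ValueError("temperature below absolute zero")


@dataclass(frozen=True)
class EquivalentCircuit:
    """Lumped circuit: series access resistor into a parallel R_m‖C_m membrane.

    C_m in pF, R_m in MΩ (``math.inf`` for an ideally sealed membrane),
    R_series in MΩ, holding potential in mV.
    """

    C_m: float
    R_series: float
    R_m: float = math.inf
    V_hold: float = -80.0

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.R_series <= 0:
            raise ValueError("R_series must be positive")
        if self.R_m <= 0:
            raise ValueError("R_m must be positive (use math.inf for ideal seal)")


@dataclass(frozen=True)
class ChannelCountInputs:
    """Inputs for the channel-count estimate N = I_m / (P_o · i).

    I_m: mean peak whole-cell current (pA) at the reference voltage;
    P_o: single-channel open probability; i_single: unitary current (pA);
    C_cell / C_cilium: capacitances (pF) standing in for the surface areas.
    """

    I_m: float
    P_o: float
    i_single: float
    C_cell: float = 18.5
    C_cilium: float = 0.091

    def __post_init__(self) -> None:
        if not 0 < self.P_o <= 1:
            raise ValueError(f"P_o must lie in (0, 1], got {self.P_o}")
        if self.i_single == 0:
            raise ZeroDivisionError("i_single must be nonzero")
        if self.I_m != 0 and np.sign(self.I_m) != np.sign(self.i_single):
            raise ValueError("I_m and i_single must carry the same sign")
        if not self.C_cilium < self.C_cell:
            raise ValueError("C_cilium must be smaller than C_cell")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def cylinder_surface_area(geom: CiliumGeometry | None = None, *,
                          radius: float | None = None,
                          height: float | None = None) -> float:
    """Surface area of a cylinder, A = 2πr(r + h), in µm².

    The two end caps are included (2πr² term); for a cilium the cap
    contribution is negligible next to the shaft.  ``height`` may be 0,
    in which case the area degenerates to the two caps.
    """
    if geom is not None:
        r, h = geom.radius, geom.length
    else:
        if radius is None or height is None:
            raise TypeError("pass a CiliumGeometry or radius= and height=")
        r, h = radius, height
        if r <= 0 or h < 0:
            raise InvalidGeometryError("radius must be > 0 and height >= 0")
    return 2.0 * math.pi * r * (r + h)


def membrane_capacitance_from_area(area_um2: float,
                                   k: MembraneConstants | None = None) -> float:
    """Membrane capacitance in pF for a surface area in µm².

    With the textbook 1 µF/cm², 1 µm² carries 0.01 pF.
    """
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    k = k or MembraneConstants()
    return area_um2 * k.specific_capacitance * units.UF_PER_CM2_TO_PF_PER_UM2


def cable_resistance(geom: CiliumGeometry | None = None,
                     k: MembraneConstants | None = None, *,
                     length: float | None = None,
                     radius: float | None = None) -> float:
    """Axial resistance of the cilium treated as an insulated cable, in MΩ.

    R = ρ·l / (πr²) with ρ the internal resistivity (Ω·cm), l the length
    and πr² the *cross-sectional* area.  ``length`` may be 0 (R = 0).
    """
    k = k or MembraneConstants()
    if geom is not None:
        l_um, r_um = geom.length, geom.radius
    else:
        if length is None or radius is None:
            raise TypeError("pass a CiliumGeometry or length= and radius=")
        l_um, r_um = length, radius
    if r_um <= 0:
        raise InvalidGeometryError("radius must be positive")
    rho_si = k.axial_resistivity * units.OHM_CM            # Ω·m
    area_si = math.pi * (r_um * units.UM) ** 2             # m²
    r_ohm = rho_si * (l_um * units.UM) / area_si
    return r_ohm / units.MOHM


def channels_per_cell(inp: ChannelCountInputs) -> float:
    """Total channel count N = I_m / (P_o · i_single).

    Read as the dimensionally sensible parse of "N = I_m/P_o(i)":
    the mean current divided by the mean current carried by one channel.
    Returned unrounded; rounding is the caller's choice.
    """
    return inp.I_m / (inp.P_o * inp.i_single)


def channels_per_cilium(n_cell: float, c_cilium_pf: float, c_cell_pf: float) -> float:
    """Scale a per-cell channel count by the cilium/cell area ratio.

    Capacitance stands in for area (both compartments share the same
    specific capacitance, so C ∝ A).
    """
    if c_cell_pf == 0:
        raise ZeroDivisionError("cell capacitance must be nonzero")
    return n_cell * c_cilium_pf / c_cell_pf


def membrane_voltage(v_command_mv, i_m_pa, r_series_mohm: float):
    """Actual membrane voltage under series resistance, V_m = V_cmd − I·R_s.

    Inward current is negative, so an inward current drives V_m positive
    of the command — the clamp error grows with current amplitude.
    Accepts scalars or arrays (mV, pA, MΩ → mV).
    """
    return np.asarray(v_command_mv) - np.asarray(i_m_pa) * r_series_mohm * 1e-3


def clamp_time_constant(c: EquivalentCircuit, *, ideal: bool = False) -> float:
    """Voltage-clamp charging time constant in ms.

    Full model: τ = C_m · (R_series‖R_m).  With ``ideal=True`` (or
    R_m = ∞) this reduces to the familiar τ = R_series·C_m.
    """
    if ideal or math.isinf(c.R_m):
        r_eff = c.R_series
    else:
        r_eff = c.R_series * c.R_m / (c.R_series + c.R_m)
    return units.tau_ms(r_eff, c.C_m)


def nernst_potential(ion_out_mm: float, ion_in_mm: float, valence: int = 1,
                     temperature_c: float = 22.0) -> float:
    """Nernst equilibrium potential (RT/zF)·ln([out]/[in]) in mV.

    Defaults are tuned for K⁺ at room temperature; e.g. 3 mM external /
    130.5 mM pipette K⁺ gives ≈ −96 mV.
    """
    if ion_out_mm <= 0 or ion_in_mm <= 0:
        raise ValueError("ion concentrations must be strictly positive")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    t_k = units.celsius_to_kelvin(temperature_c)
    volts = (units.GAS_CONSTANT * t_k / (valence * units.FARADAY)) * math.log(
        ion_out_mm / ion_in_mm
    )
    return volts / units.MV


@dataclass(frozen=True)
class CircuitDerivation:
    """Bundle of every derived quantity for one geometry/circuit configuration."""

    area_um2: float
    c_cilium_pF: float
    cable_R_MOhm: float
    tau_ms: float
    n_channels_cell: float
    n_channels_cilium: float
    E_K_mV: float


def derive_all(geom: CiliumGeometry | None = None,
               k: MembraneConstants | None = None,
               counts: ChannelCountInputs | None = None,
               r_series_mohm: float = 180.0,
               k_out_mm: float = 3.0,
               k_in_mm: float = 130.5) -> CircuitDerivation:
    """Convenience: compute the full derived-quantity table with one call."""
    geom = geom or CiliumGeometry()
    k = k or MembraneConstants()
    counts = counts or ChannelCountInputs(I_m=297.8, P_o=0.32, i_single=1.4)
    area = cylinder_surface_area(geom)
    c_cil = membrane_capacitance_from_area(area, k)
    n_cell = channels_per_cell(counts)
    circ = EquivalentCircuit(C_m=counts.C_cell, R_series=r_series_mohm)
    return CircuitDerivation(
        area_um2=area,
        c_cilium_pF=c_cil,
        cable_R_MOhm=cable_resistance(geom, k),
        tau_ms=clamp_time_constant(circ),
        n_channels_cell=n_cell,
        n_channels_cilium=channels_per_cilium(n_cell, c_cil, counts.C_cell),
        E_K_mV=nernst_potential(k_out_mm, k_in_mm, 1, k.temperature),
    )
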