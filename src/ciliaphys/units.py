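"""Unit conversion table.

All public functions in this package accept and return the units customary
in patch-clamp and cilia-imaging work (pA, pF, MΩ, mV, ms, µm, nM).
Internally, derived quantities are computed in SI and converted at the
boundary through the constants below, so every conversion lives in exactly
one place.
"""

from __future__ import annotations

from scipy import constants as _const

# --- physical constants (SI) -------------------------------------------------
FARADAY = _const.physical_constants["Faraday constant"][0]  # C/mol
GAS_CONSTANT = _const.R  # J/(mol K)
ZERO_CELSIUS = 273.15  # K

# --- multiplicative factors to SI --------------------------------------------
PA = 1e-12      # pA -> A
PF = 1e-12      # pF -> F
MOHM = 1e6      # MΩ -> Ω
MV = 1e-3       # mV -> V
MS = 1e-3       # ms -> s
UM = 1e-6       # µm -> m
NM_CONC = 1e-9  # nM -> mol/L

# specific capacitance: 1 µF/cm² expressed in pF/µm²
UF_PER_CM2_TO_PF_PER_UM2 = 0.01

# resistivity: 1 Ω·cm in Ω·m
OHM_CM = 1e-2


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + ZERO_CELSIUS


def tau_ms(r_mohm: float, c_pf: float) -> float:
    """RC product in ms from resistance in MΩ and capacitance in pF.

    1 MΩ · 1 pF = 1 µs, hence the factor 1e-3.
    """
    return r_mohm * c_pf * 1e-3


def rseries_mohm(tau_in_ms: float, c_pf: float) -> float:
    """Series resistance in MΩ from a time constant in ms and C in pF."""
    return 1e3 * tau_in_ms / c_pf
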