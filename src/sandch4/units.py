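"""Unit conversions used throughout the package.

Every numeric conversion factor lives here so that no module carries its own
silent factors. Internally the package works in SI-adjacent units (kelvin,
mol, litre, atm, hour); presentation-layer helpers convert to the units the
marine-methane literature prints (nM, %, cm h^-1, mg m^-2 d^-1, g m^-2 h^-1).
"""

from __future__ import annotations

# Physical constants
R_L_ATM = 0.082057366  # gas constant, L atm mol^-1 K^-1
MOLAR_VOLUME_STP_L = 22.414  # ideal-gas molar volume at STP (0 degC, 1 atm), L mol^-1
MOLAR_MASS_CH4 = 16.04  # g mol^-1
RN222_HALF_LIFE_DAYS = 3.8235  # radon-222 half-life

ZERO_CELSIUS_K = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + ZERO_CELSIUS_K


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - ZERO_CELSIUS_K


def ppb_to_fraction(ppb: float) -> float:
    return ppb * 1e-9


def ppm_to_fraction(ppm: float) -> float:
    return ppm * 1e-6


def mol_per_L_to_nM(c: float) -> float:
    return c * 1e9


def nM_to_mol_per_L(c_nM: float) -> float:
    return c_nM * 1e-9


def uM_to_mol_per_L(c_uM: float) -> float:
    return c_uM * 1e-6


def cm_per_h_to_m_per_day(k_cm_h: float) -> float:
    return k_cm_h * 0.01 * 24.0


def umol_per_cm2_h_to_mmol_per_m2_h(f: float) -> float:
    # 1 umol cm^-2 = 1e-6 mol * 1e4 per m^2 = 1e-2 mol m^-2 = 10 mmol m^-2
    return f * 10.0


def mmol_to_g(mmol: float, molar_mass: float) -> float:
    return mmol * molar_mass / 1000.0
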