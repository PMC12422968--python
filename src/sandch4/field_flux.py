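"""Sea-air methane flux from surface-water measurements.

The diffusive sea-air flux follows the standard bulk parameterization

    F = k * (C - C_eq)            (concentration form, default)
    F = k * K0 * (p_w - p_a)      (partial-pressure form)

where ``k`` is the wind-driven gas transfer (piston) velocity

    k = 0.251 * U10 * (Sc/660)^-0.5   (cm h^-1, U10 in m s^-1)

normalized by the Schmidt number ``Sc`` to the CO2-at-20-degC seawater
reference of 660. Flux bounds combine the wind-speed quartiles of an annual
record with the lowest/average/highest observed concentrations. A radon
utility applies the 222Rn decay correction used when radon is employed as a
groundwater tracer.

The 0.251 coefficient originates from a quadratic (U10^2) wind-speed
parameterization; the linear form is provided as the default mode and the
quadratic form is available via ``exponent_mode`` (see methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import units
from .gas_solubility import (
    AtmosphereSpec,
    SeawaterConditions,
    SolubilityConstants,
    aqueous_solubility_K0,
    equilibrium_concentration,
)
from .units import MOLAR_MASS_CH4, RN222_HALF_LIFE_DAYS

__all__ = [
    "WindRecord",
    "FluxEstimate",
    "RadonSample",
    "schmidt_number",
    "gas_transfer_velocity",
    "sea_air_flux",
    "flux_bounds",
    "radon_decay_correct",
]

# Third-order Schmidt-number polynomials for CH4 (Wanninkhof 1992 lineage,
# as implemented by the marelac gas_schmidt function):
# Sc = a - b*t + c*t^2 - d*t^3 with t in degC, valid 0-30 degC.
_SC_CH4_SEAWATER = (2039.2, 120.31, 3.4209, 0.040437)  # S = 35
_SC_CH4_FRESHWATER = (1897.8, 114.28, 3.2902, 0.039061)  # S = 0
_SC_FIT_RANGE_C = (0.0, 30.0)
SCHMIDT_REFERENCE = 660.0  # CO2 in seawater at 20 degC


@dataclass(frozen=True)
class WindRecord:
    """Wind speeds at 10 m (m s^-1), e.g. a twice-daily annual record."""

    timestamps: np.ndarray
    u10: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u10, dtype=float)
        if u.size == 0:
            raise ValueError("wind record is empty")
        if (u < 0).any():
            raise ValueError("wind speeds must be non-negative")

    def quartiles(self) -> tuple[float, float, float]:
        """(Q1, median, Q3) using the linear-interpolation (type-7) convention."""
        q1, q2, q3 = np.quantile(np.asarray(self.u10, dtype=float), [0.25, 0.5, 0.75])
        return float(q1), float(q2), float(q3)


@dataclass(frozen=True)
class FluxEstimate:
    """One sea-air flux estimate with the quantities that produced it."""

    k_m_per_s: float
    K0_mol_per_L_atm: float
    delta_c_mol_per_L: float
    flux_mg_m2_day: float
    scenario: str = "mid"
    quartile_convention: str = "linear-interpolation (type 7)"


@dataclass(frozen=True)
class RadonSample:
    """A 222Rn activity (Bq m^-3) measured ``elapsed_days`` after collection."""

    activity: float
    elapsed_days: float


def _sc_poly(coeffs: tuple[float, float, float, float], t_c: float) -> float:
    a, b, c, d = coeffs
    return a - b * t_c + c * t_c**2 - d * t_c**3


def schmidt_number(cond: SeawaterConditions) -> float:
    """Schmidt number of CH4 in (sea)water at the given conditions.

    Evaluates the seawater (S=35) polynomial and interpolates linearly to
    the freshwater polynomial for brackish salinities.
    """
    t_c = units.kelvin_to_celsius(cond.temperature)
    lo, hi = _SC_FIT_RANGE_C
    if not lo <= t_c <= hi:
        raise ValueError(
            f"temperature {t_c:.2f} degC outside Schmidt-polynomial validity [{lo}, {hi}]"
        )
    sc_fresh = _sc_poly(_SC_CH4_FRESHWATER, t_c)
    sc_sea = _sc_poly(_SC_CH4_SEAWATER, t_c)
    w = min(cond.salinity, 35.0) / 35.0
    return (1.0 - w) * sc_fresh + w * sc_sea


def gas_transfer_velocity(
    u10: float, sc: float, exponent_mode: str = "as-printed"
) -> float:
    """Gas transfer velocity k (cm h^-1) from wind speed and Schmidt number.

    ``exponent_mode='as-printed'`` uses k = 0.251*U10*(Sc/660)^-0.5 (linear
    in U10); ``'quadratic'`` uses U10^2, the form the 0.251 coefficient was
    originally fit with.
    """
    if u10 < 0:
        raise ValueError("wind speed must be non-negative")
    if exponent_mode == "as-printed":
        g = u10
    elif exponent_mode == "quadratic":
        g = u10 * u10
    else:
        raise ValueError(f"unknown exponent mode {exponent_mode!r}")
    return 0.251 * g * (sc / SCHMIDT_REFERENCE) ** -0.5


def sea_air_flux(
    concentration: float,
    cond: SeawaterConditions,
    atm: AtmosphereSpec,
    u10: float,
    consts: SolubilityConstants,
    exponent_mode: str = "as-printed",
    form: str = "concentration",
    molar_mass: float = MOLAR_MASS_CH4,
    scenario: str = "mid",
) -> FluxEstimate:
    """Sea-air flux (mg m^-2 day^-1) of a dissolved gas.

    ``form='concentration'`` computes F = k*(C - C_eq); ``'partial-pressure'``
    computes F = k*K0*(p_w - p_a) with p_w = C/K0 and p_a the moist-air
    partial pressure. The two agree identically at equilibrium and to
    within the humidity convention away from it.
    """
    if concentration < 0:
        raise ValueError("dissolved concentration must be non-negative")
    sc = schmidt_number(cond)
    k_cm_h = gas_transfer_velocity(u10, sc, exponent_mode)
    k_m_day = units.cm_per_h_to_m_per_day(k_cm_h)
    c_eq = equilibrium_concentration(cond, atm, consts)
    k0 = aqueous_solubility_K0(cond, consts)
    if form == "concentration":
        delta_c = concentration - c_eq  # mol L^-1
    elif form == "partial-pressure":
        p_w = concentration / k0
        p_a = c_eq / k0  # moist-corrected atmospheric partial pressure
        delta_c = k0 * (p_w - p_a)
    else:
        raise ValueError(f"unknown flux form {form!r}")
    # mol L^-1 -> mol m^-3 (x1000); * m day^-1 -> mol m^-2 day^-1; -> mg
    flux_mg = k_m_day * (delta_c * 1000.0) * molar_mass * 1000.0
    return FluxEstimate(
        k_m_per_s=k_m_day / 86400.0,
        K0_mol_per_L_atm=k0,
        delta_c_mol_per_L=delta_c,
        flux_mg_m2_day=flux_mg,
        scenario=scenario,
    )


def flux_bounds(
    concentrations: "np.ndarray | list[float]",
    cond: SeawaterConditions,
    atm: AtmosphereSpec,
    wind: WindRecord,
    consts: SolubilityConstants,
    exponent_mode: str = "as-printed",
) -> dict[str, FluxEstimate]:
    """Low/mid/high flux scenarios from a survey and an annual wind record.

    low = lowest concentration with Q1 wind, mid = mean concentration with
    median wind, high = highest concentration with Q3 wind.
    """
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise ValueError("survey concentration list is empty")
    q1, q2, q3 = wind.quartiles()
    pairs = {
        "low": (float(c.min()), q1),
        "mid": (float(c.mean()), q2),
        "high": (float(c.max()), q3),
    }
    return {
        name: sea_air_flux(
            conc, cond, atm, u, consts, exponent_mode=exponent_mode, scenario=name
        )
        for name, (conc, u) in pairs.items()
    }


def radon_decay_correct(sample: RadonSample) -> float:
    """222Rn activity decay-corrected back to collection time (Bq m^-3)."""
    if sample.elapsed_days < 0:
        raise ValueError("elapsed time since collection must be non-negative")
    lam = math.log(2.0) / RN222_HALF_LIFE_DAYS
    return sample.activity * math.exp(lam * sample.elapsed_days)
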