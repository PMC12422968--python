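"""Dissolved-gas solubility in seawater and percent saturation.

Implements the Bunsen-coefficient formulation used throughout marine
dissolved-methane work: a temperature/salinity exponential fit
(Wiesenburg & Guinasso 1979 lineage) gives the volumetric solubility
``beta``, the atmospheric equilibrium concentration follows

    C_eq = beta * (1 - P_vp) * f_G / V_STP

with ``P_vp`` the vapour pressure of the solution (atm) and ``f_G`` the dry
atmospheric mole fraction of the gas, and percent saturation is
100 * C / C_eq. Constants are shipped as a versioned YAML file keyed by gas
id and unit convention so further gases can be added without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from . import units
from .units import MOLAR_VOLUME_STP_L

__all__ = [
    "SeawaterConditions",
    "SolubilityConstants",
    "AtmosphereSpec",
    "SaturationResult",
    "load_constants",
    "bunsen_coefficient",
    "seawater_vapor_pressure",
    "equilibrium_concentration",
    "aqueous_solubility_K0",
    "percent_saturation",
]

# Default Southern-Hemisphere atmospheric CH4 dry mole fraction (ppb) and
# the reported annual variability used for uncertainty propagation.
DEFAULT_ATM_CH4_PPB = {"southern": 1800.0, "northern": 1900.0}
DEFAULT_ATM_CH4_PPB_SD = 15.0


@dataclass(frozen=True)
class SeawaterConditions:
    """Temperature (K), practical salinity (ppt) and total pressure (atm).

    Temperature may be supplied in Celsius via :meth:`from_celsius`; the
    class itself always stores kelvin.
    """

    temperature: float
    salinity: float
    pressure: float = 1.0

    def __post_init__(self) -> None:
        if not 270.0 < self.temperature < 320.0:
            raise ValueError(
                f"temperature {self.temperature} K outside accepted range (270, 320) K"
            )
        if not 0.0 <= self.salinity <= 45.0:
            raise ValueError(f"salinity {self.salinity} ppt outside accepted range [0, 45]")
        if self.pressure <= 0:
            raise ValueError(f"pressure must be positive, got {self.pressure} atm")

    @classmethod
    def from_celsius(cls, t_c: float, salinity: float, pressure: float = 1.0) -> "SeawaterConditions":
        return cls(units.celsius_to_kelvin(t_c), salinity, pressure)


@dataclass(frozen=True)
class SolubilityConstants:
    """Empirical fit constants A1..A3(,A4), B1..B3 for one gas and convention."""

    gas_id: str
    A1: float
    A2: float
    A3: float
    B1: float
    B2: float
    B3: float
    A4: float = 0.0
    unit_convention: str = "bunsen"

    _CONVENTIONS = ("bunsen", "nmol-per-L-atm", "mol-per-L-atm")

    def __post_init__(self) -> None:
        for name in ("A1", "A2", "A3", "A4", "B1", "B2", "B3"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"constant {name} for {self.gas_id} is not finite: {v}")
        if self.unit_convention not in self._CONVENTIONS:
            raise ValueError(
                f"unknown unit convention {self.unit_convention!r}; "
                f"expected one of {self._CONVENTIONS}"
            )

    def ln_fit(self, cond: SeawaterConditions) -> float:
        """Evaluate the ln-solubility fit at the given conditions."""
        t100 = cond.temperature / 100.0
        return (
            self.A1
            + self.A2 * (100.0 / cond.temperature)
            + self.A3 * math.log(t100)
            + self.A4 * t100
            + cond.salinity * (self.B1 + self.B2 * t100 + self.B3 * t100 * t100)
        )


@dataclass(frozen=True)
class AtmosphereSpec:
    """Dry-atmosphere mole fraction of the gas with its uncertainty."""

    mole_fraction: float
    mole_fraction_sd: float = 0.0
    hemisphere: str = "southern"

    def __post_init__(self) -> None:
        if not 0.0 <= self.mole_fraction < 1.0:
            raise ValueError(f"mole fraction must lie in [0, 1), got {self.mole_fraction}")
        if self.mole_fraction_sd < 0:
            raise ValueError("mole-fraction uncertainty must be non-negative")

    @classmethod
    def from_ppb(
        cls, ppb: float | None = None, sd_ppb: float = DEFAULT_ATM_CH4_PPB_SD,
        hemisphere: str = "southern",
    ) -> "AtmosphereSpec":
        if ppb is None:
            ppb = DEFAULT_ATM_CH4_PPB[hemisphere]
        return cls(units.ppb_to_fraction(ppb), units.ppb_to_fraction(sd_ppb), hemisphere)


@dataclass(frozen=True)
class SaturationResult:
    """Dissolved concentration, equilibrium concentration and saturation."""

    concentration: float  # mol L^-1
    equilibrium_concentration: float  # mol L^-1
    percent_saturation: float
    percent_uncertainty: float = 0.0


def load_constants(gas_id: str = "ch4", unit_convention: str = "bunsen",
                   source: Mapping | str | None = None) -> SolubilityConstants:
    """Load fit constants for ``gas_id`` from the packaged (or a user) YAML file."""
    if source is None:
        text = (resources.files("sandch4") / "data" / "solubility_constants.yaml").read_text()
        table = yaml.safe_load(text)
    elif isinstance(source, str):
        with open(source) as fh:
            table = yaml.safe_load(fh)
    else:
        table = source
    try:
        entry = table[gas_id][unit_convention]
    except KeyError as exc:
        raise KeyError(
            f"no constants for gas {gas_id!r} with convention {unit_convention!r}"
        ) from exc
    return SolubilityConstants(
        gas_id=gas_id,
        A1=entry["A1"], A2=entry["A2"], A3=entry["A3"], A4=entry.get("A4", 0.0),
        B1=entry["B1"], B2=entry["B2"], B3=entry["B3"],
        unit_convention=unit_convention,
    )


def bunsen_coefficient(cond: SeawaterConditions, consts: SolubilityConstants) -> float:
    """Volumetric Bunsen solubility coefficient beta (dimensionless).

    beta is the volume of gas at STP absorbed per unit volume of solution at
    1 atm gas partial pressure; it decreases with both temperature
    (thermal desorption) and salinity (salting-out).
    """
    if consts.unit_convention != "bunsen":
        raise ValueError(
            f"bunsen_coefficient requires 'bunsen' constants, got {consts.unit_convention!r}"
        )
    return math.exp(consts.ln_fit(cond))


def seawater_vapor_pressure(cond: SeawaterConditions) -> float:
    """Vapour pressure of seawater (atm), Weiss & Price (1980) formulation.

    Pure-water saturation pressure with a linear salinity depression term:
    ln P_vp = 24.4543 - 67.4509*(100/T) - 4.8489*ln(T/100) - 0.000544*S.
    """
    t = cond.temperature
    return math.exp(
        24.4543 - 67.4509 * (100.0 / t) - 4.8489 * math.log(t / 100.0)
        - 0.000544 * cond.salinity
    )


def equilibrium_concentration(
    cond: SeawaterConditions, atm: AtmosphereSpec, consts: SolubilityConstants
) -> float:
    """Atmospheric equilibrium concentration C_eq in mol L^-1.

    With Bunsen constants: C_eq = beta*(1-P_vp)*f_G / V_STP; with
    'nmol-per-L-atm' constants the fit already folds in the humidity
    correction and yields nmol L^-1 directly.
    """
    if consts.unit_convention == "bunsen":
        beta = bunsen_coefficient(cond, consts)
        pvp = seawater_vapor_pressure(cond)
        return beta * (cond.pressure - pvp) * atm.mole_fraction / MOLAR_VOLUME_STP_L
    if consts.unit_convention == "nmol-per-L-atm":
        if atm.mole_fraction == 0.0:
            return 0.0
        ln_c = math.log(atm.mole_fraction) + consts.ln_fit(cond)
        return math.exp(ln_c) * 1e-9
    raise ValueError(
        f"equilibrium_concentration does not support convention {consts.unit_convention!r}"
    )


def aqueous_solubility_K0(cond: SeawaterConditions, consts: SolubilityConstants) -> float:
    """Aqueous-phase solubility K0 in mol L^-1 atm^-1.

    For Bunsen constants, K0 = beta / V_STP, so that the concentration and
    partial-pressure flux forms agree at equilibrium by construction.
    """
    if consts.unit_convention == "bunsen":
        return bunsen_coefficient(cond, consts) / MOLAR_VOLUME_STP_L
    if consts.unit_convention == "mol-per-L-atm":
        return math.exp(consts.ln_fit(cond))
    raise ValueError(f"K0 not defined for convention {consts.unit_convention!r}")


def percent_saturation(
    concentration: float,
    cond: SeawaterConditions,
    atm: AtmosphereSpec,
    consts: SolubilityConstants,
) -> SaturationResult:
    """Percent saturation of a measured dissolved concentration (mol L^-1).

    100% means equilibrium with the atmosphere; supersaturated water
    (>100%) is a source of the gas to the atmosphere. The relative
    uncertainty of C_eq equals the relative uncertainty of the atmospheric
    mole fraction (first order), so the saturation uncertainty is
    saturation * sd(f_G)/f_G.
    """
    if concentration < 0:
        raise ValueError(f"dissolved concentration must be non-negative, got {concentration}")
    c_eq = equilibrium_concentration(cond, atm, consts)
    if c_eq == 0.0:
        raise ZeroDivisionError(
            "equilibrium concentration is zero (atmospheric mole fraction is zero); "
            "percent saturation is undefined"
        )
    sat = 100.0 * concentration / c_eq
    rel_atm = atm.mole_fraction_sd / atm.mole_fraction if atm.mole_fraction else 0.0
    return SaturationResult(
        concentration=concentration,
        equilibrium_concentration=c_eq,
        percent_saturation=sat,
        percent_uncertainty=sat * rel_atm,
    )
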