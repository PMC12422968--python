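"""Two-phase (water/headspace) gas partitioning and slurry inventories.

A sealed vial holding a water sample and an inert-gas headspace reaches a
partition equilibrium set by the Bunsen coefficient: the dissolved
concentration is ``beta * p / V_STP`` (mol L^-1) at gas partial pressure
``p``, while the headspace holds ``p * V_g / (R T)`` moles. Measuring the
headspace mixing ratio therefore lets the original dissolved concentration
be recovered exactly by mole balance (the standard headspace-equilibration
back-calculation). The same physics, iterated over repeated
helium-injection/withdrawal sampling events, tracks the methane inventory
of sediment-slurry incubations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gas_solubility import SeawaterConditions, SolubilityConstants, bunsen_coefficient
from .units import MOLAR_VOLUME_STP_L, R_L_ATM

__all__ = [
    "VialGeometry",
    "SamplingEvent",
    "SlurryVial",
    "partition_forward",
    "dissolved_from_headspace",
    "equilibrium_partial_pressure",
    "total_moles_from_partial_pressure",
    "slurry_inventory",
]

QUARTZ_GRAIN_DENSITY = 2.65  # g cm^-3, default for quartz sand solids displacement


@dataclass(frozen=True)
class VialGeometry:
    """Sealed-vial phase volumes (mL) plus the water conditions inside."""

    total_volume: float
    liquid_volume: float
    headspace_volume: float
    temperature: float  # kelvin
    salinity: float  # ppt
    pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        if min(self.total_volume, self.liquid_volume, self.headspace_volume) <= 0:
            raise ValueError("all vial volumes must be positive")
        if abs(self.total_volume - self.liquid_volume - self.headspace_volume) > 1e-6:
            raise ValueError(
                f"total volume {self.total_volume} mL != liquid {self.liquid_volume} "
                f"+ headspace {self.headspace_volume} mL"
            )

    @property
    def conditions(self) -> SeawaterConditions:
        return SeawaterConditions(self.temperature, self.salinity, self.pressure)


@dataclass(frozen=True)
class SamplingEvent:
    """One slurry sampling event: He injected, gas removed, mixing ratio read."""

    time_h: float
    injected_he_mL: float
    removed_gas_mL: float
    measured_ppm: float


@dataclass(frozen=True)
class SlurryVial:
    """Sediment-slurry serum vial; headspace volume derives from the fill.

    headspace = vial volume - seawater volume - sediment mass / grain density.
    """

    vial_volume: float  # mL
    sediment_mass: float  # g
    seawater_volume: float  # mL
    sampling_events: Sequence[SamplingEvent]
    grain_density: float = QUARTZ_GRAIN_DENSITY  # g cm^-3
    temperature: float = 293.15  # K
    salinity: float = 35.0
    pressure: float = 1.0

    @property
    def headspace_volume(self) -> float:
        v = self.vial_volume - self.seawater_volume - self.sediment_mass / self.grain_density
        if v <= 0:
            raise ValueError("derived headspace volume is non-positive; check fill volumes")
        return v

    @property
    def geometry(self) -> VialGeometry:
        hs = self.headspace_volume
        return VialGeometry(
            total_volume=self.seawater_volume + hs,
            liquid_volume=self.seawater_volume,
            headspace_volume=hs,
            temperature=self.temperature,
            salinity=self.salinity,
            pressure=self.pressure,
        )


def _phase_capacity(geom: VialGeometry, consts: SolubilityConstants) -> tuple[float, float]:
    """Moles per atm of gas partial pressure held by (water, headspace)."""
    beta = bunsen_coefficient(geom.conditions, consts)
    water = beta / MOLAR_VOLUME_STP_L * (geom.liquid_volume / 1000.0)  # mol atm^-1
    gas = (geom.headspace_volume / 1000.0) / (R_L_ATM * geom.temperature)
    return water, gas


def equilibrium_partial_pressure(
    total_moles: float, geom: VialGeometry, consts: SolubilityConstants
) -> float:
    """Partial pressure (atm) once ``total_moles`` equilibrates across phases."""
    water, gas = _phase_capacity(geom, consts)
    return total_moles / (water + gas)


def total_moles_from_partial_pressure(
    p_atm: float, geom: VialGeometry, consts: SolubilityConstants
) -> float:
    water, gas = _phase_capacity(geom, consts)
    return p_atm * (water + gas)


def partition_forward(
    dissolved_c: float, geom: VialGeometry, consts: SolubilityConstants
) -> float:
    """Headspace mixing ratio (ppm) after equilibrating a water sample.

    ``dissolved_c`` (mol L^-1) is the concentration in the retained liquid
    volume before the headspace was introduced; all of its gas then
    re-partitions between liquid and headspace.
    """
    if dissolved_c < 0:
        raise ValueError("dissolved concentration must be non-negative")
    n_total = dissolved_c * (geom.liquid_volume / 1000.0)
    p = equilibrium_partial_pressure(n_total, geom, consts)
    return p / geom.pressure * 1e6


def dissolved_from_headspace(
    measured_ppm: float, geom: VialGeometry, consts: SolubilityConstants
) -> float:
    """Original dissolved concentration (mol L^-1) from a headspace reading.

    Exact inverse of :func:`partition_forward`: the measured mixing ratio
    fixes the equilibrium partial pressure, the two-phase mole balance gives
    the total moles, and dividing by the liquid volume recovers the
    pre-equilibration concentration.
    """
    if measured_ppm < 0:
        raise ValueError("measured mixing ratio must be non-negative")
    p = measured_ppm * 1e-6 * geom.pressure
    n_total = total_moles_from_partial_pressure(p, geom, consts)
    return n_total / (geom.liquid_volume / 1000.0)


def slurry_inventory(vial: SlurryVial, consts: SolubilityConstants) -> pd.DataFrame:
    """Per-event total CH4 inventory of a slurry vial, in micromoles.

    At each sampling event the He injection dilutes the headspace mixing
    ratio by V_g/(V_g + V_inj) at constant vial volume, so the pre-injection
    mixing ratio is recovered by the inverse factor. The withdrawn gas
    sample is booked at 1 atm reference with the post-injection mixing
    ratio; with equal injection and withdrawal volumes the vial returns to
    1 atm. Columns:

    - ``total_umol``: gas + dissolved CH4 in the vial just before the event
    - ``removed_umol``: CH4 leaving in the withdrawn sample
    - ``cumulative_umol``: dilution/removal-corrected production series
      (total plus everything removed at earlier events, minus the initial
      inventory)
    - ``naive_umol``: the uncorrected series (total minus initial only)
    """
    events = list(vial.sampling_events)
    times = [e.time_h for e in events]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("sampling events must be time-ordered")
    geom = vial.geometry
    vg = geom.headspace_volume

    rows = []
    removed_so_far = 0.0
    initial_total = None
    for ev in events:
        if ev.removed_gas_mL > vg:
            raise ValueError("removed gas volume exceeds headspace volume")
        y_measured = ev.measured_ppm * 1e-6
        # undo the He dilution to get the pre-injection equilibrium state
        dilution = vg / (vg + ev.injected_he_mL) if ev.injected_he_mL else 1.0
        y_pre = y_measured / dilution
        p_pre = y_pre * geom.pressure
        total = total_moles_from_partial_pressure(p_pre, geom, consts)
        removed = (
            y_measured * geom.pressure * (ev.removed_gas_mL / 1000.0)
            / (R_L_ATM * geom.temperature)
        )
        if initial_total is None:
            initial_total = total
        rows.append(
            {
                "time_h": ev.time_h,
                "total_umol": total * 1e6,
                "removed_umol": removed * 1e6,
                "cumulative_umol": (total + removed_so_far - initial_total) * 1e6,
                "naive_umol": (total - initial_total) * 1e6,
            }
        )
        removed_so_far += removed
    return pd.DataFrame(rows)
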