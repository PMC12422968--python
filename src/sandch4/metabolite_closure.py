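"""Stoichiometric closure of methane production by methylated metabolites.

Methylotrophic methanogens demethylate osmolytes (TMA, TMAO, choline,
DMSP, DMS, methylamines); each methyl group can yield at most one methane
molecule, and under disproportionation 4 CH3 -> 3 CH4 + 1 CO2 the yield is
3/4 per methyl. Summing panel concentrations weighted by methyl groups per
molecule gives the methyl-equivalent pool; multiplying by the yield factor
gives the theoretical methane potential; and comparing the implied supply
rate with an observed maximum production rate gives the percent closure
(the fraction of production the measured substrates can explain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import yaml

__all__ = [
    "MetaboliteSpec",
    "MetabolitePanel",
    "load_methyl_groups",
    "methyl_equivalents",
    "theoretical_methane_yield",
    "supply_rate",
    "closure_fraction",
    "YIELD_DISPROPORTIONATION",
    "YIELD_UNITY",
]

YIELD_DISPROPORTIONATION = 0.75  # 4 CH3 -> 3 CH4 + 1 CO2
YIELD_UNITY = 1.0


@dataclass(frozen=True)
class MetaboliteSpec:
    name: str
    methyl_groups: int

    def __post_init__(self) -> None:
        if self.methyl_groups < 1:
            raise ValueError(f"{self.name}: methyl groups per molecule must be >= 1")


@dataclass(frozen=True)
class PanelEntry:
    spec: MetaboliteSpec
    concentration_uM: float
    sd_uM: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration_uM < 0 or self.sd_uM < 0:
            raise ValueError(f"{self.spec.name}: concentration and sd must be non-negative")


@dataclass(frozen=True)
class MetabolitePanel:
    entries: Sequence[PanelEntry]

    @classmethod
    def from_concentrations(
        cls,
        concentrations_uM: Mapping[str, float],
        sds_uM: Mapping[str, float] | None = None,
        methyl_table: Mapping[str, int] | None = None,
    ) -> "MetabolitePanel":
        """Build a panel from a {name: uM} mapping using the shipped methyl table."""
        table = methyl_table if methyl_table is not None else load_methyl_groups()
        sds = sds_uM or {}
        entries = []
        for name, conc in concentrations_uM.items():
            key = name.lower()
            if key not in table:
                raise KeyError(
                    f"unknown metabolite {name!r}: add it to the methyl-group table"
                )
            entries.append(
                PanelEntry(MetaboliteSpec(key, table[key]), conc, sds.get(name, 0.0))
            )
        return cls(entries)


def load_methyl_groups(path: str | None = None) -> dict[str, int]:
    """Methyl-groups-per-molecule table (shipped as data so users can extend it)."""
    if path is None:
        text = (resources.files("sandch4") / "data" / "methyl_groups.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return {k.lower(): int(v) for k, v in yaml.safe_load(text).items()}


def methyl_equivalents(panel: MetabolitePanel) -> tuple[float, float]:
    """Total methyl-group concentration (uM) with quadrature-propagated sd."""
    # fsum: exactly rounded, so the result is invariant to panel order
    total = math.fsum(e.concentration_uM * e.spec.methyl_groups for e in panel.entries)
    var = math.fsum((e.sd_uM * e.spec.methyl_groups) ** 2 for e in panel.entries)
    return total, math.sqrt(var)


def theoretical_methane_yield(methyl_uM: float, yield_factor: float = YIELD_DISPROPORTIONATION) -> float:
    """Theoretical CH4 (uM) obtainable from a methyl-equivalent pool."""
    if not 0.0 < yield_factor <= 1.0:
        raise ValueError(f"yield factor must lie in (0, 1], got {yield_factor}")
    return methyl_uM * yield_factor


def supply_rate(
    panel: MetabolitePanel,
    flow_mL_h: float,
    dilution: float = 20.0,
    yield_factor: float = YIELD_DISPROPORTIONATION,
) -> float:
    """Theoretical CH4 supply to a reactor (umol h^-1) from a substrate feed.

    The metabolite panel describes the concentrated extract; the feed is the
    extract diluted ``dilution``-fold into seawater and pumped at
    ``flow_mL_h``.
    """
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    methyl, _ = methyl_equivalents(panel)
    feed_ch4_uM = theoretical_methane_yield(methyl, yield_factor) / dilution
    return feed_ch4_uM * flow_mL_h / 1000.0  # uM * mL/h = nmol/h -> umol/h


def closure_fraction(theoretical_rate: float, observed_rate: float) -> dict[str, float | bool]:
    """Percent of observed production explained by the theoretical supply.

    Values above 100% are permitted and flagged (``exceeds_observed``); the
    unexplained remainder is reported explicitly and never imputed.
    """
    if observed_rate <= 0:
        raise ValueError(f"observed production rate must be positive, got {observed_rate}")
    if theoretical_rate < 0:
        raise ValueError("theoretical supply rate must be non-negative")
    pct = 100.0 * theoretical_rate / observed_rate
    return {
        "closure_pct": pct,
        "unexplained_pct": max(0.0, 100.0 - pct),
        "exceeds_observed": pct > 100.0,
    }
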