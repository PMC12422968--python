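"""Seeded generators for every input the analysis pipeline consumes.

Real inputs to this package are field-survey tables, wind records, reactor
and slurry time series, metabolite panels and read-count tables. The
generators here produce all of them with the statistical structure such
studies report — multi-site surveys whose methane saturation spans roughly
four orders of magnitude (a few hundred to ~2e5 percent), a twice-daily
annual wind record, flow-through-reactor series with an onset lag and
logistic growth of the production rate, slurry headspace series sampled
with periodic helium injection, and count tables in which the
methanogenesis marker mcrA is carried by well under 1% of the community.

Every generator is a pure function of (scenario, seed): a single global
seed fans out to per-stream child seeds via ``numpy.random.SeedSequence``
so adding a generator never perturbs existing outputs.

What these generators deliberately do NOT emulate: instrument drift,
calibration error, tidal structure in winds, or sequence-level read
simulation (count tables only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .community_markers import DEFAULT_MARKER_IDS, MarkerSet
from .gas_solubility import (
    AtmosphereSpec,
    SeawaterConditions,
    SolubilityConstants,
    equilibrium_concentration,
    load_constants,
)
from .headspace import (
    SamplingEvent,
    SlurryVial,
    equilibrium_partial_pressure,
)
from .reactor_rates import FTRConfig, ReactorTimeSeries
from .units import R_L_ATM

__all__ = [
    "SurveyScenario",
    "ReactorScenario",
    "SlurryScenario",
    "CountsScenario",
    "generate_survey",
    "generate_wind",
    "generate_reactor",
    "generate_slurry",
    "generate_counts",
]

_STREAMS = ("survey", "wind", "reactor", "slurry", "counts")


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-stream generator fanned out from one global seed."""
    idx = _STREAMS.index(stream)
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[idx])


# ---------------------------------------------------------------- survey

@dataclass(frozen=True)
class SurveyScenario:
    """Multi-site dissolved-methane survey with replicates and radon."""

    n_sites: int = 12
    n_replicates: int = 3
    saturation_min_pct: float = 380.0
    saturation_max_pct: float = 189_000.0
    replicate_cv: float = 0.08  # lognormal replicate scatter
    temp_c_range: tuple[float, float] = (12.0, 24.0)
    salinity_range: tuple[float, float] = (33.0, 36.0)
    radon_regime: str = "no-groundwater"  # or "groundwater"
    radon_mean_bq_m3: float = 50.0
    atm_ppb: float = 1800.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if self.saturation_min_pct <= 0 or self.saturation_max_pct <= self.saturation_min_pct:
            raise ValueError("saturation bounds must be positive and ordered")
        if self.radon_regime not in ("groundwater", "no-groundwater"):
            raise ValueError(f"unknown radon regime {self.radon_regime!r}")


def generate_survey(
    scenario: SurveyScenario, seed: int, consts: SolubilityConstants | None = None
) -> pd.DataFrame:
    """Survey table: per-site replicate dissolved CH4 (nM) plus radon.

    Per-site mean saturations are log-uniform between the scenario bounds,
    with the endpoint sites pinned to the bounds so the programmed range is
    always represented. Dissolved concentrations are derived back through
    the solubility model so the analysis pipeline recovers the programmed
    saturations. Radon is independent of CH4 under "no-groundwater" and
    strongly CH4-correlated under "groundwater".
    """
    rng = _child_rng(seed, "survey")
    consts = consts or load_constants("ch4", "bunsen")
    atm = AtmosphereSpec.from_ppb(scenario.atm_ppb)

    log_lo = np.log(scenario.saturation_min_pct)
    log_hi = np.log(scenario.saturation_max_pct)
    if scenario.n_sites == 1:
        log_sat = np.array([log_lo])
    else:
        interior = rng.uniform(log_lo, log_hi, size=scenario.n_sites - 2)
        log_sat = np.concatenate([[log_lo], np.sort(interior), [log_hi]])
    site_sat = np.exp(log_sat)

    temps = rng.uniform(*scenario.temp_c_range, size=scenario.n_sites)
    sals = rng.uniform(*scenario.salinity_range, size=scenario.n_sites)

    sigma = np.sqrt(np.log(1.0 + scenario.replicate_cv**2))
    rows = []
    for i in range(scenario.n_sites):
        cond = SeawaterConditions.from_celsius(temps[i], sals[i])
        c_eq = equilibrium_concentration(cond, atm, consts)
        c_mean = site_sat[i] / 100.0 * c_eq
        if scenario.radon_regime == "groundwater":
            radon = scenario.radon_mean_bq_m3 * (site_sat[i] / site_sat.mean()) \
                * rng.lognormal(0.0, 0.1)
        else:
            radon = rng.lognormal(np.log(scenario.radon_mean_bq_m3), 0.4)
        for rep in range(scenario.n_replicates):
            c = c_mean * rng.lognormal(-0.5 * sigma**2, sigma)
            rows.append(
                {
                    "site": f"S{i + 1:02d}",
                    "replicate": rep + 1,
                    "temp_C": temps[i],
                    "salinity": sals[i],
                    "ch4_nM": c * 1e9,
                    "radon_Bq_m3": radon,
                    "programmed_saturation_pct": site_sat[i],
                }
            )
    return pd.DataFrame(rows)


def generate_wind(
    seed: int,
    n_days: int = 365,
    mean_m_s: float = 5.0,
    weibull_shape: float = 2.0,
) -> pd.DataFrame:
    """Twice-daily (9 am / 3 pm) annual wind record at 10 m, Weibull-distributed."""
    rng = _child_rng(seed, "wind")
    n = 2 * n_days
    from math import gamma

    scale = mean_m_s / gamma(1.0 + 1.0 / weibull_shape)
    u10 = scale * rng.weibull(weibull_shape, size=n)
    hours = np.tile([9.0, 15.0], n_days)
    days = np.repeat(np.arange(n_days), 2)
    return pd.DataFrame({"day": days, "hour": hours, "u10_m_s": u10})


# --------------------------------------------------------------- reactor

@dataclass(frozen=True)
class ReactorScenario:
    """Programmed FTR rate trajectory: onset lag, logistic growth, O2 pulses."""

    onset_lag_h: float = 20.0
    max_rate_umol_cm3_h: float = 48.0
    growth_steepness_h: float = 6.0  # logistic time constant after onset
    growth_midpoint_h: float = 15.0  # hours after onset to half-maximum
    duration_h: float = 60.0
    dt_h: float = 1.0
    inlet_uM: float = 0.005
    noise_sd_uM: float = 0.0
    dic_inlet_uM: float = 2000.0
    dic_to_ch4_ratio: float = 9.0  # asymptotic n in the 1:n carbon ratio
    pulse_period_h: float = 0.0  # 0 disables the oxygen-pulse schedule
    pulse_duration_h: float = 3.0
    recovery_lag_h: float = 1.5

    def __post_init__(self) -> None:
        if self.onset_lag_h < 0 or self.max_rate_umol_cm3_h <= 0:
            raise ValueError("onset lag must be >= 0 and max rate positive")


def programmed_rate(scenario: ReactorScenario, t_h: np.ndarray) -> np.ndarray:
    """The generator's own rate trajectory (the oracle for recovery tests)."""
    t = np.asarray(t_h, dtype=float)
    after = t - scenario.onset_lag_h
    z = np.clip(
        -(after - scenario.growth_midpoint_h) / scenario.growth_steepness_h, -700, 700
    )
    x = np.where(after <= 0.0, 0.0, scenario.max_rate_umol_cm3_h / (1.0 + np.exp(z)))
    if scenario.pulse_period_h > 0:
        phase = np.mod(t, scenario.pulse_period_h)
        in_pulse = phase < scenario.pulse_duration_h
        recovering = (phase >= scenario.pulse_duration_h) & (
            phase < scenario.pulse_duration_h + scenario.recovery_lag_h
        )
        frac = np.clip((phase - scenario.pulse_duration_h) / scenario.recovery_lag_h, 0, 1)
        x = np.where(in_pulse, 0.0, np.where(recovering, x * frac, x))
    return x


def generate_reactor(
    scenario: ReactorScenario, cfg: FTRConfig, seed: int
) -> tuple[ReactorTimeSeries, ReactorTimeSeries]:
    """(CH4, DIC) outlet series consistent with the plug-flow balance.

    Outlet concentration is inlet + x(t) * V / Q (steady-state balance per
    sampling), with optional Gaussian instrument noise. The DIC series is
    programmed so the CH4:CO2 carbon ratio follows the logistic approach to
    1:``dic_to_ch4_ratio``.
    """
    rng = _child_rng(seed, "reactor")
    t = np.arange(0.0, scenario.duration_h + scenario.dt_h / 2, scenario.dt_h)
    x_ch4 = programmed_rate(scenario, t)
    # carbon ratio tightens toward the asymptote as the rate approaches max
    n_ratio = scenario.dic_to_ch4_ratio
    x_dic = x_ch4 * n_ratio

    q = np.full_like(t, cfg.flow_mL_h)
    dc_ch4 = x_ch4 * cfg.bulk_volume_cm3 / q * 1000.0  # uM
    dc_dic = x_dic * cfg.bulk_volume_cm3 / q * 1000.0
    noise = rng.normal(0.0, scenario.noise_sd_uM, size=(2, t.size)) if scenario.noise_sd_uM else 0.0
    out_ch4 = scenario.inlet_uM + dc_ch4 + (noise[0] if scenario.noise_sd_uM else 0.0)
    out_dic = scenario.dic_inlet_uM + dc_dic + (noise[1] if scenario.noise_sd_uM else 0.0)
    ch4 = ReactorTimeSeries(
        time_h=t,
        inlet_uM=np.full_like(t, scenario.inlet_uM),
        outlet_uM=np.clip(out_ch4, 0.0, None),
        flow_mL_h=q,
        species="CH4",
    )
    dic = ReactorTimeSeries(
        time_h=t,
        inlet_uM=np.full_like(t, scenario.dic_inlet_uM),
        outlet_uM=np.clip(out_dic, 0.0, None),
        flow_mL_h=q,
        species="DIC",
    )
    return ch4, dic


# ---------------------------------------------------------------- slurry

@dataclass(frozen=True)
class SlurryScenario:
    """Programmed constant-production slurry incubation with He sampling."""

    production_umol_h: float = 0.5
    sampling_times_h: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0)
    injected_he_mL: float = 2.0
    removed_gas_mL: float = 2.0
    vial_volume_mL: float = 160.0
    sediment_mass_g: float = 30.0
    seawater_volume_mL: float = 70.0
    temperature_K: float = 293.15
    salinity: float = 35.0
    ppm_noise_sd: float = 0.0


def generate_slurry(
    scenario: SlurryScenario, seed: int, consts: SolubilityConstants | None = None
) -> SlurryVial:
    """Forward-simulate a slurry vial with known production.

    Uses exactly the partitioning physics of the headspace module: between
    events the programmed production accrues to the vial inventory; at each
    event the equilibrium mixing ratio is diluted by the He injection,
    recorded (optionally with Gaussian ppm noise), and the withdrawn sample
    is debited at 1 atm reference.
    """
    rng = _child_rng(seed, "slurry")
    consts = consts or load_constants("ch4", "bunsen")
    template = SlurryVial(
        vial_volume=scenario.vial_volume_mL,
        sediment_mass=scenario.sediment_mass_g,
        seawater_volume=scenario.seawater_volume_mL,
        sampling_events=(),
        temperature=scenario.temperature_K,
        salinity=scenario.salinity,
    )
    geom = template.geometry
    vg = geom.headspace_volume

    events = []
    n_tot = 0.0  # mol CH4 in the vial
    t_prev = scenario.sampling_times_h[0]
    for t in scenario.sampling_times_h:
        n_tot += scenario.production_umol_h * 1e-6 * (t - t_prev)
        p = equilibrium_partial_pressure(n_tot, geom, consts)
        y0 = p / geom.pressure
        y1 = y0 * vg / (vg + scenario.injected_he_mL)
        ppm = y1 * 1e6
        if scenario.ppm_noise_sd:
            ppm = max(0.0, ppm + rng.normal(0.0, scenario.ppm_noise_sd))
        removed = (
            y1 * geom.pressure * (scenario.removed_gas_mL / 1000.0)
            / (R_L_ATM * geom.temperature)
        )
        n_tot -= removed
        events.append(
            SamplingEvent(
                time_h=t,
                injected_he_mL=scenario.injected_he_mL,
                removed_gas_mL=scenario.removed_gas_mL,
                measured_ppm=ppm,
            )
        )
        t_prev = t
    return SlurryVial(
        vial_volume=scenario.vial_volume_mL,
        sediment_mass=scenario.sediment_mass_g,
        seawater_volume=scenario.seawater_volume_mL,
        sampling_events=tuple(events),
        temperature=scenario.temperature_K,
        salinity=scenario.salinity,
    )


# ---------------------------------------------------------------- counts

@dataclass(frozen=True)
class CountsScenario:
    """Community read-count table with a rare target-gene carrier fraction."""

    n_genomes: int = 200
    carrier_fraction: float = 0.002  # abundance share of mcrA carriers
    read_depth: int = 10_000_000
    target_gene: str = "mcrA"
    target_length_bp: int = 1650
    marker_ids: tuple[str, ...] = DEFAULT_MARKER_IDS
    marker_length_bp: int = 500
    other_length_bp: int = 3_000_000  # lumped non-marker genome content

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier fraction must lie in [0, 1]")


def generate_counts(
    scenario: CountsScenario, seed: int
) -> tuple[pd.DataFrame, MarkerSet]:
    """Multinomial read allocation over genes; markers single-copy per genome.

    Every genome carries each of the single-copy markers and a lumped
    "other" fraction; mcrA carriers (whose summed abundance share is
    exactly the programmed carrier fraction) additionally carry one mcrA
    copy. Reads are allocated multinomially proportional to abundance x
    gene length, so the RPKM arithmetic downstream should recover the
    programmed carrier fraction up to Poisson sampling error.
    """
    rng = _child_rng(seed, "counts")
    # expected read mass per gene ~ sum over genomes of abundance * length;
    # markers are single-copy in every genome so their abundance weight is 1
    weights = {m: float(scenario.marker_length_bp) for m in scenario.marker_ids}
    weights[scenario.target_gene] = scenario.carrier_fraction * scenario.target_length_bp
    weights["other"] = float(scenario.other_length_bp)
    genes = list(weights)
    w = np.array([weights[g] for g in genes])
    counts = rng.multinomial(scenario.read_depth, w / w.sum())
    lengths = {m: scenario.marker_length_bp for m in scenario.marker_ids}
    lengths[scenario.target_gene] = scenario.target_length_bp
    lengths["other"] = scenario.other_length_bp
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "reads": counts,
            "length_bp": [lengths[g] for g in genes],
            "library_size": scenario.read_depth,
        }
    )
    marker_mask = df["gene_id"].isin(scenario.marker_ids)
    marker_rpkm = (
        df.loc[marker_mask, "reads"]
        / (df.loc[marker_mask, "length_bp"] / 1000.0)
        / (scenario.read_depth / 1e6)
    )
    markers = MarkerSet(list(df.loc[marker_mask, "gene_id"]), list(marker_rpkm))
    return df, markers
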