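# Methods

This note records the models implemented in `sandch4`, their assumptions,
the defaults that matter, and the choices made where the design was open.

## Gas solubility and saturation

The volumetric Bunsen coefficient follows the classic seawater fit

    ln β = A1 + A2(100/T) + A3 ln(T/100) + S[B1 + B2(T/100) + B3(T/100)²]

with T in kelvin and S in practical salinity (ppt). The CH₄ constants are
the Wiesenburg & Guinasso (1979) values, shipped in
`src/sandch4/data/solubility_constants.yaml` keyed by gas id and unit
convention so further gases (a Weiss-1974 CO₂ K₀ entry is included) can be
added without touching code. The same reference's independent fit for the
atmospheric equilibrium concentration in nmol L⁻¹ (constants A1–A4, B1–B3,
humidity correction built in) is also shipped; the two transcriptions agree
within 0.3% over 0–30 °C and S 0–35, and that agreement is asserted in the
tests as a mutual transcription check — an error in either set of constants
would break it.

Seawater vapour pressure uses the Weiss & Price (1980) formulation
(pure-water Antoine-type fit with a linear salinity depression,
`ln P_vp = 24.4543 − 67.4509(100/T) − 4.8489 ln(T/100) − 0.000544 S`),
which reproduces the 25 °C steam-table value (3.169 kPa) to 0.1%. The
equilibrium concentration is `C_eq = β(1 − P_vp) f_G / V_STP` with
V_STP = 22.414 L mol⁻¹ (ideal-gas molar volume; the ~0.3% real-gas
correction for CH₄ is inside the fit-agreement tolerance).

Accepted ranges are 270–320 K and S 0–45; temperatures are accepted in °C
at the I/O boundary (`SeawaterConditions.from_celsius`) and stored in
kelvin. The default atmosphere is 1800 ppb CH₄ (southern hemisphere;
1900 ppb northern) with a 15 ppb annual-variability standard deviation,
both configurable. Saturation uncertainty is first-order: the relative
uncertainty of C_eq equals that of f_G; replicate analytical scatter is a
separate quantity and is reported separately (site replicate spread in the
survey tables), never merged with the atmospheric term.

## Headspace partitioning

A sealed vial with liquid volume V_l and headspace V_g at total pressure P
and temperature T holds, at partial pressure p, `β p V_l / V_STP` moles
dissolved and `p V_g / (R T)` moles in the gas phase. Forward partitioning
and back-calculation are the two directions of this single linear balance,
so the round trip is exact to machine precision (the tests require <1e−9
relative over the full T × S grid). Full re-equilibration between phases is
assumed before each measurement (vials are shaken); no kinetic
mass-transfer model is attempted.

Slurry vials (default 160 mL serum vial, 30 g sediment, 70 mL seawater)
derive their headspace volume from a solids-displacement term with grain
density 2.65 g cm⁻³ (quartz sand; configurable). Each sampling event
injects V_inj of helium at constant vial volume — diluting the headspace
mixing ratio by V_g/(V_g + V_inj) while raising pressure — and withdraws
an equal gas volume, booked at 1 atm reference with the post-injection
composition, returning the vial to 1 atm. The inventory reconstruction
inverts the dilution, converts the pre-injection mixing ratio to a
two-phase total, and reports both a sampling-corrected cumulative series
(total plus all previously removed moles) and the naive uncorrected
series, since published slurry time courses do not always state which
convention they use. Overpressure transients, the ~50 µL HgCl₂ preservative
volume and any sorption of CH₄ to sediment grains are neglected.

## Sea–air flux

Schmidt numbers use the Wanninkhof (1992) third-order polynomials for CH₄
in freshwater and in S = 35 seawater (the parameterization behind the
`marelac` R package's Schmidt function), valid 0–30 °C, with linear
interpolation in salinity for brackish water. The gas transfer velocity is

    k = 0.251 · U₁₀ · (Sc/660)^(−0.5)   [cm h⁻¹, U₁₀ in m s⁻¹]

as the default "as-printed" mode. The 0.251 coefficient and the 660
normalization originate from a quadratic-in-U₁₀ parameterization
(Wanninkhof 2014 lineage); a `quadratic` mode (U₁₀²) is exposed behind the
same interface, and the discrepancy is documented here rather than silently
"fixed". Fluxes default to the concentration form F = k·(C − C_eq); the
partial-pressure form F = k·K₀·Δp uses K₀ = β/V_STP so the two agree
identically by construction. Output units are mg CH₄ m⁻² day⁻¹.

Flux bounds pair the lowest/mean/highest survey concentrations with the
Q1/median/Q3 of the wind record. Quartiles use numpy's default
linear-interpolation (type-7) convention, recorded in the output metadata
because the convention was not standardizable from published descriptions.
Radon handling is decay-only (`A·exp(λt)`, λ = ln 2 / 3.8235 d);
instrument-side salinity/temperature partition corrections are out of
scope and must be applied upstream.

## Reactor and slurry rates

The FTR balance `x = Q (C_out − C_in) / V_FTR` assumes steady state between
samplings; the ~1 h residence time (V/Q ≈ 50 cm³ / 45 mL h⁻¹) is not
deconvolved. Rates are per bulk sand volume (no porosity division),
matching how sand-column rates are conventionally reported; a porosity
option is deliberately absent rather than defaulted wrong. Time-varying
flow is supported per timepoint (oxygen-pulse experiments raise Q).
Negative rates (consumption) are flagged, not raised. The default
integration depth for areal fluxes is 0.5 cm — the conservative advective
penetration depth of substrate-rich surface water under wave pumping, not
the full 2 cm bed — and areal flux is linear (hence additive) in depth.
The CH₄:CO₂ remineralization ratio divides the DIC rate by the CH₄ rate
(reported as 1:n), linearly interpolating DIC onto the CH₄ timestamps;
carbonate re-equilibration effects on DIC are ignored. "Maximum rate" is
reported as the single-timepoint maximum; a windowed mean is available via
the OLS fitter. Slurry rates are OLS slopes over a user window (≥3 points)
with standard errors, per vial and per gram wet sediment.

## Metabolite closure

Methyl equivalents are Σ concᵢ × methylsᵢ with the methyl-group table
shipped as data (TMA/TMAO/choline/glycine betaine = 3, DMSP/DMS = 2,
methylamine/methanol = 1); uncertainties propagate in quadrature and the
sum uses exact (fsum) accumulation so panel order cannot change the result.
The methyl→CH₄ yield is an open stoichiometric choice: disproportionation
(4 CH₃ → 3 CH₄ + CO₂, factor 0.75) is the default because it is the
canonical methylotrophic pathway without external electron donors, and a
1.0 mode is provided; neither is labelled authoritative. Supply to a
reactor is panel concentration ÷ extract dilution (default 20:1; 50:1 used
in oxygen-pulse protocols) × flow. Closure above 100% is flagged, and the
unexplained remainder is reported as its own line item, never imputed to
unmeasured compounds.

## Marker-gene normalization

RPKM = reads / (length/1000) / (library/10⁶). Community fraction =
100 × target RPKM / mean(marker RPKMs) over 14 single-copy ribosomal
markers; the marker list ships as configurable placeholder ribosomal-
protein ids because the arithmetic, not any particular database, is the
contract. Identity/coverage read filtering is upstream of this package:
inputs are post-filter count tables. Fraction estimates are invariant to
uniform library-size scaling (the ratio cancels it) and unbiased on the
forward multinomial simulator within Monte-Carlo error.

## Synthetic-data generators

Generators are pure functions of (scenario, seed); one global seed fans out
to per-stream child seeds (`SeedSequence.spawn`) so adding a stream never
perturbs existing outputs. Defaults encode the study conditions the
package targets: surveys of 12 sites × 3 replicates spanning 380% to
189,000% saturation (log-uniform, endpoints pinned), ~8% lognormal
replicate CV, radon either independent of CH₄ (no-groundwater) or
proportional to it; twice-daily (9 am/3 pm) annual Weibull winds with mean
5 m s⁻¹; FTR series with a 20 h onset lag, logistic growth to
48 µmol cm⁻³ h⁻¹, an asymptotic 1:9 CH₄:CO₂ carbon ratio, and an optional
3 h-per-24 h oxygen-pulse schedule with a 1.5 h recovery lag; slurries at
0.5 µmol h⁻¹ production sampled every 24 h with 2 mL He in/2 mL out; and
count tables whose mcrA carriers hold 0.2% of community abundance at
10⁷ reads. Noise models are lognormal for concentrations, Gaussian for
instrument readings (ppm), and multinomial for reads.

The generators deliberately omit instrument drift and calibration error,
tidal/diurnal structure in wind and temperature, kinetic (non-equilibrium)
headspace exchange, and sequence-level read simulation. Passing tests
therefore demonstrate that the calculation chain is self-consistent and
correctly inverts its own physics at realistic magnitudes — not that any
particular field dataset is reproduced. Field-specific published flux
values that depend on external wind records and unpublished concentration
tables are accordingly not regression targets anywhere in the suite.

## Numerical choices and problem sizes

All internal arithmetic is double precision in kelvin/mol/L/atm/h with one
conversion module (`units.py`) holding every factor. Acceptance-style
checks run on deliberately small problems — a 16 × 11 T×S round-trip grid,
12-site surveys, 60–120 h reactor series at 1 h steps, 500-replicate
count simulations at 2 × 10⁶ reads — chosen so the whole suite and the
acceptance script each complete in seconds while leaving the statistical
tolerances honest (tolerances are derived from the programmed Poisson /
binomial errors, 3–4σ, not tuned). Degenerate inputs follow one rule:
physically meaningless values (negative concentrations, zero depth,
non-positive observed rates) raise; measurable-but-awkward outcomes (zero
CH₄ rate in a ratio, over-closure, zero fold-change baseline) are flagged
in the output instead.

## Known limitations

- Solubility constants are validated by cross-transcription agreement and
  physical monotonicity, not against the original reference's printed check
  table, which is not distributable here.
- The Schmidt polynomial is the 1992 parameterization for consistency with
  the `marelac`-based workflow it mirrors; the 2014 re-fit differs by a few
  percent.
- Radon corrections beyond decay, GC/LC–MS calibration, read QC/mapping
  and porosity effects are explicitly out of scope.
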