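# Methods

This note documents the models implemented in `dustrisk`, the defaults they
ship with, the numerical choices behind them, and what the synthetic data
and the test suite do and do not establish about real stockpiles.

## Source term

The emission rate of one size fraction is the aggregate-handling emission
factor times the material throughput:

```
ER [mg/s] = V·ρ_b · k · 0.0016 · (U/2.2)^1.3 / (M/2)^1.4 · (1−η) · 10⁶
```

- `V` — disturbance rate, m³/s (configs accept m³/h with a unit tag;
  default 500 m³/h).
- `ρ_b` — bulk density, Mg/m³, converting disturbed volume to handled mass.
  The emission factor is defined per megagram handled, so a density is
  required dimensionally; the default of 1.0 Mg/m³ recovers the bare
  factor-times-volume form. Override it for compacted or fluffy slag.
- `k` — size multiplier: 0.053 (PM2.5), 0.35 (PM10), 0.74 (TSP), the
  standard aggregate-handling values; all overridable.
- `U` — mean ground wind speed, m/s (default 2).
- `M` — moisture content as a percent-valued number (default 30, i.e.
  30 %), the emission-factor convention. Passing 0.30 would overstate
  emissions by ~600×; the convention is fixed, only the value is
  configurable.
- `η` — dust removal efficiency in [0, 1] (default 0.5).

The exponents make the model a pure power law in `U` and `M` and exactly
linear in `V` and `(1−η)`; several tests and the sensitivity closed forms
rest on that structure.

## Plume model

Concentration at a receptor `(x, y, z)` downwind of a continuous source at
stockpile height `h` is the Gaussian plume with full ground reflection,
multiplied by a settling depletion factor:

```
C = ER/(2π U σy σz) · exp(−y²/2σy²) · [exp(−(z−h)²/2σz²) + exp(−(z+h)²/2σz²)]
    · exp(−g·x·(ρ−ρa)·d²/(18 μ U))
```

The settling exponent is the Stokes terminal velocity `g(ρ−ρa)d²/18μ`
times the travel time `x/U` per unit mixing depth. It is the only term
that distinguishes the size fractions beyond their emission rates, and it
produces the characteristic downwind shift from coarse- to fine-fraction
dominance of metal exposure.

**Particle density units.** The scenario literature sometimes prints slag
dust density as "1.21 kg/m³", which is within half a percent of the density
of air and would disable settling entirely — contradicting the observed
coarse-to-fine shift. We read those figures as g/cm³ and ship 1210 kg/m³
(range 1030–1360). The literal reading remains available: construct the
`ParticleClass` with the printed value and pass `allow_buoyant=True` to
`settling_factor` where the particle is lighter than the air.

**Dispersion coefficients.** `σy`, `σz` are piecewise power laws
`γ·x^α` per Pasquill stability class in the dialect of the Chinese
dispersion guideline GB/T 3840-1991. The stability class of the original
scenario is unstated; we ship the neutral class-D table (near-field band to
1000 m, far-field band beyond) as the default and accept full custom tables
in the config. Published band tables are only approximately continuous at
the band breaks; at construction we re-anchor each band's `γ` to match the
previous band at the break, keeping `σ(x)` continuous and strictly
increasing — which the compliance-distance solver requires and which
changes far-field σ values by ≲3 % relative to the raw table.

**Receptor defaults.** Height 1.5 m (adult breathing height), crosswind
offset 0. The release height equals the stockpile height (no plume rise —
a passive dust source).

**Mass budget.** With settling disabled, `U·∬C dy dz` over the half-space
recovers `ER` exactly (the reflection term folds below-ground mass back);
the test suite verifies this to 0.5 % by quadrature. With settling active
the plume is deliberately non-conservative: deposited mass leaves the air.

## Risk characterisation

Intake per body weight: `Q = PM_i·DAIR·ED·PIAF·EF·10⁻⁶/(BW·AT)`, with
`PM_i` in mg/m³; the 10⁻⁶ makes `Q` a kg-dust/kg-bw/day quantity so `Q·C`
(content `C` in mg/kg) is a dose in mg/kg-d. Then `CR = Q·C·SF` on the
lifetime averaging time and `HQ = Q·C/(RfD·SAF)` on the exposure-duration
averaging time. Acceptability thresholds: CR 10⁻⁶, HQ 1.

Shipped exposure defaults are the adult inhalation route of HJ 25.3-2019
(DAIR 14.5 m³/d, ED 24 a, EF 350 d/a, PIAF 0.75, BW 61.8 kg, AT 27740 d
carcinogenic / 8760 d non-carcinogenic, SAF 0.5). Slope factors and
inhalation reference doses are standard inhalation toxicity values; Pb and
Hg carry no slope factor here, so they produce no CR entry, and Pb is
assessed through exceedance multiples only. Ambient metal limits follow the
GB 3095-2012 reference concentrations and soil screening values the
GB 36600-2018 Class II levels. Every constant is a config table, not a
hard-coded number, and tests that depend on them use inverted-content
fixtures rather than asserting the constants.

Screening indices: PHI-E = C / soil screening value;
PHI-H = C·TSP_limit·10⁻⁶ / air limit, i.e. the metal concentration implied
by dust at the ambient TSP standard (80 µg/m³) against the metal's own air
standard. Cr(VI)'s tiny air limit (2.5×10⁻⁵ µg/m³) is what drives its
PHI-H into the hundreds at sub-percent PHI-E.

**Content calibration.** Measured dust contents are often unavailable.
`calibrate_contents` inverts the linear relation between contents and
modelled metal air concentrations to find the contents that reproduce a
set of target exceedance multiples at a reference distance (default
1000 m), splitting each metal across fractions by a fixed PM2.5/PM10
enrichment ratio (default 2). The inversion is exact (linear), so
round-trips reproduce the targets to solver precision. Because the model's
absolute dust concentrations under the default scenario are small,
contents calibrated to large multiples can exceed physically plausible
values; they are a consistency device for exercising the chain, not
estimates of real slag composition.

## Compliance distances

The ground-level concentration of an elevated source rises to a maximum
near the source and then decays monotonically. The solver locates the
maximum on a 512-point log grid over [10 m, 20 km], brackets the crossing
on the decaying tail and refines it by Brent root-finding to ≤1 m. A limit
never exceeded returns the lower window edge flagged `already_compliant`;
a limit not reached inside the window returns the upper edge flagged
unattained — both results, not exceptions.

## Uncertainty and sensitivity

Each uncertain parameter is a bounded distribution (min, max, central).
Families: truncated lognormal matched to the stated mean by solving for the
log-location at fixed log-scale 0.5 (used when the mean sits off-centre:
wind speed 2 on [1, 6], disturbance rate 500 on [250, 2500] m³/h);
triangular with the central value as mode (pile height 15 on [5.2, 19],
moisture 30 on [21, 44], density 1210 on [1030, 1360] kg/m³); uniform for
the removal rate on [0, 1]. All sampling is inverse-CDF on a
`numpy.random.default_rng(seed)` stream, so ensembles are bit-reproducible
and all draws respect their bounds by construction. The default ensemble
size is 10 000 draws, each re-running the full deterministic chain at the
1000 m reference receptor.

Sensitivity ratios perturb one parameter to ±25 % of its default and
report the larger-over-smaller ratio of the selected output (default: the
PM2.5 concentration at the 500 m residential receptor). For parameters
entering as pure power laws the ratio has the closed form
`((1+δ)/(1−δ))^|exponent|`: moisture 1.4 → 2.045, removal rate (linear in
1−η around 0.5) → 1.667, disturbance rate → 1.667. Wind speed couples the
emission power law (+1.3), the plume denominator (−1) and the settling
exponent, giving ≈1.20 at 500 m; particle density enters only the settling
exponent and gives ≈1.03 for 2.5 µm particles there. A perturbation that
leaves the physical range (η beyond 1) is clipped with a warning; if the
clipped endpoint shuts the source off the ratio is reported as infinite.
Uncertainty spans evaluate the same output at the range extremes; the
disturbance-rate span is exactly 10 because the chain is linear in V.

## Synthetic cohorts

The generator emulates an 80-sample campaign of pulverised-slag assays,
two sieved size fractions per sample. Per metal, the coarse-fraction
content is lognormal (arithmetic mean anchored: Pb 325, Cd 33, Hg 6,
As 22, Cr(VI) 2 mg/kg; log-sd 0.5) and the fine-fraction content is the
coarse content times a per-sample lognormal enrichment ratio (mean 2,
log-sd 0.2; Cd 1.5 so that fine-fraction Pb remains the largest PHI-E
contributor). Anchors were chosen so the two reported cohort means are
reproduced (Pb PM2.5 650 = 325×2, Cd PM10 33 mg/kg) and every mean PHI-E
stays inside (0, 1). The multiplicative coupling makes per-sample
fine ≥ coarse hold in ≥95 % of samples, as enrichment in real sieved pairs
does.

Trace analytes (Ni, Be) are detected with probability 0.08 per sample and
fraction; the number of detects is drawn from the binomial truncated below
a 10 % ceiling, so the realized cohort always shows the "sporadically
detected" pattern rather than crossing it by sampling luck. Organics carry
detection probability 0. Non-detects are explicit (NaN content with a
`detected` flag), excluded from summary means — the standard censored-assay
convention, not zero-substitution.

What the generator does **not** emulate: inter-metal correlation across
samples, spatial structure of the pile, analytical measurement error
distinct from natural variability, and values below a quantification limit
for the key metals. Tests passing on synthetic cohorts therefore establish
that the pipeline handles realistically structured inputs, not that real
slag has these contents.

## Problem sizes

The shipped defaults run the full pipeline — 20-point profiles, compliance
solves, a 10 000-draw ensemble and seven sensitivity pairs — in a few
seconds; the test suite uses ensembles of 300–10 000 draws and 1 m-step
scan oracles over the 20 km window, all chosen as the sizes at which the
statistical assertions (3-standard-error bands, 2 % median stability) are
comfortably discriminating.

## Known limitations

- Single constant wind direction and speed; no joint meteorology, seasonal
  cycle, or wind-rose weighting.
- No plume rise, building downwash, terrain, or dry-deposition flux to
  soil (the settling factor removes mass from the plume but does not track
  where it lands), and no resuspension of deposited dust.
- Inhalation route only; ingestion and dermal exposure, child receptors,
  and bioavailability/speciation adjustments are out of scope.
- The dispersion-coefficient table is a neutral-class default; assessments
  of a specific site should supply the class fitted to local stability
  statistics.
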