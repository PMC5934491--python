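# Methods

`matbgc` implements the calculation chains of a low-light microbial-mat
biogeochemistry campaign: in situ irradiance calibration and spectral
decomposition, ¹³C-tracer carbon-uptake inference, ³⁵S whole-core
sulfate-reduction rates, and solid-phase Fe-S pool partitioning. No raw
field tables exist for this kind of campaign in public archives, so the
package ships a first-class synthetic-data module that emulates each
input family with known ground truth; every stage is tested by
parameter recovery against that truth.

## Light field

**Calibration model.** The PMT logger's response per gain level is
modeled as a power law, irradiance = a·signalᵇ, fitted by least squares
in log-log space on the descent samples where the PAR sensor is also in
range. A power law is a deliberate choice — the instrument is described
only as having "a calibration curve" — because it covers proportional
response (b = 1) with per-gain amplitude offsets and is strictly
monotone by construction; monotonicity is additionally asserted on a
dense probe grid after every fit. Gains missing sufficient PAR overlap
are a hard error rather than an extrapolation.

**Longpass decomposition.** With a longpass filter of cutoff λc and
transmission τ (0.90 for the filters modeled), the above-cutoff
irradiance is reading/τ; differencing successive cutoffs yields band
irradiances, and the unfiltered reading anchors the band below the
lowest cutoff. This is exact for any spectrum in the absence of noise
(verified against an independent 0.1 nm midpoint-quadrature oracle).
Noise can make the cumulative sequence non-monotone; negative bands are
clamped to zero and fractions renormalized to sum to one, with a flag
recording that clamping occurred. The PMT's slightly elevated
sensitivity at 500–680 nm (< 2% overestimate) is treated as a no-op:
readings are taken at face value, and the config exposes the
transmission as the only spectral correction. Sensor geometry (270°
scalar acceptance vs. cosine response) is not modeled.

## Carbon uptake

**Labeling fraction.** Atom fraction of label in the substrate pool by
mole balance: (label × labeled/total positions × purity) /
(label + ambient × vial volume). A singly labeled two-carbon acetate
with negligible ambient acetate gives exactly 0.5; the DIC default
(73.8 nmol label into ≈105 μmol L⁻¹ ambient DIC in 6 mL) gives ≈0.105.

**Rate fitting.** Isotope ratios are converted to atom fractions
(x = R/(1+R), applied identically to samples and the natural-abundance
baseline); excess ¹³C per vial is the baseline-subtracted atom fraction
times the vial's total carbon in nmol. The vial rate is the ordinary
least-squares slope over all time points including t = 0, divided by
the labeling fraction. OLS through all points (rather than a two-point
difference) is a design choice; with triplicates at t = 0, 24 and 60
light-hours it uses all information and is exact on noise-free linear
data. The time basis is the hours recorded in the input series
(natural-light hours for the field protocol). Light and dark rates are
fitted separately and reported with their difference; headline values
use the light rate. Negative fitted slopes are reported with a warning,
never clamped — a censored dark rate would bias the net rate.

**Extrapolations.** Cells per vial = blank-corrected filter carbon /
(106 fg μm⁻³ × (4/3)πr³) with r = 0.6125 μm (≈102 fg C per cell).
Areal rate assumes a gapless monolayer of disk cross-sections:
10⁸ μm² cm⁻² / (πr²) ≈ 8.5 × 10⁷ cells cm⁻², times the per-cell rate,
times 24 h d⁻¹. Both the 24 h basis and the no-packing-correction disk
tiling are deliberate: they are the only reading under which the
per-cell, areal and sulfide-equivalent numbers form a consistent chain;
the 10.5 h daylight alternative is exposed as `CellModel.daily_hours`.
The sulfide-oxidation equivalent is exactly twice the areal carbon rate
(2HS⁻ + CO₂ + 2H⁺ → 2S⁰ + CH₂O + H₂O).

**Quantum yield.** Photon delivery per vial = green-band fraction ×
total scalar irradiance × total absorptive cell surface (cell count ×
0.62 μm²) × 3600 s h⁻¹; yield = vial rate / delivery. The delivery is
computed from the band *fraction* times the *total* irradiance
(0.21 × 0.27 μmol photons m⁻² s⁻¹) rather than from any separately
stated per-band flux: a per-band flux of order 10⁻⁵ μmol m⁻² s⁻¹ is
dimensionally inconsistent with this chain (it would imply a yield far
above one), so it is treated as a suspected unit error and not guessed
at. The yield assumes every in-band photon hitting a cell is absorbed
and all cells are photoautotrophs, so it is a lower bound.

## Sulfate reduction

**Rate formula.** Volumetric rate per slice:
SRR = [SO₄²⁻] × a_TRIS/(a_TRIS + a_SO₄) × 1.06 / t, with the sulfate
pool as nmol S cm⁻³ whole mat (a helper converts porewater molarity via
porosity), activities in dpm and t in days. This is the standard
single-pool turnover form of the whole-core injection method; the 1.06
factor corrects for the slower microbial turnover of ³⁵S. The form is
linear only while tracer turnover is small; the package warns above 5%
turnover and the generator refuses truths implying > 100%. The 4 h and
6 h incubations are handled identically through the time field.

**Detection limit.** One-sided normal bound on process blanks:
mean + z(confidence) × sd with z(0.95) = 1.645 by default; the quantile
is configurable (e.g. 0.975 → 1.96). Slices with a_TRIS below the limit
are censored. For depth integration the censored slices contribute zero
by default — the conservative choice — with limit-substitution (the
rate an activity exactly at the limit would imply) available as an
upper-bound sensitivity analysis. Areal flux is the rectangle-rule sum
of rate × slice thickness, per core, summarized as mean ± sd across
cores. Radioactive decay schedules and counter efficiency are out of
scope; activities are taken as decay-corrected dpm.

## Solid phase

Pyrite-S = CRS − S⁰, clamped at zero with a warning when noise puts S⁰
above CRS. Fe(III) is reported as an interval rather than a point
estimate: the dithionite-extractable pool is the upper bound and the
pool minus all AVS (treating every AVS mole as FeS, the maximal
correction) the lower bound — the interval makes the "FeS is
negligible" inference checkable instead of assumed. Porewater
concentrations convert to whole-mat volume via porosity (default 0.92),
masses to volume via wet density (default 1.11 g cm⁻³); a single
bulk-average density is used for all slices, with per-slice densities
possible by constructing `MatPhysical` per slice. The Zn-acetate
preservation caveat (possible non-extractable Fe-acetate) is carried as
a report note, not a numeric correction. Depth convention: cm below the
mat surface, positive downward, half-open slices [top, bottom); layer
summaries are thickness-weighted and windows select slices by midpoint.

## Synthetic data

The generators define one simulated campaign per `ScenarioConfig`:

- **Light log** — a descent at 4.3 m min⁻¹ through a piecewise-
  exponential attenuation profile (stronger attenuation through the
  chemocline), anchored to 0.27 μmol photons m⁻² s⁻¹ at the 30 m cave
  center, followed by a 2 h mooring at the 30 m wall where a clear-sky
  decline modulated by cloud dips keeps the truth inside the observed
  0.021–0.084 μmol photons m⁻² s⁻¹ window. The true sensor law is a
  per-gain power law with automatic gain switching; PAR readings are
  masked below a 0.1 μmol m⁻² s⁻¹ floor, so the wall phase relies
  entirely on the calibrated PMT.
- **Filter sequence** — readings integrate a piecewise-constant wall
  spectrum (64% below 400 nm, 21% at 475–530 nm, nothing above 590 nm,
  a local minimum at 400–475 nm where chlorophyll absorption in the
  overlying oxic water bites) with transmission 0.90 applied above each
  cutoff.
- **Incubation** — natural-abundance and t = 0 triplicates plus
  light/dark triplicates at 24 and 60 natural-light hours; excess ¹³C
  grows linearly at true rate × cells × labeling fraction; dark vials
  run at 8% of the light rate. Defaults (7.155 × 10⁻⁹ nmol C cell⁻¹ h⁻¹
  over 1.16 × 10⁸ cells) put the vial rate at 0.83 nmol C h⁻¹.
- **³⁵S cores** — ten cores of seven 0.6 cm slices; each slice's true
  rate is a lognormal quiet background (median 0.8 nmol cm⁻³ d⁻¹,
  mostly below detection) plus Poisson-distributed hot spots drawn from
  10–99.2 nmol cm⁻³ d⁻¹, reproducing the observed pattern of mostly
  censored slices with strong within- and between-core heterogeneity
  and areal fluxes of a few tens of nmol S cm⁻² d⁻¹. Injected activity
  partitions between the sulfate and reduced-sulfur fractions by the
  turnover implied by the truth.
- **Solid phase** — piecewise-linear truth profiles (near-zero AVS, CRS
  rising to ~44 μmol cm⁻³ at depth, S⁰ at 0.12 μmol cm⁻³ in the top
  0.25 cm falling to 0.02 below 0.5 cm, flat dithionite Fe, seawater-
  level sulfate), sliced at 0.25 cm with exact piecewise-linear slice
  averages as the noise-free expectation.

**Noise model.** Multiplicative unit-mean log-normal noise for sensor
and chemistry measurements (positive-valued by construction) and
Poisson-like counting noise (normal approximation, sd = √activity) for
tracer activities, with a relative-sd override for controlled recovery
experiments. No instrument error magnitudes are documented for this
kind of campaign, so the defaults (2% sensors, 0.5% isotope ratios, 3%
filter carbon, 5% solid-phase chemistry) are deliberate, config-exposed
choices. Each generator draws from its own RNG stream keyed by
(seed, generator id), so adding a generator never perturbs another's
draws and equal seeds give bit-identical tables.

**What the generators do not emulate** — and hence what passing
recovery tests do not show about real data: radiative transfer in the
water column (the attenuation profile is prescribed, not derived), mat
growth or community dynamics, isotope fractionation during uptake,
DIC speciation chemistry, tracer diffusion away from the injection
line, and systematic (non-random) instrument drift. Recovery under the
synthetic noise model demonstrates the estimators are unbiased and
correctly inverted, not that field measurements carry these error
magnitudes.

## Numerical choices and degenerate inputs

- Band decomposition tolerates filtered readings exceeding the
  unfiltered total by a relative 10⁻⁹ before warning and clamping.
- Fractions are renormalized after clamping so they always sum to 1.
- `detection_limit` requires ≥ 2 blanks; `fit_calibration` requires ≥ 3
  overlap points per gain; `uptake_rate` requires ≥ 2 distinct time
  points and a natural-abundance baseline.
- Zero recovered activity, zero photon delivery, zero cells, and blank
  carbon above total carbon are hard errors, not silent zeros.
- Weighted layer sd is the population form (weights = thickness).
- Recovery tests at 5% noise use 100 seeded replicates; the bias of the
  mean recovered/true ratio is required below 2%. Problem sizes
  (10 cores × 7 slices, triplicate vials at three time points, ~1300
  light-log rows) match the simulated campaign design.

## Known limitations

- The calibration functional form is an assumption; instruments with
  saturating response need a different law (the `CalibrationCurve`
  container admits any per-gain monotone parameterization in principle,
  but only the power law is implemented).
- Censored-slice handling (zero vs. limit substitution) changes areal
  fluxes by up to the limit-equivalent rate times the censored
  thickness; both policies are exposed because the field convention is
  not fixed.
- The quantum yield inherits every assumption of the absorptive-area
  model (all cells photoautotrophic, no shading, full in-band
  absorption) and should be read as an order-of-magnitude lower bound.
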