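# Methods

## The energy-balance model

`streambem` implements the standard Wisconsin formulation of a daily
whole-fish energy budget, `G = C − (R + SDA + E + U)`, with all terms in
J/day. Consumption and respiration are power functions of mass multiplied
by temperature-dependence functions: the Thornton–Lessem unimodal curve for
consumption (maximum exactly at the preferendum `CTO`, zero at and above
the feeding ceiling `CTM`, clamped to 0 for `T ≥ CTM`, evaluated as-is at
low temperature where it decays naturally) and a simple exponential
`e^(RQ·T)` for respiration. Grams of oxygen and grams of prey are converted
to joules by the oxycalorific coefficient (`OXY`, default 13 560 J/g O₂)
and the prey energy density (`ED_prey`, default 3698 J/g wet mass, a median
larval-fish value appropriate when age-1 black bass feed on larval fish).

Assumptions worth stating explicitly:

- **Waste terms.** Egestion and excretion are constant proportions of
  *total* consumption (`E = FA·C`, `U = UA·C`), and specific dynamic action
  a constant proportion of respiration (`SDA = SA·R`). The classic
  Wisconsin convention ties SDA to assimilated consumption instead; that
  variant is available via `SimulationSettings(sda_on_consumption=True)`
  but is not the default, because the proportional-to-respiration form is
  the model this package implements.
- **Mass update.** `M_{t+1} = max(M_t + G_t/ED_pred, mass_floor)` with
  `mass_floor = 0.01 g`. No mortality is modelled; a starving fish is
  clamped at the floor and the trajectory records that clamping occurred.
- **Calendar.** A 365-day non-leap year, Julian days 1–365.
- **Growing season.** The longest run of consecutive days with a strict
  bioenergetic surplus (`G > 0`; `G = 0` days do not count). The
  *end of growing season* is the last Julian day with `G > 0`; simulated
  length is taken from the mass on that day, because mass declines after
  the season ends while length does not.
- **Length–weight.** `W = a·L^b` (W in g, L in mm) with fixture defaults
  `a = 4.83e−6`, `b = 3.191`, typical of black basses; used only to convert
  simulated masses to comparable lengths.

### Default physiological parameters

The shipped parameter set (`fixture_params()`) is a literature-plausible
black-bass-style fixture, not a measurement of any particular population:
`CA = 0.33`, `CB = −0.325`, `CQ = 2.65`, `CTO = 27.5 °C`, `CTM = 36 °C`,
`RA = 0.00279`, `RB = −0.355`, `RQ = 0.0811 °C⁻¹`, `FA = 0.104`,
`UA = 0.068`, `SA = 0.163`. The predator energy density `ED_pred = 4186
J/g` (≈1 kcal/g wet mass, juvenile centrarchid range) is likewise a fixture
constant; it is a required entry in any user parameter file because no
universal value exists. Simulation defaults are an age-1 fish of 6.4 g on
day 1, realized consumption `CP = 0.5`, and activity multiplier
`RACT = 1.0`.

## Thermal regime construction

Water temperatures are built per reach in two steps, in this order:
(1) each of the 12 monthly mean *air* temperatures is converted to water
temperature through a logistic response
`water = lower + (upper−lower)/(1+e^(steepness·(inflection−air)))`
(fixture coefficients 0.8 / 32.0 / 15.0 °C, 0.14 °C⁻¹ — a plausible
warm-temperate parameterization, configurable per run); (2) a
single-harmonic sine `T(d) = mean + amplitude·sin(2πd/365 + phase)` is fit
to the 12 monthly water values anchored at the mid-month Julian days
(15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349) and evaluated on
all 365 days. The fit uses the exact linear reparameterization
`mean + a·sin + b·cos` solved by least squares, so there is no iterative
optimizer, no initialization, and no convergence tolerance; amplitude is
reported nonnegative and phase in (−π, π]. The sigmoid saturates at high
air temperature, which is why historically cooler reaches warm more in
water terms than already-warm reaches under the same air-temperature
offset.

## Ensemble resampling and validation

Physiological constants borrowed from a surrogate species carry
unquantified error, which is propagated by resampling: each of 12
parameters (`CA CB CQ CTO CTM RA RB RQ FA UA SA ED_pred`; `CP`, `RACT`,
`ED_prey` and `OXY` are simulation inputs or physical constants and stay
fixed, overridable in config) is drawn independently from
`Uniform(base·0.95, base·1.05)` — the default `perturb_fraction` is 0.05 —
for each of `n_sets = 500` synthetic sets, using one named generator
(numpy `default_rng`, PCG64) so a seed fully determines the ensemble. Draws
violating the structural invariants (e.g. a perturbed `CTO` crossing `CTM`)
are redrawn whole rather than clamped, which would pile probability on the
margins; the redraw count is logged.

Each set is validated by simulating every validation temperature series
(one per reach-year), converting mass at the last surplus day of each
series to length, and averaging across series with equal weight (the
aggregation rule is a package choice; per-series comparison would be
stricter). A set passes if that mean length is within ±2.5% (relative) of
the empirical target length. A set with any series lacking a surplus day
has undefined length and fails. Ensemble outputs are summarized as the
arithmetic mean and the coefficient of variation using the sample (n−1)
standard deviation, reported as a proportion; a nonpositive mean leaves the
CV undefined (NaN) rather than sign-flipped.

## Projection

Validated sets are projected over every reach × scenario combination. The
five default scenarios are historical climate at `CP = 0.5`, moderate- and
high-emissions climates at `CP = 0.5`, and the moderate climate with
consumption suppressed (`CP = 0.45`) or enhanced (`CP = 0.55`). Per reach
the package reports the ensemble mean and CV of end-of-year mass and the
ensemble *median* growing-season duration (medians are robust to the
occasional set whose season splits in two). Scenario differences are
`(future − historical)/historical × 100`, reported to one decimal and
undefined where the baseline is nonpositive; regional summaries (median and
min–max range across reaches) can be restricted by a boolean reach mask
such as a historically occupied subset, since occupancy modelling is out of
scope here. Projection is a pure function of its inputs: simulation is
vectorized across (reach, parameter-set) pairs within a scenario — a year
costs 365 numpy operations regardless of network size — and chunked
execution produces identical results to a single pass.

## The synthetic world

`streambem.synthetic` generates everything the pipeline consumes. Monthly
air temperature at latitude φ is
`base − gradient·(φ − φ_south) + amplitude·cos(2π(m−7)/12) + ε`,
`ε ~ N(0, noise_sd)` — warmest month July, linear latitudinal cooling.
Defaults: 100 reaches between 28–32° N, `base = 14 °C`,
`gradient = 0.7 °C/degree`, `amplitude = 7.5 °C`, `noise_sd = 0.5 °C`.
Through the shipped sigmoid this produces water temperatures of roughly
8 °C in winter and 23 °C in summer: a groundwater-buffered warm-temperate
regime with a real winter deficit and summer temperatures at or below the
fixture `CTO` of 27.5 °C under every scenario — the regime in which the
projection design's directional expectations (warming lengthens the season
and raises growth) actually hold. Warming offsets are uniform across months,
+2.4 °C (moderate) and +4.4 °C (high) — fixture values representative of
end-of-century projections — with an optional north-amplified profile.

The validation fixture is manufactured from a known truth: the base
parameter set is simulated over 5 validation reaches × 3 years (yearly
`N(0, 0.8 °C)` offsets on the monthly climatology), and the mean simulated
end-of-growing-season length becomes the "empirical" target. Validation is
therefore a parameter-recovery experiment: the truth must pass at any
tolerance ≥ 0, and with 500 sets at ±5% perturbation a strict subset passes
at ±2.5% (about 10% of sets in practice).

What the generator does **not** emulate: spatial autocorrelation of climate
(noise is independent across reaches and months), stream-network topology,
groundwater mixing dynamics, interannual trends within the validation
window, or real occurrence data — the `occupied_hist` flag is an
independent Bernoulli draw. A green end-to-end test therefore establishes
that the *pipeline machinery* is correct and directionally faithful, not
that any particular real river network would show these magnitudes.

## Numerical choices

- Energy conservation is exact by construction: `G` is computed as the
  literal floating-point difference `C − (R + SDA + E + U)` in both the
  scalar and vectorized paths, so the identity holds bit-for-bit.
- The scalar and vectorized simulators may differ in the last ulp (SIMD
  vs scalar libm transcendentals); equivalence is asserted at 1e−12
  relative tolerance.
- Surplus days use strict `G > 0`.
- Output CSVs are written with `%.17g` floats and read back with
  pandas' round-trip parser, so write→read is exact; the metadata sidecar
  records config hash, seed and version but deliberately no timestamp,
  making identical runs byte-identical.
- All randomness flows from a single integer seed through derived
  sub-seeds (network, fixture, ensemble), so one integer reproduces a whole
  study.

## Limitations

Single cohort, no mortality or reproduction, no prey feedback; daily mean
temperature only (no diel cycles); the air–water sigmoid is stationary
(no hydrological change between scenarios); ensemble members are treated
as exchangeable (no likelihood weighting); the validation aggregation rule
(pooled mean across reach-years) is a declared choice, and per-reach-year
validation would retain a different subset.
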