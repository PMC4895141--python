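# Methods

## Development model

Development is driven solely by daily mean temperature, (Tmin + Tmax)/2,
with no diurnal interpolation, photoperiod response, transplanting shock,
or water/nitrogen stress. Accumulation starts the day after emergence
(that day is DAE 1); a stage's simulated DAE is the first whole day on
which the cumulative development units reach the cultivar's thermal
requirement. Whole-day, first-crossing accounting matches how stage dates
are recorded in field trials and sets an irreducible "rounding floor" of
roughly ±0.5 days on any fit.

The four response families:

| family      | parameters          | shape |
|-------------|---------------------|-------|
| GDD         | T_b                 | linear above the base, unbounded |
| exponential | T_b, TSEN           | saturating monotone, 1 − exp(−TSEN·(T − T_b)) |
| bilinear    | T_b, T_o, T_c       | linear rise to 1 at T_o, linear fall to 0 at T_c |
| beta        | T_b, T_o, T_c, TSEN | Yin-type unimodal, normalized to 1 at T_o |

The exponential and beta closed forms are this package's choices among the
standard rice-modelling variants: they reproduce the canonical schematic
shapes (saturating monotone without an optimum; unimodal with an optimum
and ceiling) and keep the parameter sets minimal. The exponential family
has no ceiling cutoff. The GDD rate is left on its conventional °C·day
scale while the other three are normalized to a maximum of 1; thermal
requirements are therefore family-specific and model comparisons are made
only in simulated days, never in accumulated units. Default schematic
values used throughout the tests: T_b = 8 °C, T_o = 30 °C, T_c = 42 °C,
TSEN = 0.25 (exponential) or 1.25 (beta).

## Calibration

The loss is the summed squared day error over flowering and maturity
jointly. The search is two-level:

- **Inner (closed form).** An observed stage on day d only brackets the
  thermal requirement between the units accumulated by day d−1 and by day
  d. θ is set to the mean of the interval midpoints across calibration
  trials. The midpoint matters: using the accumulated value *at* the
  observed date overestimates θ by about half a day's units on average,
  which measurably skews the outer search (on a noiseless test instance
  the loss at the true base temperature exceeded the loss at a base
  temperature 2.7 °C too low until the midpoint form was adopted). With a
  single calibration trial the midpoint lies strictly inside the trial's
  bracketing interval, so that trial's dates are reproduced exactly.
- **Outer (bounded search).** Either an exhaustive grid (used when one or
  two parameters are free, e.g. recovering T_b at 0.1 °C resolution) or a
  seeded Latin-hypercube multistart (24 starts, the best 4 refined by
  Nelder–Mead, first-found wins ties) for the 3–4 parameter families.
  Default bounds T_b ∈ [5, 15], T_o ∈ [25, 35], T_c ∈ [38, 46],
  TSEN ∈ [0.05, 3] °C bracket typical rice cardinal temperatures; all are
  overridable, and any parameter can be pinned.

Candidates whose simulation never reaches a threshold receive a finite
penalized loss ((span − obs)² + 10⁶ per failed trial) so the search is
steered, not aborted; a search in which every candidate is penalized
raises. Calibration is bit-reproducible given identical inputs and seed.

Fit metrics mirror standard crop-model evaluation: MAD (mean absolute
deviation, days), NRMSE (RMSE as % of the observed mean), and slope α,
intercept β and R² of the OLS regression of simulated on observed days;
the regression fields are reported absent for degenerate observations.

## ΔGST design

GST is the arithmetic mean of daily mean temperature over
[emergence, observed maturity], both endpoints included (the inclusive
convention shifts GST by well under 0.1 °C versus alternatives). Grouping
uses observed — never simulated — maturity, since the split precedes any
fitting. ΔGST thresholds are inclusive: a trial at exactly the threshold
calibrates. The ALL pseudo-threshold calibrates on every trial and
evaluates bias on the same trials; it is the control that separates
calibration-data coverage from model structure as the source of a bias
trend.

## Bias trends

Percent bias is 100·(sim − obs)/obs, positive when the simulated duration
is too long. Pooled across cultivars, bias is regressed on ΔGST at
τ = 0.025, 0.5, 0.975 by exact linear-programming minimization of the
check loss (HiGHS, tightened feasibility tolerances); among alternate
optima the lexicographically smallest (intercept, slope) is selected via
two epsilon-constrained follow-up LPs, making results deterministic to
~10⁻⁸. For numeric thresholds only validation (held-out) points enter the
pooled trends — they measure predictive bias; under ALL the same points
necessarily serve both roles. Extreme quantiles require ≥ 40 points and
are otherwise reported absent with a warning; quantile-line crossings
within the observed range (possible in small samples) are logged, never
hidden.

Per cultivar × model × stage, the bias trend is tested by the two-sided
t-test on the OLS slope of percent bias against ΔGST (significant at
P < 0.05, ≥ 4 points required). The choice of an OLS slope test is this
package's own; its type-I error is verified by simulation to sit at the
nominal 5% level.

## Synthetic data generator

Site weather is a sinusoidal seasonal cycle (annual mean + amplitude,
warm peak in mid-July) plus an optional AR(1) daily anomaly with marginal
SD `noise_sd` and lag-1 autocorrelation `ar1`; Tmin/Tmax sit symmetrically
around the daily mean (default diurnal range 8 °C). GST variation comes
from both a ladder of site climates and emergence-date spread within the
window, mirroring multi-site, multi-year trial networks. Observed stage
dates are the truth-model simulation plus independent rounded Gaussian
noise per stage (floored so records stay valid). A cultivar whose realized
ΔGST span misses the design target by more than the configured tolerance
raises before anything is written.

What the generator does *not* emulate: real station climatology and
geography, weather variables beyond temperature, year-to-year trends,
cultivar × management interactions, or measurement protocols that differ
between stations. Passing tests therefore demonstrate correctness of the
pipeline and the *mechanism* of model-mismatch bias, not the magnitude of
bias in any real trial network.

### Study conditions used by the test suite

Chosen once as realistic for temperate/subtropical rice networks and
sized to run on a single CPU in minutes:

- **Matched-family recovery**: 1 cultivar × 40 noiseless trials, 8-site
  ladder (annual means 17–20 °C, amplitude 9 °C), ΔGST ≤ 2 °C split.
- **Mismatch experiment**: 10 cultivars × 28–34 noiseless trials, 12-site
  ladder (annual means 16–23 °C, amplitude 13 °C — warm-site summer daily
  means of 36–37.5 °C exceed the optimum-temperature search region), GDD
  truth with θ = 1000–1090 / 1800–1908 °C·d (maturity 68–104 DAE),
  target ΔGST span 8 °C; fitted families GDD (matched), bilinear and
  beta at thresholds 2 °C and ALL. A linear no-optimum truth is used
  because a saturating truth can be absorbed in-sample by the flexible
  beta family, leaving its ALL-control trend at numerical-noise scale.
- **Constant-regime recovery**: 60 noiseless growth-chamber-style regimes
  evenly spanning 18–30 °C, emergence days drawn from doy 100–140.

## Known limitations

- The day-rounding floor means MAD can never reach 0 on realistic data;
  values ≤ 1 day are at the discretization limit.
- The bilinear/beta ALL-control median slopes on noiseless data are
  near zero by construction; sign comparisons there are meaningful only
  for families whose mismatch is actually expressed (the beta family in
  the shipped design).
- Quantile trends pool cultivars; cultivar-stratified pooling is handled
  only through the per-cultivar slope tests.
- Yield consequences of phenology bias are out of scope; the pipeline
  exports per-trial simulated stage dates for consumption by an external
  crop growth model.
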