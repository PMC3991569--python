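# Methods

## Soil-temperature recursion

The simulator treats one soil layer at depth `Z_S` as a single thermal
store updated once per day:

```
T(t) = T(t−1) + α·(T_AIR − T(t−1)) + β·(T_LOW − T(t−1))
```

`α` is the fraction of the layer–air temperature difference closed in one
step, `β` the corresponding fraction toward the deeper soil.  Both derive
from a finite-difference collapse of one-dimensional heat conduction in
which the conductivity profile is replaced by a constant: the surface
fraction is `Δt·K_T / (C_A·(2Z_S)²)` and the lower fraction
`Δt·K_T,LOW / (C_S,LOW·(2Z_l)²)`, with `Z_l = 2·Z_S` by default (the depth
at which the lower-boundary temperature is taken to act).  Assumptions
inherited from this simplification: soil-moisture dynamics are ignored
(the model degrades under very wet or very dry conditions), the lower
boundary temperature `T_LOW` is constant in time, and all heat transfer is
vertical.

Three physically motivated mechanisms complete the update:

- **Snow insulation.** The surface coupling is damped by `exp(−f_S·D_S)`
  with `f_S` in m⁻¹ and snow depth converted mm→m inside the factor, so a
  50 cm pack with `f_S = 4` attenuates the air coupling to `e^−2 ≈ 0.14`.
  The lower-boundary term is not snow-damped — snow lies above the layer,
  not below it.
- **Apparent heat capacity.** At or below the ice threshold (default
  0 °C) the layer responds with capacity `C_S + C_ICE`; the latent term
  represents heat absorbed or released by phase change, and makes frozen
  soil strictly slower to respond.  The switch condition is evaluated on
  the previous day's temperature.
- **Stability clamp.** Each fraction is capped at 1, and if `α + β > 1`
  both are scaled by `1/(α+β)`.  For thin layers (a 1 cm surface layer is
  the configured stand-in for 0 cm sensors) the raw surface fraction
  exceeds 1 over much of the sampling range; the clamp keeps every update
  a convex combination of `T(t−1)`, `T_AIR` and `T_LOW`, which is also the
  boundedness property the tests enforce.  The alternative — sub-daily
  sub-stepping — was rejected to keep the 10⁵-run calibration cheap.

Initialisation: `T_init` defaults to the mean air temperature of the
first 14 forcing days; a 365-day spin-up (simulated, then discarded) is
the default in the CLI and in all shipped experiments, long enough for
the slowest configurations in the sampling ranges to forget the initial
condition.

Setting `K_T,LOW = 0` removes the lower term exactly; additionally
`f_S = 0` (or zero snow) recovers the plain air-driven relaxation —
these nestings are exact, not approximate, and are tested as such.

## Parameter ranges and calibration

The seven calibratable parameters are drawn independently and uniformly:

| parameter | unit | range | role |
|---|---|---|---|
| `C_S` | J m⁻³ °C⁻¹ | 0.5–3.5 ×10⁶ | heat capacity of the layer |
| `K_T` | W m⁻¹ °C⁻¹ | 0–1 | conductivity to the surface |
| `C_ICE` | J m⁻³ °C⁻¹ | 4–15 ×10⁶ | latent (freeze/thaw) capacity |
| `f_S` | m⁻¹ | 0–10 | snow insulation strength |
| `T_LOW` | °C | 0–1 | lower boundary temperature |
| `K_T,LOW` | W m⁻¹ °C⁻¹ | 0–1 | conductivity to the lower soil |
| `C_S,LOW` | J m⁻³ °C⁻¹ | 0.5–3.5 ×10⁶ | lower soil heat capacity |

The first two thirds (by count, in time order, ceiling rule) of the
non-missing observations form the calibration window, scored with
Nash–Sutcliffe efficiency; the remaining third is reported with NS, R²
(squared Pearson correlation) and RMSE.  Missing observation days are
excluded pairwise from all scores.  Runs are ranked by calibration NS
with ties broken by run index.  The top-5000 runs feed posterior CDFs
(values normalised to the sampling range, so a flat CDF means an
insensitive parameter); the top-100 are the behavioral set used for
projection.  The default 100 000 runs are the study-scale setting; the
shipped tests and the acceptance script use 20 000, which the recovery
experiment shows is ample for a three-year record (the daily loop is
vectorised across runs, so 20 000 runs over four years cost a few
seconds).  Sampling is plain independent uniform — no Latin hypercube —
matching the rank-based selection logic, which involves no likelihood
weighting or MCMC.

## Bias correction

Quantile mapping `x* = F_obs⁻¹(F_contr(x))`, fitted per calendar month and
variable over a common control period: Gaussian (μ, σ, maximum
likelihood) for temperature, Gamma (shape, scale, MLE with location fixed
at 0) for wet-day precipitation.  Choices:

- **Monthly windows.** Fitting per calendar month is required for the
  correction to preserve month-resolved change signals; at least 30
  usable values per side per month are required.
- **Wet-day threshold 0.1 mm.** Days at or below it pass through as 0.
  Optional wet-day frequency adaptation (raising the control threshold to
  the control quantile of the observed dry fraction) is available but off
  by default.
- **Tail handling.** CDF arguments are clipped to [10⁻⁶, 1−10⁻⁶]: a
  scenario value beyond the fitted control range maps to an extreme
  observed quantile rather than being extrapolated.
- Temperature and precipitation are corrected independently (the transfer
  is univariate); inter-variable correlation is not adjusted.

The defining round-trip property — correcting the control run reproduces
the observed monthly means — is exact for the Gaussian branch up to
clipping, and is verified to 0.1 °C on 30 synthetic years.

## Snow and weather generation

Scenario forcing carries no snow depth, so a single-layer degree-day
model supplies it: precipitation on days below 0 °C accumulates as snow
water equivalent (SWE); melt is `3 mm SWE °C⁻¹ day⁻¹` above 0 °C, capped
at the stock; depth = SWE / 0.25 (bulk density ratio).  This is a
deliberate minimal gap-filler — no energy balance, compaction, canopy
interception or rain-on-snow — and projected winter soil temperatures are
conditional on it.  It is bypassed whenever observed snow depth is
available.

The weather generator emulates a middle-boreal Swedish climatology:
annual mean 2.4 °C, seasonal half-amplitude 11 °C peaking in mid-July,
AR(1) temperature noise (φ = 0.7, innovation SD 2 °C — `noise_sd` is the
innovation SD, not the marginal SD), and Bernoulli–Gamma precipitation
(wet-day probability 0.45, Gamma(0.8, 4.4 mm)), giving ≈ 580 mm yr⁻¹.
What it does not emulate: weather-regime persistence beyond AR(1),
temperature–precipitation cross-correlation, trends, and observed snow
micro-variability.  Passing recovery tests on this generator therefore
demonstrate the machinery is correct and identifiable under realistic
signal/noise — not that any specific field site is well described.

Soil "observations" are manufactured by running the recursion with known
parameters, adding Gaussian noise (default 0.3 °C) and masking a random
fraction of days (default 10 %), mimicking the gaps of long-term
monitoring records; the hidden truth is returned for recovery tests.

## Projection

Each ensemble member is simulated under every behavioral parameter set
and reduced to the per-day **median** across sets (robust, consistent
with reporting ensemble medians across members).  Monthly climatologies
(calendar-month means over all years, requiring at least one full year),
scenario-minus-control deltas, per-year means with standard deviations
(complete calendar years only, SD across days within the year), and the
across-member ensemble median are reported as tidy tables.  Seasonal
DJF/MAM/JJA/SON roll-ups are available on top of the monthly resolution.

## Problem sizes in shipped experiments

The packaged experiments use 4 synthetic years (1 spin-up + 3 observed,
10 % gaps), 20 000 Monte Carlo runs, 30-year climate pairs for the
bias-correction round trip, and 2-member projection ensembles.  These
sizes make the recovery behaviour unambiguous (best NS ≈ 0.996 against a
0.3 °C noise floor) while keeping the full suite fast.

## Known limitations

- No soil-moisture coupling: conductivity and capacity are constants per
  layer, so very wet/dry episodes are outside the model's validity.
- `T_LOW` constant in time; multi-decadal deep-soil warming is not
  represented.
- The degree-day snow model is uncalibrated against snow observations;
  scenario-period snow (and hence winter soil temperature) inherits its
  structural uncertainty.
- Quantile mapping assumes distributional stationarity of model biases
  between control and scenario periods.
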