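# soiltherm

Daily soil-temperature modelling for snow-covered boreal forest soils, and
the machinery needed to use such a model for climate-impact studies:
distribution-mapping bias correction of climate-model output, Monte Carlo
calibration with Nash–Sutcliffe ranking, and ensemble projection with
monthly/seasonal/annual change summaries.

## The problem

Snow is a very effective insulator: a winter snowpack decouples soil
temperature from air temperature, so the soil response to climate warming
in boreal regions cannot be read off the air-temperature trend alone.
Assessing how soil thermal regimes — and the biogeochemistry they control —
respond to warming requires a soil-temperature model that (i) is cheap
enough to run 10⁵ times for uncertainty analysis, (ii) represents snow
insulation and freezing explicitly, and (iii) can be driven by
bias-corrected regional-climate-model (RCM) series.

## The model

One soil layer at depth `Z_S` relaxes daily toward air temperature from
above and toward a constant deeper-soil temperature from below:

```
T(t) = T(t−1) + α·[T_AIR(t) − T(t−1)] + β·[T_LOW − T(t−1)]

α = min(1, Δt·K_T / (C_A·(2·Z_S)²)) · exp(−f_S·D_S)
β = min(1, Δt·K_T,LOW / (C_S,LOW·(2·Z_l)²))
C_A = C_S                 if T(t−1) > 0 °C
    = C_S + C_ICE         otherwise
```

with thermal conductivity `K_T` (W m⁻¹ °C⁻¹), volumetric heat capacity
`C_S` (J m⁻³ °C⁻¹), latent (freeze/thaw) capacity `C_ICE`, empirical snow
parameter `f_S` (m⁻¹, snow depth `D_S` converted mm→m), and lower-boundary
parameters `T_LOW`, `K_T,LOW`, `C_S,LOW` acting at `Z_l = 2·Z_S`.  The
seven parameters are calibrated by uniform Monte Carlo sampling
(default 100 000 runs), ranked by NS over the first two thirds of the
non-missing observations; the top 100 runs ("behavioral" sets) drive the
projections, and top-5000 posterior CDFs diagnose parameter sensitivity.

Scenario climate is corrected by quantile mapping, `x* = F_obs⁻¹(F_contr(x))`,
with Gaussian CDFs for temperature and wet-day Gamma CDFs for
precipitation, fitted per calendar month against a control period.
A degree-day snowpack model supplies snow depth where it is unobserved
(e.g. scenario runs).

## Worked example

Calibrate against three years of synthetic observations with known truth
(`K_T = 0.8`, 0.3 °C observation noise, 10 % gaps), then project a +2 °C
air-warming scenario:

```python
import soiltherm as st

weather = st.simulate_snowpack(
    st.generate_synthetic_weather(st.WeatherGenParams(seed=1), n_years=4))
truth = st.SoilLayerParams(C_S=2.0e6, K_T=0.8, C_ICE=9.0e6, f_S=4.0,
                           T_LOW=0.5, K_T_LOW=0.3, C_S_LOW=2.0e6, Z_S=0.29)
spinup = st.SimulationConfig(spinup_days=365)
observed, _ = st.generate_soil_fixture(weather, truth, obs_noise_sd=0.3,
                                       missing_frac=0.1, seed=2, config=spinup)

result = st.run_monte_carlo(observed, weather, Z_S=0.29,
                            n_runs=20_000, seed=3, config=spinup)
behavioral = st.select_behavioral(result, top_n=100)

warm = st.simulate_snowpack(st.ForcingSeries(
    weather.dates, weather.t_air + 2.0, precip=weather.precip))
proj = st.run_ensemble(behavioral, {"warm2": warm}, weather,
                       Z_S=0.29, config=spinup)
```

This prints (via the obvious `print` statements):

```
best calibration NS : 0.996
behavioral K_T median: 0.784  (truth 0.8)
posterior KS distance: K_T 0.300, C_ICE 0.011
soil delta under +2 degC air: Jan +0.33, Jul +1.82 degC
```

The calibration recovers the generating conductivity; the Kolmogorov–
Smirnov distances of the top-5000 posterior CDFs from uniform show `K_T`
is strongly identified while `C_ICE` is nearly insensitive (classic
equifinality).  Under a uniform +2 °C air warming the snow-insulated,
partly frozen January soil warms by only ~0.3 °C while July soil warms by
~1.8 °C — the seasonal asymmetry that makes air-temperature-only
assessments misleading in snow-dominated regions.

The same pipeline is available from the shell:

```
soiltherm make-fixtures site/
soiltherm calibrate --config site/site.yaml --n-runs 20000 --seed 3 --out cal/
soiltherm bias-correct --obs-forcing obs.csv --control-forcing contr.csv \
    --scenario rcm1.csv --out rcm1_corrected.csv
soiltherm project --config site/site.yaml --behavioral cal/behavioral.csv \
    --control-forcing site/forcing.csv --scenario rcm1=rcm1_corrected.csv --out proj/
```

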