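# ricepheno

Rice phenology models disagree about what happens when it gets hot. The
growing-degree-day (GDD) and exponential response functions let development
keep accelerating (or saturate) with temperature; the bilinear and beta
functions impose an optimum temperature beyond which development slows.
When a model with the wrong temperature-response *shape* is calibrated on
trials from cooler growing seasons and then applied to warmer ones, its
phenology predictions drift — and that drift propagates into yield
simulation. `ricepheno` is a pipeline for studying exactly this failure
mode: it simulates days after emergence (DAE) to flowering and maturity
under the four response families, auto-calibrates cultivar parameters on
cooler-than-threshold trials, validates on the warmer remainder, and
quantifies how prediction bias trends with growing-season warming.

It is aimed at crop-model developers and climate-impact researchers who
need a controlled, fully synthetic testbed: the built-in generator produces
multi-site, multi-cultivar trial networks with *known* true parameters, so
every stage of the analysis can be checked against ground truth.

## The model

Daily development rate is a function of the daily mean temperature
T = (Tmin + Tmax)/2:

- **GDD** — r(T) = max(T − T_b, 0)
- **exponential** — r(T) = 1 − exp(−TSEN·(T − T_b)) for T > T_b, else 0
- **bilinear** — linear rise from T_b to 1 at T_o, linear fall to 0 at T_c
- **beta** (Yin-type) —
  r(T) = [((T − T_b)/(T_o − T_b)) · ((T_c − T)/(T_c − T_o))^((T_c − T_o)/(T_o − T_b))]^TSEN
  on (T_b, T_c), normalized to 1 at T_o

A stage is reached on the first day the running sum of r(T) from the day
after emergence meets the cultivar's thermal requirement θ_flowering or
θ_maturity. Calibration minimizes Σ (sim − obs)² in days over both stages:
an outer bounded search over the cardinal temperatures (grid or seeded
Latin-hypercube multistart with Nelder–Mead refinement) wrapped around a
closed-form inner step for the two θ values.

Per cultivar, each trial's growing-season temperature (GST; mean daily
temperature from emergence to maturity) is expressed relative to the
cultivar's coolest trial (ΔGST). Trials with ΔGST ≤ 1, 2 or 3 °C calibrate;
warmer trials validate. Percent bias 100·(sim − obs)/obs is regressed on
ΔGST at quantiles 0.025/0.5/0.975 (exact check-loss minimization by linear
programming), and per cultivar an OLS slope t-test flags significant bias
trends (P < 0.05).

## Worked example

```python
import numpy as np
from ricepheno import (CultivarParams, ModelId, ResponseParams,
                       calibrate_cultivar, validate_cultivar)
from ricepheno.synth import constant_regime_trials

truth = CultivarParams("cv", ResponseParams(ModelId.GDD, tb=8.0), 900.0, 1600.0)
trials, weather = constant_regime_trials(np.linspace(18, 30, 60), truth, seed=1)
res = calibrate_cultivar(trials, weather, ModelId.GDD,
                         method="grid", grid_resolution={"tb": 0.1}, seed=1)
print(res.params.response.tb, res.metrics_maturity.mad)
```

prints

```
8.0 0.31666666666666665
```

— the base temperature is recovered exactly at the 0.1 °C search
resolution from 60 noiseless constant-temperature trials, and the
calibrated model reproduces observed maturity dates to a mean absolute
deviation of 0.32 days (the floor set by whole-day rounding of stage
dates).

The full experiment — synthetic network, 4 models × thresholds × cultivars,
bias tables — runs from the command line:

```
ricepheno synth --design design.yaml --out data/ --seed 21
ricepheno run --config run.yaml --seed 3
```

Each run directory carries a manifest, Table-style calibration metrics
(n, MAD, α, β, R², NRMSE), tidy bias records, pooled quantile trends and
per-cultivar slope tests, all stamped with the seed and a config hash.

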