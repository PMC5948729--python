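# ricekey

Toolkit for monitoring heavy-metal stress in paddy rice by combining a
crop growth model with sparse field and satellite observations — and for
deciding **when** those observations are worth acquiring.

Heavy metals in paddy soil depress rice growth, and the root system
responds earliest and strongest; but root dry weight (WRT) cannot be
seen from space. The workaround implemented here is model-data fusion:

1. **Simulate.** A reduced WOFOST-style daily simulator
   (`ricekey.crop_model`) grows a rice season — phenology, light-limited
   assimilation, respiration, partitioning, leaf cohorts — with a
   dimensionless stress factor *f* ∈ (0, 1] scaling gross assimilation:

       gross = f · min(Amax, ε · I · (1 − e^(−k·LAI))),
       LAI   = Σ over live cohorts of LV(i) · SLA(i).

   Smaller *f* means a more stressed, slower-growing crop.
2. **Assimilate.** `ricekey.assimilation` estimates *f* by particle-swarm
   minimization of the mean squared misfit P = (1/n) Σ (obsᵢ − simᵢ)²
   against WRT measurements (g/m²) or satellite-retrieved LAI — per
   site, or independently per pixel to map stress over a field.
3. **Pick the key period.** `ricekey.keyperiod` rasterizes the seasonal
   LAI curve (and the stressed/reference LAI-ratio curve) into a
   grayscale image and runs Harris corner detection,
   R = det M − k (tr M)², on it. The corner days — growth onset,
   allocation shifts, canopy peak, senescence breaks — are the dates at
   which an observation constrains the model most, i.e. the dates worth
   tasking imagery and field campaigns for. Using only these few dates
   preserves the accuracy of assimilating every available image at a
   fraction of the cost.
4. **Retrieve.** `ricekey.retrieval` turns 4-band reflectance into LAI
   via the Green-Blue NDVI regression LAI = 0.3243·e^(5.3944·GBNDVI)
   and summarizes soil contamination with single-factor pollution
   indices (mean concentration/background, levels Safe / I / II).

`ricekey.synthetic` generates all study conditions — subtropical
weather, observation campaigns, known-corner curves, multi-zone
reflectance scenes — so the whole chain runs and is tested without any
field or satellite data. `ricekey.pipeline` + the `ricekey` CLI
orchestrate the workflows.

## Worked example

Generate a synthetic season with true stress factor 0.85 and 2 % noisy
root-weight observations, then calibrate:

```sh
$ ricekey synth --out synth --f-true 0.85 --rel-noise 0.02 --seed 42
$ cat > config.yaml <<EOF
weather_path: synth/weather.csv
observations_path: synth/observations.csv
output_dir: calib
n_days: 100
EOF
$ ricekey calibrate --config config.yaml --seed 1
{
  "f_hat": 0.8540658795750642,
  "cost": 2.489096056201301,
  "n_obs": 4,
  "r_squared": 0.9986401769852133,
  "mae": 1.2594941033088753
}
```

The swarm recovers `f_hat` ≈ 0.854 against a truth of 0.85 (the 0.004
gap is the observation noise); `cost` is the mean squared WRT misfit in
(g/m²)², and R²/MAE compare the recalibrated simulation with the
measurements at the four campaign dates.

Key-period selection from the simulated clean (f = 0.984) and stressed
(f = 0.850) LAI curves of the same season:

```python
from ricekey import (PipelineConfig, WeatherSeries, default_crop_parameters,
                     run_keyperiod, run_simulation)

w = WeatherSeries.from_csv("synth/weather.csv")
p = default_crop_parameters()
ref = run_simulation(w, p, 0.984, 170, 100)
stressed = run_simulation(w, p, 0.850, 170, 100)
merged, report = run_keyperiod(PipelineConfig(output_dir="kp"),
                               ref.lai, stressed.lai, 170)
print(report)
# {'points_lai': [178, 228], 'points_ratio': [199, 235, 253],
#  'merged': [199, 235, 253], 'fit_r_squared': 0.945715948293702}
```

The LAI curve contributes its growth-onset and canopy-peak corners, the
ratio curve the dates where stress divergence changes regime; the
growth-rate screen merges them into the key period (here three DOYs),
and a piecewise-linear fit through the merged points reproduces the
full curve with R² ≈ 0.95.

## Layout

| module | contents |
|---|---|
| `ricekey.crop_model` | weather/parameter containers, daily simulator, fast f-sweep path |
| `ricekey.assimilation` | observation sets, misfit costs, PSO, R²/MAE, stress summaries |
| `ricekey.keyperiod` | curve rasterization, Harris response, dominant-point detection/screening |
| `ricekey.retrieval` | GBNDVI, LAI regression (+ exact inverse), pollution indices, TIFF I/O |
| `ricekey.synthetic` | weather/observation/curve/scene generators |
| `ricekey.pipeline`, `ricekey.cli` | calibrate / keyperiod / retrieve / assimilate / compare workflows |

See `docs/methods.md` for the model description, parameter defaults and
the design decisions behind the detector settings.
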