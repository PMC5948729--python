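# Methods

## The crop model

`ricekey.crop_model` is a reduced daily simulator of a transplanted rice
season in the WOFOST tradition: thermal-time phenology, gross
assimilation, maintenance respiration, dry-matter partitioning into
root/leaf/stem/storage pools, and leaf-cohort bookkeeping, at a 1-day
step over a ~100-day season. The full canopy photosynthesis integration
is replaced by a Monteith-style light-interception law,

    gross = f * min(amax, lue * radiation * (1 - exp(-k * LAI))),

because every downstream use of the simulator in this toolkit touches it
only through its LAI and root-dry-weight (WRT) outputs; the cohort-based
LAI law — each day's leaf allocation forms a cohort that keeps the
specific leaf area (SLA) of its birth development stage and is dropped
entirely once older than `leaf_span` days — is preserved exactly, since
it is the part of the model the key-period analysis depends on.

Assumptions: potential production (water and nutrients never limit),
no CO2 response, one cultivar per parameter set, hard-cutoff senescence
(no gradual death rate; `leaf_span` is the only senescence parameter).
The heavy-metal **stress factor f ∈ (0, 1]** multiplies gross daily
assimilation and nothing else: it models reduced carbohydrate
assimilation efficiency under toxicity, and deliberately does not touch
phenology or partitioning, so simulated series are monotone
non-decreasing in f day by day (a property the tests assert for both
LAI and WRT).

Two further rules keep the trajectories physical:

* net assimilate is floored at 0 — maintenance demand in excess of the
  daily gain does not shrink organs;
* after `root_decline_dvs` (default DVS 1.7) the root pool loses a fixed
  relative weight per day (default 0.5 %/d), representing late-season
  root ageing; this is what makes the WRT series peak and then decline.

### Default parameters

| parameter | default | units | why |
|---|---|---|---|
| tsum emergence→anthesis | 1100 | °C·d above 8 °C | anthesis just past mid-season at ~27 °C means |
| tsum anthesis→maturity | 600 | °C·d | maturity near day 90 |
| amax | 350 | kg ha⁻¹ d⁻¹ | ceiling on daily gross gain |
| light-use efficiency | 25 | kg ha⁻¹ per MJ m⁻² | ≈ 2.5 g DM/MJ intercepted |
| extinction k | 0.6 | — | typical erect-leaf rice canopy |
| SLA | 0.0022→0.0016 | ha kg⁻¹ vs DVS | thinner leaves later |
| conversion efficiency | 0.7 | — | growth respiration cost |
| leaf span | 50 | d | cohort lifetime |
| initial weights | 40/40/10/0 | kg ha⁻¹ | transplanted seedlings |
| initial leaf age | 20 | d | seedlings are ~3 weeks old at transplanting |

The partition table has a **root-priority establishment phase**
(DVS < 0.2: 80 % of assimilate to roots) emulating transplanting shock,
then a leaf-dominated vegetative phase, a sharp reallocation to stem and
storage across DVS 0.62–0.72, and grain filling after anthesis. These
phases are what give the seasonal LAI curve its corner structure — flat
establishment, fast canopy growth, a mid-season slope break, a single
peak after anthesis, then decline — the structure the key-period
detector is designed to find. Fractions sum to 1 at every knot and are
interpolated linearly (which preserves the sum between knots).

Simulated WRT is compared with field data in g m⁻² (kg ha⁻¹ ÷ 10);
plot-level root weights scale from per-plant samples by the planting
density, default 9 plants m⁻².

### The fast path

Phenology, partition fractions and SLA do not depend on f, so
`phenology_schedule` precomputes them once per site and
`simulate_from_schedule` re-runs only the f-dependent arithmetic
(~0.2 ms per 100-day season). Cohort death days are deterministic
(cohort *i* dies on day *i* + span), so the fast path needs no per-day
age scan. It agrees with the cohort-object path to 1e-9 (float
accumulation order only); the suite asserts this.

## Stress-factor assimilation

`estimate_stress_factor` minimizes the mean squared misfit
P(f) = (1/n) Σ (obs_i − sim_i(f))² between observations (WRT in g m⁻²
or LAI) at a few dates and the simulated series, with a standard
global-best particle swarm: swarm 20, 50 iterations, inertia 0.7,
cognitive = social = 1.5, bounds f ∈ [0.5, 1.0], velocities clamped to
half the bound width, positions reflected at the bounds, explicit seed.
The objective is 1-D and smooth here, so the optimizer is far from
stressed — a 1e-4 grid scan agrees to 1e-3 in the tests — but PSO is
kept as the method because it generalizes to rougher objectives and
needs no derivative. With three noiseless WRT dates the true f is
recovered within ±0.01 across the calibrated range (0.82–0.98), and
within ±0.02 mean error under 1 % multiplicative observation noise.

All supplied observations enter the cost; `n_obs` is recorded. The
bundled synthetic campaigns use the last three of the four observation
dates for WRT calibration, since the first date falls in the
establishment phase where root weights are small and uninformative.

Evaluation metrics are the squared Pearson correlation R² (in [0, 1],
affine-invariant, undefined for zero-variance input — raised as an
error) and the mean absolute error.

## Key-period detection

The detector converts a seasonal curve into a grayscale image — one
column per day, one row per `y_step` of curve value — and finds
corner-like days with the Harris measure.

Rendering choices (the curve-to-image step is where all the freedom
lives, and these are frozen after considerable experimentation):

* the curve is drawn as a **connected 1-pixel Bresenham polyline**
  between consecutive days. Attributing a day's whole vertical run to
  one column (the naive fill) biases corner localization by several
  days; the Bresenham split removes that bias.
* 16 rows of empty headroom are padded above and below the curve so the
  reflective border handling of the filters never touches it.
* `rasterize_curve` defaults to `y_step` = 0.001 (the minimum daily LAI
  increment). For detection, however, the adaptive step
  `auto_y_step` = max |Δvalue| / 10 is the default: it keeps the
  steepest day-to-day move near 10 px/column, the aspect regime where a
  9×9 window actually sees orientation change at a bend. With a fixed
  fine step such as 0.001, fast-growth segments render as
  near-vertical lines whose bends a fixed-size window cannot
  distinguish from edges. Doubling the step moves detected days by
  ≤ 3 days on the bundled season fixture (asserted, as a regression
  bound, not a scale-invariance claim).
* light Gaussian pre-smoothing (σ = 1 px, 9×9 kernel), then Harris with
  Gaussian-derivative gradients at σ_deriv = 1 px, structure-tensor
  averaging with a 9×9 Gaussian window at σ_window = 3 px, k = 0.04
  (lower end of the conventional 0.04–0.06 range: most sensitive to
  weak corners).
* detection keeps pixels that are window-maxima of R **and** exceed
  0.01 × the interior maximum response (suppressing numerically-zero
  maxima on flat background); columns within half a window of the
  left/right border are not reported; several maxima in one column keep
  the highest-R row; points within 9 columns merge to the stronger one.

On synthetic single-break curves the detector localizes the corner
within ±1 day over the whole season; on smooth double-logistic curves
every detected point lies within ±3 days of a curvature extremum of the
analytic curve (curvature evaluated in the raster geometry, i.e. with
the value axis in pixels, since that is the geometry the detector
sees).

**Screening.** Points found on the stressed LAI curve and on the
stressed/reference ratio curve are merged: coincident within 2 days —
kept once; otherwise each point is paired with the nearest unpaired
point of the other set and, if the pair lies within 30 days (the scale
on which the two curves plausibly disagree about one feature), the one
with the larger |growth-rate change| over a ±3-day window survives,
ties going to the LAI-curve point; unpaired points are kept. The ratio
curve drops leading/trailing days where the reference LAI is below 0.05
(bare-field ratio is meaningless). `select_images` then maps each key
point to the nearest available acquisition date, earlier on ties.

On the default synthetic season the merged set has 3–5 points
(asserted as the 3–6 bracket); the screened result for the documented
four-plus-four input sets is the four dates 184/199/217/243.

## LAI retrieval and soil indices

GBNDVI = (NIR − (G+B)) / (NIR + (G+B)); LAI = 0.3243·e^(5.3944·GBNDVI).
The regression coefficients are treated as fixed constants of the
retrieval (no refitting). No saturation cap is applied; retrievals
above LAI 8 are counted and logged as suspicious. No-data is a
dedicated sentinel (−9999), never 0, since LAI 0 is legal; masked
pixels never enter any downstream statistic (audited in tests).

The single-factor soil pollution index is the per-area mean of
concentration/background. The full-precision value is returned; the
2-decimal report **truncates** rather than rounds (0.84/1.43 = 0.5874
is reported as 0.58), matching the reporting convention of the
reference soil tables this index reproduces. Levels: Safe ≤ 1 <
Level I ≤ 2 < Level II.

## Synthetic study conditions

The generators fix the study conditions used throughout the tests:

* **weather** — subtropical-monsoon summer: sinusoidal annual cycle
  sampled over DOY 170–269, daily means ~25–30 °C with σ = 1.5 °C
  noise, diurnal range ~8 °C, radiation ~14–22 MJ m⁻² d⁻¹ with
  σ = 3 noise, all seeded;
* **observation campaigns** at DOYs 184/211/241/260 with multiplicative
  lognormal noise of chosen relative sd;
* **zones** — a near-clean reference (f = 0.984) and a stressed zone
  (f = 0.850), the documented area-average values;
* **scenes** — per-pixel LAI from the crop model at the pixel's zone f,
  mapped to GBNDVI by the exact regression inverse and decomposed into
  bands at fixed brightness NIR + G + B = 0.6 with G = B (red fixed at
  0.05; it does not enter GBNDVI). The split is chosen for exact
  invertibility and is synthetic-only: real canopies do not pin
  brightness, and the generator has no radiative-transfer model, no
  atmosphere, no clouds or shadows, no mixed pixels, no sensor PSF.

Because scene reflectances encode the model's own LAI exactly (at zero
noise), the full-loop tests — scene → GBNDVI → LAI → per-pixel PSO →
f map, zone means recovered within ±0.02 — demonstrate the internal
consistency and numerical correctness of the chain, not retrieval skill
on real imagery. The same applies to the key-period accuracy
comparison: a 4-scene key period matches an 8-scene period to within
0.05 R² on this fixture because both recover the truth almost exactly;
on real data the gap depends on observation error structure.

Problem sizes in the test suite are deliberately modest — 8×8 or 6×6
pixel scenes, 20-seed noise studies, 50 random images for the detector
oracle — chosen so the whole suite exercises every loop end-to-end in a
few minutes on one core.

## Known limitations

* The reduced simulator has no water/nutrient limitation and a single
  stress scalar; it cannot represent stage-dependent toxicity.
* Harris detection is scale-dependent by construction; the adaptive
  `y_step` stabilizes it across fixtures but a multi-scale detector
  would be the principled fix.
* The pollution-level thresholds (1 and 2) are inferred from three
  reference classifications, not from the underlying soil standard.
* Which process block the stress factor should multiply is a modelling
  choice; scaling gross assimilation is recorded here as this package's
  choice, with phenology and partitioning left unstressed.
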