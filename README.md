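# grazerange

Do herded livestock displace wild deer?  `grazerange` is a Python toolkit
for answering that question from GPS telemetry: it implements the full
use–availability resource-selection workflow around *conservation grazing*
— targeted, low-intensity grazing with a herded flock used to keep
heathland and dry grassland open — and ships a synthetic-telemetry
generator with known ground truth so that every stage of the analysis can
be verified end to end.

It is written for quantitative wildlife ecologists working with collared
ungulates (2-hourly fixes, a few dozen animals, planar metric coordinates)
who want a reproducible, scriptable version of the classic two-step
analysis:

1. **Use model** — a random-intercept mixed logistic regression for the
   probability that a fix falls *inside* a grazing site, as a function of
   21-day treatment windows around each grazing term (*before*, *early* =
   days 1–21, *ongoing* = days 22–42, *after*), time of day (day / night /
   twilight from solar geometry), and calving/rut periods.
2. **Resource selection functions (RSF)** — each used fix is contrasted
   with 16 random points from the animal's home range (the 0.99 isopleth
   of a fixed-kernel density estimate over all its fixes); a mixed
   logistic model over scaled tree cover, NDVI and distance-to-site (plus
   quadratics and treatment/time-of-day interactions) is AIC-selected,
   and its significant coefficients (p < 0.05) form the exponential RSF

       w(x) = exp(β₁x₁ + β₂x₂ + … + βₙxₙ),

   validated by five-fold and animal-blocked cross-validation using
   binned, area-adjusted frequencies (Spearman's ρ between bin rank and
   used:available share).

The mixed models are fitted by an in-package marginal-likelihood maximiser
(adaptive Gauss–Hermite quadrature, analytic score, Wald inference) that
reproduces `lme4::glmer(nAGQ=15)` to four decimals on test data.

## Worked example

Run the bundled synthetic study (six animals, two grazing years) through
the whole pipeline:

```python
from grazerange.pipeline import run_pipeline

run_dir = run_pipeline({
    "seed": 1,
    "simulate": {"years": [2016, 2017], "n_animals": 6,
                 "n_fixes": 8760, "cell_m": 40.0},
    "analysis": {"ratio": 8, "kde_cell_m": 40.0, "quad_points": 9,
                 "cv": {"k": 3, "n_bins": 10}},
}, "scratch/demo")
```

The run directory then contains the relocations, schedules, home-range
GeoJSONs, coefficient tables, CV report, scenario maps and a manifest.
The manifest's accounting for this seed:

```
"fixes_labelled": 10368,
"per_treatment": {"before": 3024, "after": 3024, "early": 2808, "ongoing": 1512},
"cv_mean_rho": {"summer/random": 1.000, "summer/by_animal": 1.000,
                "winter/random": 0.992, "winter/by_animal": 0.992}
```

so 10 368 fixes fell inside treatment windows, and the fitted seasonal
RSFs order held-out habitat essentially perfectly (ρ ≈ 0.99–1.0 — on
synthetic data the model family is exactly right, so this is an upper
bound, not an expectation for field data).  The summer RSF table
(`rsf_model_summer.csv`) begins:

```
term        estimate   se      z       p
cover        0.2560   0.0146   17.5   8.9e-69
cover2      -0.2654   0.0114  -23.2   4.2e-119
ndvi         0.4830   0.0130   37.1   1.9e-301
dist        -1.2978   0.0323  -40.2   0.0
dist2       -0.5758   0.0157  -36.7   1.2e-294
```

Negative `dist`/`dist2` mean selection concentrated near the grazing
sites; positive `dist:treatment[...]` interactions (further down the
table) weaken that attraction while and after the flock is present — the
displacement signature.  Because the generator's truth is known, the run
also writes `recovery_summer.csv`, comparing estimates (re-expressed under
the generator's reference scaling) with the generating coefficients:

```
term                     truth  estimate   se      error    abs_z  sign_agree
cover                     0.40    0.3856  0.0170  -0.0144   0.85   True
dist                     -0.60   -0.6196  0.0256  -0.0196   0.77   True
dist2                    -0.50   -0.4979  0.0136   0.0021   0.15   True
dist:treatment[ongoing]   0.55    0.5684  0.0405   0.0184   0.46   True
```

— every effect within one standard error of truth here.

The same workflow is available from the shell:

```bash
grazerange run-all config.yaml --seed 1
grazerange simulate --out simulated --seed 0
```

## Library highlights

- `MixedLogit(y, X, groups).fit()` → estimates, SEs, Wald p-values,
  random-intercept SD, log-likelihood, AIC, `summary()`.
- `kde_surface` / `isopleth_polygon` / `sample_available` — kernel home
  ranges and timestamp-paired availability sampling.
- `assign_treatment`, `classify_time_of_day`, `exclude_hunt_windows`,
  `assign_season`, `flag_biological_periods` — temporal labelling.
- `build_rsf`, `predict_map`, `score_distance_profile` — RSF scores,
  scenario maps, displacement profiles.
- `kfold_cv`, `boyce_spearman`, `recovery_report` — validation against
  held-out data and against ground truth.
- `simulate_deer`, `generate_schedule`, `generate_landscape`,
  `simulate_use_series` — the synthetic world.

See `docs/methods.md` for the statistical details, generator assumptions
and numerical conventions.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main analysis from scratch: it simulates a
complete study system from the seed, runs labelling, home-range
estimation, availability sampling, both model stages, cross-validation and
map prediction (artifacts under `scratch/`), and writes the JSON report to
`--out`.
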