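# pestscape

Integrated species distribution modelling of tree pest and disease burdens.

`pestscape` is a desk-scale Python pipeline for mapping the spatial
intensity of pest/disease occurrence from two fused observation streams —
structured presence–absence inspections (detections out of repeat visits
per site) and opportunistic presence-background reports — and for
estimating the causal effects of landscape drivers on that intensity. It is
aimed at quantitative ecologists and plant-health analysts who want the
full chain (covariate engineering → causal covariate choice → integrated
model → maps and effect estimates) runnable and testable end to end on
synthetic data with known ground truth.

## The model

The shared process model is a log-Gaussian Cox process on a planar km grid:

    log λ(s) = α + Σ_k β_k x_k(s) + ξ(s)

where x_k are z-standardized covariate rasters and ξ is a Matérn (ν = 1)
Gaussian random field represented by the SPDE approach on a mesh, with
penalised-complexity priors p(σ > 1) = 0.05 and p(ρ < 10 km) = 0.05.
Presence–absence sites observe Binomial(n, p) detections with the cloglog
link p = 1 − exp(−e_vis·λ); presence-background points follow a thinned
Poisson process with a second Matérn field absorbing reporting bias.
Inference is empirical-Bayes Laplace: Newton optimization of the latent
Gaussian state inside a Nelder–Mead search over field hyperparameters.

Around the model, the package provides:

* covariate engineering: Gaussian-kernel connectivity (sd 3 km),
  distance-to-nearest-feature layers, per-cell habitat area/edge,
  z-standardization;
* causal analysis: DAG parsing, d-separation, minimal back-door adjustment
  sets, nested-DAG sensitivity sequences, per-driver effect estimation;
* WAIC covariate search over random candidate sets (5–20 covariates per
  model, 50 per size, 800 candidates) on the presence–absence stream;
* intensity prediction with 0–1 rescaled mean and sd maps, and Huber
  robust-regression residuals of intensity against host cover;
* a synthetic-data generator (linear-Gaussian structural causal model over
  covariates + LGCP observations) with fully known ground truth.

## Worked example

Simulate an integrated study with known truth (β = (1.0, −0.5), field
σ = 0.5, ρ = 10 km on a 50×50 km grid) and fit the joint model:

```python
import pestscape as ps

grid = ps.GridSpec(50, 50, 1.0)
scm = ps.ScmSpec(ps.parse_dag("node: x1, x2"), {}, seed=1)
covs = ps.stack_standardize(ps.simulate_covariate_fields(grid, scm))
truth = ps.TrueModel(alpha=-2.4, beta={"x1": 1.0, "x2": -0.5},
                     field_sd=0.5, field_range=10.0)
lam, xi = ps.simulate_intensity(grid, covs, truth, seed=2)
pb = ps.simulate_pb_points(lam, None, seed=3)
sites = ps.sample_sites(grid, 200, seed=4)
pa = ps.simulate_pa_surveys(lam, sites, ps.sample_visit_counts(200, seed=5),
                            truth.e_vis, seed=6)

cfg = ps.IsdmConfig(covariates=("x1", "x2"), max_edge_km=5.0,
                    bias_field=False)
fit = ps.fit_isdm(covs, pa, pb, cfg)
print(fit.summary.round(3))
```

One such run (431 PB points; 43 detections in 302 visits at 200 PA sites)
prints:

```
           mean     sd   q2.5  q97.5
alpha_pa -1.911  0.265 -2.430 -1.392
alpha_pb -2.065  0.230 -2.516 -1.614
beta_x1   0.910  0.060  0.793  1.027
beta_x2  -0.514  0.057 -0.627 -0.401
```

Both coefficients cover the truth (1.0 and −0.5) within their 95%
intervals, and the fitted process field (σ ≈ 0.60, ρ ≈ 22 km) is of the
right order. Prediction and rescaling then give a 0–1 intensity map:

```python
mean, sd = ps.predict_intensity(fit, covs, ps.GridSpec(10, 10, 5.0))
mean01, sd01 = ps.rescale_unit(mean, sd)
```

Causal adjustment sets come straight from the packaged (editable) maximal
DAG; for urban area the confounder is human population, while woodland
connectivity can be adjusted either through total woodland area or through
its components:

```python
dag = ps.load_maximal_dag()
ps.minimal_adjustment_sets(dag, "Ur").sets   # ({'H'},)
ps.minimal_adjustment_sets(dag, "W_c").sets  # ({'W_a'}, {'A','Af','B_a','C_a','Df'})
```

`ps.estimate_driver_effect("Ur", dag, covs, pa, pb, cfg)` fits one model
per adjustment set and returns the focal coefficient's posterior summary.

A command-line interface mirrors the library
(`pestscape simulate / adjust-sets / sensitivity / fit / predict / effects /
select / residuals`), exchanging rasters as ESRI ASCII grids, tables as
CSV, DAGs as plain-text edge lists and settings as JSON.

## Layout

```
src/pestscape/
  grids.py       planar km grids, rasters, standardization
  covariates.py  connectivity, distance and area/edge layers
  causal.py      DAGs, d-separation, back-door adjustment sets
  fields.py      SPDE Matérn fields, PC priors, sampling
  synthetic.py   SCM covariates, intensity, PA/PB simulators
  isdm.py        the integrated model: likelihoods, fitting, prediction
  selection.py   WAIC search, Huber regression, residual maps
  cli.py         command-line interface
  data/          editable maximal-DAG text asset
docs/methods.md  model, priors, algorithms, limitations
```
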