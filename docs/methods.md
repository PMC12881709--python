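# Methods

This note documents the models, algorithms and numerical choices behind
`pestscape`, and what its synthetic studies do and do not demonstrate.

## The modelling problem

The package targets a common situation in landscape epidemiology: pest or
disease occurrence is recorded in two very different ways — structured
repeat-visit inspections that include non-detections (presence–absence, PA),
and opportunistic public reports with no effort information
(presence-background, PB). Neither stream alone supports reliable intensity
mapping: the PA data are sparse and clustered around inspected premises, the
PB data are dense but spatially biased toward where people look. An
integrated species distribution model (ISDM) fuses them through one shared
process model.

## Process model

Occurrence is a log-Gaussian Cox process over a planar km grid:

    log λ(s) = α + Σ_k β_k x_k(s) + ξ(s)

with z-standardized covariate rasters x_k, and ξ a zero-mean Matérn
(ν = 1) Gaussian random field with marginal sd σ and range ρ. The two
observation models are:

* **PA**: at site i with n_i visits, detections k_i ~ Binomial(n_i, p_i)
  with the complementary log–log link p_i = 1 − exp(−e_vis·λ(s_i)). The
  per-visit exposure e_vis (default 1.0, in cell-area units) sets the scale
  linking intensity to detection; it is a convention, not a calibrated
  value, because per-visit detection rates conditional on intensity are not
  identified separately from the PA intercept.
* **PB**: a thinned Poisson point process with log-intensity
  α_PB + Σβ_k x_k + ξ + b, where b is a second Matérn field absorbing
  spatially structured reporting effort. The Berman–Turner cell-centre rule
  (weights = cell areas, configurable refinement) discretizes the
  point-process integral.

Each stream has its own intercept (α_PA, α_PB): the streams' effort and
reporting scales are unknown and different, and a shared intercept would
force one to absorb the other's scale. Predictions anchor to the PB
intercept; since predicted maps are 0–1 rescaled, the multiplicative scale
this choice sets cancels exactly.

## Spatial fields

Fields use the SPDE representation: (κ² − Δ)x = W on a mesh, κ = √8/ρ,
giving sparse precision Q = τ²(κ²C + G)C⁻¹(κ²C + G) with lumped mass C,
stiffness G and τ² = 1/(4πκ²σ²). The default mesh is a regular node lattice
triangulated by splitting squares (piecewise-linear elements); the
"maximum edge" parameter is the lattice spacing, never allowed below a
1-km minimum so the field cannot be finer than the covariates. The mesh
extends 20 km beyond the data bounding box by default (twice the 10-km
prior range threshold) so SPDE boundary variance inflation stays outside
the modelled domain. On this discretization the implied marginal variance
is within ~10% of σ² at interior nodes and the correlation at separation ρ
is ≈ 0.13, matching the Matérn (ν = 1) curve within 0.05 over
[0.5ρ, 2ρ] (verified against dense covariance in the test suite).

Hyperparameters carry penalised-complexity priors: σ has the exponential
density with rate −ln(α_σ)/σ_0 and ρ the density (λ/ρ²)e^{−λ/ρ} with
λ = −ρ_0 ln(α_ρ). The defaults calibrate p(σ > 1) = 0.05 and
p(ρ < 10 km) = 0.05, concentrating prior mass on "no spatial structure" so
the fields activate only when the data demand it. The same thresholds apply
to the bias field by default but are configurable separately. Fixed effects
and intercepts have normal(0, precision 1) priors, which regularize the
exponential intensity scale.

## Inference

Empirical-Bayes Laplace approximation, in place of a full INLA-style
integration:

1. **Inner loop**: for fixed (σ, ρ) of both fields, a damped Newton
   iteration maximizes the joint log posterior over the latent Gaussian
   state (intercepts, β, field node values). The binomial-cloglog and
   Poisson likelihood terms are log-concave in the linear predictor, so
   Newton with step halving increases the objective monotonically (asserted
   per fit). Exponentials are clamped at e^±40 and probabilities computed
   with expm1/log1p forms.
2. **Outer loop**: Nelder–Mead on the log-scale hyperparameters maximizes
   the Laplace marginal likelihood plus PC-prior log-density (with the
   log-scale Jacobian), warm-starting each inner solve from the previous
   mode.
3. **Summaries**: the Gaussian approximation at the mode gives marginal
   sds and 95% intervals (mean ± 1.96 sd). These are Gaussian on the
   linear-predictor scale, slightly narrower than full marginal posteriors;
   the recovery tests budget for this.

Intensity prediction uses lognormal moments of the Gaussian η per cell
(mean = exp(μ + v/2), sd = mean·√(e^v − 1)), excluding the bias field —
b models observation, not ecology. Mean maps are rescaled to 0–1 and the
sd map divided by the same factor, so ranking and relative uncertainty are
unchanged.

## Causal driver analysis

The assumed data-generating process is a DAG over observed covariates,
latent introduction/establishment probabilities and the occurrence outcome.
The shipped maximal DAG (`data/maximal_dag_synthetic.txt`) is a plausible
reconstruction — the authoritative graph exists only as a published figure —
and is deliberately a plain-text config file, not code.

For a focal driver, all inclusion-minimal observed back-door adjustment
sets are computed by subset scan with d-separation checks in the graph with
the focal variable's outgoing edges removed; descendants of the focal
variable are excluded (total effects), latent nodes are never adjustable.
Because conditioning can open colliders, validity is not monotone in the
set, so the scan cannot early-exit on the full candidate set; supersets of
found minimal sets are skipped since they cannot be minimal. One model is
fitted per adjustment set ({focal} ∪ set as covariates); the focal
coefficient's posterior is the total-effect estimate on the
standardized-covariate log-intensity scale. A sensitivity analysis rebuilds
the adjustment sets along a nested DAG sequence from the focal-only graph
(unadjusted estimate) to the maximal DAG, adding observed variables in
topological order by default (reproducible; the original ordering is not
specified), and deduplicates the implied models.

## Covariate selection and residual analysis

WAIC is undefined for the point-process stream, so selection runs on
PA-only binomial spatial GLMs sharing the ISDM's field and priors.
Candidate sets sample 5–20 covariates uniformly without replacement, 50 per
size (800 total), with uniqueness enforced by bounded resampling. WAIC uses
S = 1000 posterior draws of the pointwise log-likelihood by default (the
draw count is a package choice); lppd uses log-mean-exp, p_waic the
sample variance with S − 1, and waic = −2(lppd − p_waic) holds exactly by
construction. Failed fits rank last with the error recorded, never dropped.

The residual analysis regresses 0–1 rescaled intensity on host-species
cover with a hand-rolled Huber IRLS (tuning constant 1.345, scale
MAD/0.6745 re-estimated per iteration, convergence on parameter change
< 1e-8); it agrees with the standard robust-regression implementations on
clean and contaminated data and is cross-checked against one in the tests.
Residual maps propagate missing cells from either input.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Covariates**: a linear-Gaussian structural causal model over a DAG —
  each node is Σ coef·parent + Matérn noise (default sd 1, range 5 km) —
  so every total causal effect equals a sum of path coefficient products,
  giving exact ground truth for the causal machinery.
* **Intensity**: log-linear in covariates plus a Matérn field draw.
* **PA surveys**: sites uniform over the domain; visit counts
  zero-truncated geometric with mean 1.5 (median 1, occasionally many
  visits, mimicking inspection data where most premises are visited once);
  detections binomial through the cloglog link.
* **PB points**: per-cell Poisson counts from exp(log λ + bias)·area with
  uniform within-cell placement (sub-cell position is irrelevant at the
  likelihood's cell resolution).

The default integrated study uses a 50×50 km grid, two independent
standardized covariates, β = (1.0, −0.5), α = −2.4 (≈ 500 expected PB
points), field σ = 0.5 and ρ = 10 km, and 200 PA sites. The
mesh-sensitivity comparison (5 vs 30 km maximum edge) runs on a 100×100 km
domain so the coarse mesh still places several nodes across the domain, a
sensible scale ratio for a check aimed at national-extent analyses.

What these simulations do **not** show: the generator's covariates are
stationary Gaussian fields without the skewness, zero-inflation and sharp
land-cover boundaries of real landscape layers; PA site placement is
uniform rather than administratively clustered; and there is no temporal
dimension. Passing recovery tests demonstrates the estimator is correct
under its own assumptions, not that real pest data satisfy them.

## Numerical and degenerate-input conventions

* Constant rasters raise a degenerate-layer error on standardization
  (population 1/n sd; layers are complete cell populations).
* Connectivity kernels are truncated at 3σ (9 km at the 3-km default, where
  99.7% of the 1-D profile weight lies) and normalized to sum 1; edge cells
  renormalize over in-domain support, so constant layers are invariant.
* σ = 0 disables a field exactly (no degenerate precision assembly).
* Sparse precision factorizations use symmetric-mode LDLᵀ via SuperLU;
  non-positive pivots raise a numerical error signalling a degenerate mesh.
* All simulators and fits are bit-reproducible under fixed seeds; the fit
  seed also governs WAIC posterior draws.

## Known limitations

* Hyperparameter uncertainty is not propagated (empirical Bayes): intervals
  condition on the optimized (σ, ρ).
* The Nelder–Mead outer search can stop at a local optimum for very weakly
  informative data; `hyper_maxiter` and the initial point are configurable.
* The regular-lattice mesh wastes nodes on empty corners of highly
  non-convex domains; a true triangular mesh backend would fit such domains
  with fewer nodes.
* Adjustment-set enumeration scans subsets of the observed candidate pool
  and is exponential in its size; it is comfortable for graphs of ~15
  observed nodes but not for hundreds.
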