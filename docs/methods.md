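# Methods

This note records the statistical models, algorithms and design choices
behind `slopesim`, at the level of detail a maintainer or reviewer needs to
judge what the package computes and what its simulations do and do not show.

## 1. Models

### 1.1 Random slopes (conditional form)

The planning/analysis model for a trial with visits `t_0 = 0 < t_1 < ... <
t_K` (years) is

    y_ij = β0 + β1 t_j + γ z_i t_j + u_0i + u_1i t_j + e_ij,

with `(u_0i, u_1i)` bivariate normal, zero mean, covariance
`G = [[σ²_u0, σ_u01], [σ_u01, σ²_u1]]`, and `e_ij ~ N(0, σ²_e)` i.i.d.
The shared intercept `β0` exploits randomisation (equal means at baseline)
and is what makes `γ · t_K` equal to the final-visit difference in group
means. The observational (design-stage) model drops the `γ` term.

Marginally, a subject's visit vector is multivariate normal with covariance

    Σ_jk = σ²_u0 + t_j t_k σ²_u1 + (t_j + t_k) σ_u01 + 1{j=k} σ²_e.      (RS covariance)

### 1.2 Marginal models with unstructured covariance

Three relaxations share one free symmetric positive-definite Σ (n_visits ×
n_visits) across arms and differ only in the mean:

* **LTFC** (linear trajectories, free covariance): mean as in the
  random-slopes model.
* **FCTFC** (free control trajectory, free covariance): per-visit control
  means `β_j`, effect still `γ z_i t_j`.
* **FTFC** (free trajectories, free covariance): per-visit means `β_j` and
  per-visit effects `γ_j z_i` with `γ_0 ≡ 0` (not estimated).

All are summarised on the same estimand: the treated-minus-control mean at
the final visit (`γ·t_K` for slope-parameterised models, `γ_K` for FTFC).

## 2. Fitting algorithms

### 2.1 Balanced-data sufficient statistics

Every dataset the package produces is complete and balanced, so subjects in
one arm share a design matrix and covariance pattern. All likelihood work
reduces to per-arm statistics `(N_a, Σ_i y_i, Σ_i y_i y_iᵀ)`: one visit-level
Cholesky per likelihood evaluation, cost independent of the number of
subjects. A brute-force implementation that assembles the full
`(N·n_visits)²` joint covariance is kept in the test suite as an oracle; the
two agree to ~1e-13.

### 2.2 REML for the random-slopes model

The restricted log-likelihood (fixed effects profiled by GLS, including the
`log|XᵀV⁻¹X|` adjustment and all Gaussian constants) is maximised over an
unconstrained parameterisation:

    θ = (log σ²_u0, log σ²_u1, arctanh-scaled ρ, log σ²_e),  ρ = 0.999·tanh(·)

so the correlation boundary becomes a finite interior point; a fit with
|ρ̂| > 0.99 is flagged `boundary` (common, and expected, when strongly
non-linear trajectories are forced through a linear random-effects
structure). Log-variances are box-bounded at ±15 (≈ 3e−7 to 3e6 on an
outcome² scale) — far beyond plausible values while keeping Σ numerically
sane — and likelihood evaluations reject covariances whose Cholesky
condition proxy exceeds 1e8, because ill-conditioned solves can masquerade
as huge likelihoods.

The optimiser ladder (worked through until one rung converges):

1. L-BFGS-B from method-of-moments starts (per-subject OLS lines on
   arm-centred outcomes; their coefficient covariance minus the OLS noise
   contribution starts G, pooled within-subject residuals start σ²_e);
2. Nelder–Mead restarted from the rung-1 endpoint;
3. L-BFGS-B from a diagonal-G start (σ_u01 = 0).

The accepted point is then polished by a short simplex descent: the
quasi-Newton rungs use finite-difference gradients whose noise caps their
final precision, and the polish recovers the last decimals (the suite
checks the optimum against independent brute-force optimisation to 1e-6).
Non-convergence is reported on the fit object, never raised.

Fixed effects and their covariance come from GLS at the optimum,
`(XᵀΣ̂⁻¹X)⁻¹`. Estimates cannot leave the valid variance-component region by
construction.

### 2.3 Iterated GLS for the marginal models

Gaussian maximum likelihood by alternating the GLS solve for the fixed
effects with the covariance update Σ̂ = (1/N)·Σ_i r_i r_iᵀ (residual outer
products), to a fixed point (relative log-likelihood change < 1e-10, budget
200 iterations — in practice a handful). ML rather than REML is used for Σ̂
(divisor N): the fixed-effect estimates, which are the quantities compared
across models, are identical under either, and the simulations confirm the
model-based SEs track the empirical SEs within Monte-Carlo error at the
trial sizes involved. A by-product worth knowing: at their respective ML
fixed points LTFC and FCTFC give *identical* γ̂ (the extra lack-of-fit
direction in the LTFC covariance is GLS-orthogonal to the effect column),
which the suite asserts to 1e-8.

### 2.4 Tests and degrees of freedom

All models are tested by a two-sided Wald t-test on the final-visit effect.
The small-sample policy is: Satterthwaite-style df for the random-slopes
model — `df = 2V²/Var(V̂)` with `V = Var(γ̂)` as a function of the variance
components, its gradient and the observed REML information both by central
finite differences (parameterisation-invariant); and between-subject
residual df (N − 2) for the marginal models. An exact Kenward–Roger
correction is deliberately not implemented: at the trial sizes this package
is designed around (hundreds of subjects), the difference between these df
policies and KR is far below Monte-Carlo resolution, which the calibration
scenarios confirm. The Satterthwaite computation falls back to N − 2 when
the information matrix is unusable (e.g. exactly on the correlation
boundary, where the saturated direction carries no information).

## 3. Sample-size machinery

`V(γ̂)` for a hypothetical 2-person trial is the (3,3) element of
`(XᵀΣ⁻¹X)⁻¹` with X stacking one control and one treated subject over the
schedule and Σ block-diagonal from the RS covariance; an N-person 1:1 trial
has `V/(N/2)`, and

    N = 2 · ceil( (z_{1−α/2} + z_{1−β})² · V(γ̂) / d² ),

with normal (not t) quantiles, exactly as the standard formula prints; the
2×ceil structure is the only rounding and keeps N even. The "2 n_t" in the
usual description of the stacked covariance is read as 2·(number of visits
including baseline). At the returned N the analytic normal-approximation
power is ≥ the target, and N − 2 falls short unless the ceiling was exact.

**Pseudo-true effects.** When the true group means `μ_c, μ_t` are not of
the proportional form, the large-sample limit of γ̂ is the GLS projection
`[(XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹ μ]₃` — a covariance-weighted linear combination of the
per-visit mean differences. The Σ to use is the one the misspecified fit
converges to; `projection_vc` approximates this KL-projection covariance by
fitting the observational model to one large simulated untreated cohort
(default 50 000 subjects) under the target generator, and callers may
substitute any components. This reproduces the simulated mean slope of the
misspecified scenarios to Monte-Carlo precision (e.g. −0.080/yr for
early-decline trajectories analysed over 3 years when the design assumed
−0.05/yr).

## 4. The synthetic-cohort generator

The generator *is* the study condition set, not a tuning surface:

* control-arm mean `6 + 0.2·f(t)` with the four shapes given in the README;
  all calibrated to 6.00 at baseline and 7.00 at five years (2 dp);
* components `σ²_u0 = 0.5`, `σ²_u1 = 0.01`, `σ_u01 = 0.5·√(σ²_u0 σ²_u1)`
  (correlation 0.5), residual `σ²_e ∈ {0.15, 2}`;
* treatment effects calibrated to a −0.25 group-mean difference at five
  years in every σ²_e = 0.15 scenario (γ = −0.05/yr, delay 1.25 y) and
  −0.5 when σ²_e = 2 (γ = −0.1/yr, delay 2.5 y);
* non-linearity enters only the fixed part — the random-effect contribution
  `u_1i t_j` stays linear — so all shapes share one covariance structure;
* observational studies have 1000 subjects, annual visits over five years;
  trials randomise 1:1 with *exact* balance (first N/2 control, ids then
  shuffled under the seed), matching the equal-allocation variance formula;
* no missing data, Gaussian errors throughout, real-valued visit times
  accepted (for e.g. six-monthly schedules).

What this does **not** emulate about real cohorts: dropout and intermittent
missingness, non-Gaussian or heteroscedastic errors, measurement floors/
ceilings, unequal allocation, site effects, and subject-specific timing of
non-linear decline (a variant with a person-level time shift of the
intermediate decay is out of scope). Passing simulations therefore
demonstrate properties of the estimators under clean, balanced, Gaussian
conditions — the regime the sample-size formula itself assumes — not
robustness to those real-data features.

## 5. The Monte-Carlo harness

Each replicate: simulate an observational study → fit the observational RS
model (optimiser ladder) → compute N from the estimates and the trial
schedule → simulate the trial under the scenario's effect → fit each
requested model and extract the final-visit estimand. Scenario summaries
report convergence %, boundary %, rejection rate with its MC SE
`100·√(p(1−p)/reps)`, mean effect, empirical SE (SD of effects), mean
model-based SE (root-mean of variances) and the percentage SE bias.

Seeding: all streams derive from `numpy` `SeedSequence`s keyed on the
scenario base seed plus structural indices. Observational-stage streams are
keyed on (shape, σ²_e, replicate) only, so every treatment-effect option
within a family sees the identical sequence of observational studies and
hence of sample sizes — the standard computational shortcut for comparing
effect shapes on common designs. Replicates are independent given their
child seeds and bit-reproducible individually; execution order is
irrelevant.

Exclusions: replicates whose observational fit fails are unusable; metrics
are computed only over replicates where *every* requested model converged,
and the exclusion counts are always reported. The optional
`exclude_obs_boundary` filter drops whole replicates whose observational
correlation estimate exceeds 0.99 in magnitude (the sensitivity analysis an
analyst would run after noticing a boundary fit); it never alters surviving
estimates.

The factorial grid crosses 4 shapes × {none, proportional,
non-proportional} × {5-year, 3-year trial} × σ²_e ∈ {0.15, 2}; FCTFC is
carried only in the scenario used to establish its equivalence with LTFC,
which is where it adds information.

**Problem sizes.** The package's default reproduction scale is 200–500
replicates per scenario (the tests use 300; `scripts/acceptance.py` uses
the counts printed next to each value). At 500 replicates a rejection rate
carries an MC SE of ~1.8 points near 80% and ~1.0 near 5%, so conclusions
are stated against 3-MC-SE bands. Full-scale grids (thousands of replicates
per scenario) are a matter of `n_reps` and patience; one replicate costs a
few tens of milliseconds thanks to the sufficient-statistic likelihoods.

## 6. Numerical and design choices

* **Convergence declarations.** L-BFGS-B rungs: optimiser success or small
  projected gradient; simplex rungs: scipy's xatol/fatol criteria
  (1e-8/1e-10). Iterated GLS: relative log-likelihood change < 1e-10.
* **Degenerate inputs.** Zero-variance components are allowed in the
  generator (noise-free fixtures lie exactly on their mean curves); the
  fitting engines require data with positive residual variance. Fewer than
  two distinct visit times makes the slope inestimable and is rejected at
  schedule construction.
* **Ties and identifiability.** FTFC needs ≥ 2 visits; with exactly 2 it
  reduces to baseline-adjusted GLS (asserted in closed form in the tests).
* **df fallbacks.** Satterthwaite df is clipped to [3, 1e7] and falls back
  to N − 2 on numerical failure; with hundreds of subjects the choice is
  immaterial, and no claim is made about small-N behaviour.
* **Reports.** `write_report` emits one CSV row per scenario × model with
  the documented column schema; plotting is left to the caller (the
  examples print, rather than draw, their summaries).

## 7. Known limitations

* Exact Kenward–Roger df/covariance corrections are not implemented (see
  §2.4); results at N below ~50 subjects should not be taken at face value.
* Sample-size formulas are provided for the random-slopes estimand only;
  powering a trial for the FTFC estimand directly is out of scope.
* The likelihoods assume complete balanced data; there are no
  missing-data (unbalanced) likelihood paths.
* Correlation estimates are constrained to (−1, 1); software that permits
  out-of-boundary estimates will disagree on the (pathological) boundary
  datasets, though not materially on aggregate metrics.
* The boundary sensitivity filter drops whole replicates based on the
  observational fit; finer-grained variants (e.g. refitting with a
  different covariance) are not provided.
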