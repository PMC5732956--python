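# Methods

## The problem

Standardized tests register ability only within a bounded score range. When a
sample sits mostly near the bottom of that range — common when tests normed on
one population are administered to another — scores pile up at the lowest
attainable value. Such a *floor effect* is conventionally flagged when 15% or
more of a sample scores at the lowest level of the measure. Analysing floored
scores as if they were ordinary observations attenuates regression slopes and
understates uncertainty; the attenuation grows with the fraction of floored
observations.

`mltobit` treats the floored outcome as *left-censored*: the latent score
y\*_ij exists below the floor l but is recorded as l whenever y\*_ij ≤ l
(ties at the threshold count as censored; the comparison is an exact ≤ with
no tolerance). Right-censoring (a ceiling) is supported symmetrically.

## Models

All estimators share the two-level random-intercept regression

    y*_ij = β0_j + γ10 x1_ij + e_ij,      e_ij ~ N(0, σ²)
    β0_j  = γ00 + γ01 x2_j + u_j,          u_j ~ N(0, φ)

with i indexing units inside cluster j. Slopes are fixed (no random slopes);
random effects are Gaussian; the model is two-level only.

**Naive ML** (`MultilevelRegression`). Ignores censoring. The random
intercept integrates out analytically: each cluster's outcome vector is
multivariate normal with compound-symmetric covariance σ²I + φJ, whose
determinant and inverse have closed forms. Fixed effects are profiled out by
GLS and the two variance components are optimised on the log scale
(L-BFGS-B), which enforces positivity; φ may reach an effective boundary of
exp(−30). Model-based standard errors come from the inverse observed
information, which is analytic on the natural (β, φ, σ²) scale.

**Cluster-robust SEs** (`robust_se`, `se="cluster_robust"`). The same point
estimates with sandwich covariance A⁻¹BA⁻¹, where A is the observed
information and B the sum of per-cluster score outer products, both analytic
and evaluated at the ML solution, times a small-sample factor G/(G−1)
(toggleable; the factor used by commercial MLR implementations is not
public). This is the analogue of the "robust maximum likelihood" (MLR)
standard-error correction: it repairs standard errors for non-normality and
within-cluster dependence but cannot repair the attenuated point estimates.

**Multilevel Tobit** (`MultilevelTobit`). Full ML for the censored outcome.
Conditional on u_j, uncensored rows contribute normal densities and floored
rows contribute Φ((l − μ_ij − u_j)/σ); the integral over u_j is evaluated by
*adaptive* Gauss–Hermite quadrature: a vectorised Newton iteration finds each
cluster's posterior mode of u (the log-integrand is strictly concave, so this
is globally convergent), the rule is recentred there and rescaled by the
curvature, and 21 nodes are used by default. Adaptivity matters because with
heavy censoring the integrand can sit far from the prior mode; at 21 nodes,
doubling the node count changes the log-likelihood by less than 1e−8 on
10-cluster fixtures. The optimiser (L-BFGS-B, numerical gradients) starts at
the naive solution with σ² inflated by 1/(1 − p_censored) — censoring
attenuates the residual variance, so the de-attenuated start shortens the
search. Standard errors come from a central-difference observed-information
Hessian on the internal (β, log φ, log σ²) scale, delta-methoded back to the
natural scale.

**Degenerate designs.** Without within-cluster replication (every cluster of
size 1) φ and σ² are identified only through their sum; φ is then pinned at
zero, naive ML reduces to its OLS closed form, and the φ row of any
covariance matrix is reported as NaN. The same rule applies whenever φ̂ ends
at its boundary. With all clusters of size 1 the cluster sandwich equals the
single-level HC0 heteroscedasticity-consistent sandwich exactly.

**Inference.** Two-tailed Wald z-tests at α = 0.05 on each fixed effect,
standard-normal reference.

## Synthetic data

`generate_two_level` draws from the model above with x1 ~ N(0,1) per unit and
x2 ~ N(0,1) per cluster. Defaults are the study conditions: γ = (1, 0.75,
0.5), φ = 0.5, σ² = 1, 100 clusters of 10 (n = 1,000). The latent outcome is
then marginally normal with mean 1 and variance 0.75² + 0.5² + 0.5 + 1 =
2.3125 (SD ≈ 1.521). `apply_floor` censors at a threshold;
`threshold_for_proportion` inverts the marginal normal CDF to place a floor
at any target censoring fraction. The six standard conditions floor 0, 5,
10, 15, 20 and ~26% of outcomes at thresholds (none, −1.50, −0.95, −0.60,
−0.25, 0.03). The last two thresholds are kept at these tabulated values
rather than the analytic quantiles (−0.28, −0.03) so the conditions match
the established benchmark exactly; the 0.03 threshold actually censors
≈26.2% of rows.

One caveat on the variance components: the two values {1, 0.5} are assigned
as σ² = 1 (within) and φ = 0.5 (between). This assignment — not its
transpose — makes the marginal SD √2.3125 consistent with the tabulated
threshold/proportion pairs (P(Y ≤ −1.50) ≈ 5%, P(Y ≤ −0.95) ≈ 10%).

`generate_study_like` emulates a classroom-randomised vocabulary-intervention
trial: 42 classrooms × 6 children (252 children, matching the scale of the
motivating study), eight child-level covariates (pretest, age, gender,
bilingual status, ethnicity, attendance, two language-proficiency scores)
and seven classroom-level covariates (district, a balanced randomised
intervention indicator, teacher language, experience and training measures).
Outcomes are in z-score units with effect sizes small-to-moderate (pretest
0.5, intervention 0.3 by default, others ≤ 0.2 in magnitude), φ = 0.2,
σ² = 0.8 — an intraclass correlation of 0.2/(0.2+0.8+…) ≈ 0.15, typical of
classroom data. Binary covariates are centred so the intercept remains the
marginal mean; the floor is placed at the analytic quantile for the requested
floor fraction (the marginal distribution is only approximately normal with
binary covariates, so the realised fraction deviates by a point or two).

What the generators deliberately do **not** emulate: the discreteness and
norming (mean 100, SD 15) of real standard scores, item-level responses,
missing data, non-normal latent ability, unequal cluster sizes, or selection
into the sample. Passing tests therefore show the estimators behave correctly
when the censored-Gaussian model holds — they do not validate the model
against real vocabulary-score data.

## Monte Carlo design and estimands

`run_condition`/`run_study` cross the six floor conditions with the three
methods. Seeding: one master seed spawns per-replication `SeedSequence`
children, so results are bitwise-reproducible and independent of `n_jobs`.
Failed or non-converged fits are excluded from summaries and counted (a
warning fires above 10% per condition; in practice non-convergence is rare).

Per condition × method × parameter, `summarize_study` reports:

* **relative bias** (θ̄ − θ)/θ of the mean point estimate (undefined where
  θ = 0; absolute bias is also reported);
* **relative SE bias** (SE̅ − σ̂_MC)/σ̂_MC, where σ̂_MC is the Monte-Carlo SD
  of that method's own point estimates in that condition;
* 95% CI **coverage** and the Wald **rejection rate** (power off the null,
  type I error under it).

The reference value in the SE-bias ratio deserves care. Using each method's
*own* Monte-Carlo SD answers "does the method estimate its own sampling
variability correctly?" — by that yardstick even the naive estimator is only
mildly off (≈ −0.10 at the heaviest floor), because its reported SEs shrink
roughly in step with its attenuated estimates. The benchmark results this
package reproduces instead measure reported SEs against the *population*
dispersion — the sampling SD of the correctly specified (censored-likelihood)
estimator. `population_se` computes it from the expected information of the
correct model at the true parameters, approximated by the observed
information on one large simulated design (10,000 clusters by default,
rescaled to the target cluster count). Against that reference the naive SEs
are ≈27% too small at the heaviest floor, the robust correction recovers
about a third of the gap, and the Tobit SEs are within a few percent.
Both definitions are exposed; the summaries carry the own-SD version and
`population_se` provides the reference for the population version.

## Numerical choices

* Quadrature: 21 adaptive Gauss–Hermite nodes; mode-finding Newton tolerance
  1e−11 with step clipping at 5·√(φ+σ²).
* Optimisers: L-BFGS-B, `ftol` ≈ 1e−12/1e−13, `gtol` 1e−7/1e−8; variance
  parameters bounded in log space to [−30, 10].
* Numerical Hessians: central differences with relative step 1e−4.
* Censoring ties: y ≤ l is censored, exactly.
* Rounding: report layers round to 2 decimals; all stored summaries keep
  full precision.

## Problem sizes used in the shipped tests

The acceptance suite regenerates the full design at 500 replications per
method and condition, with the population-SE reference computed once per
condition; the type-I-error check on study-shaped data uses 200
replications. These sizes leave the Monte-Carlo error comfortably inside the
asserted tolerances (e.g., the MC SE of a 500-rep bias estimate for γ10 is
≈0.002, and ≈0.007 for γ01).

## Known limitations

* Random intercepts only; no random slopes or three-level nesting.
* Gaussian latent outcome and random effects; no heavy-tailed or skewed
  latent alternatives.
* The sandwich small-sample factor G/(G−1) is one common convention among
  several; with few clusters the robust SEs remain anti-conservative.
* Wald z-tests on cluster-level coefficients are anti-conservative when the
  number of clusters is small relative to the number of cluster-level
  parameters: on the default study-shaped design (42 classrooms, 7
  classroom-level covariates) ML slightly underestimates the SE of the
  intervention coefficient for *every* estimator — a small-G effect, not a
  censoring issue — and the nominal 5% z-test rejects several points above
  5% under the null (the type-I-error acceptance test measures this
  directly). Trials of this size should pair the estimates with a t
  reference or a small-sample SE correction.
* Variance-component SEs are delta-method approximations and unreliable near
  the φ = 0 boundary (reported NaN exactly at it).
* The quadrature cost grows linearly in nodes × rows; designs with very
  large clusters and heavy censoring may need more nodes for tail accuracy.
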