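# Methods

## The statistical problem

The package analyses individual-level household-survey records of women of
reproductive age, with a binary outcome — whether the preceding birth
interval was 24 months or shorter — observed together with the province of
residence, age in completed years, and categorical risk factors (urban/rural
residence, household wealth, education, contraception, breastfeeding
practice). Two questions drive the design: which individual factors shift
the odds of a short interval, and how much province-level variation remains
after adjusting for them — i.e. where the residual geographic excess risk
sits. Both the full population (15–49) and the young subset (15–24) are
analysed, since fertility behaviour and covariate mixes differ sharply
between them.

## Model

The structured additive predictor for woman $i$ is

    logit P(y_i = 1) = x_i' beta + f(a_i) + s_{r(i)} + u_{r(i)}

with four ingredients:

* **Fixed effects** `beta`: dummy coding against declared reference
  categories (urban, high wealth, secondary+ education, modern
  contraception, mixed feeding; Kinshasa for the classical province
  contrasts). Prior N(0, c) with c = 1e6 — effectively flat at the scale of
  log odds ratios.
* **Age smooth** `f`: cubic B-splines, default 20 basis functions on the
  observed age range, second-order random-walk (RW2) penalty
  `K = D2'D2`, prior `gamma ~ N(0, tau_f^2 K^-)`. K has rank m−2; the
  constant is removed by centering (below) and the unpenalized linear trend
  is identified because no separate linear age term enters the model. The
  published-style tabular (classical) analysis instead uses derived 5-year
  age bands with the oldest band as reference.
* **Structured spatial effect** `s`: intrinsic CAR (ICAR/MRF) prior with
  precision `Q/tau_s^2`, `Q = D − A` the Laplacian of the province
  adjacency graph. The quadratic form `s'Qs` is the sum of squared
  differences across edges, so the prior only penalises disagreement
  between neighbours. A connected graph is required (rank n−1); draws and
  posteriors are constrained to sum to zero.
* **Unstructured effect** `u` (optional, on by default): exchangeable
  N(0, sigma_u^2) province effects. Reported maps summarise the *total*
  residual spatial effect s + u; both components are stored separately.

Variance hyperpriors are IG(0.001, 0.001) — a conventional diffuse choice
for this model family — surfaced in `ModelSpec`.

## Sampler

Inference uses Pólya-Gamma data augmentation: `omega_i ~ PG(1, eta_i)`
renders the logistic likelihood Gaussian in all coefficients, so one Gibbs
scan is (1) PG draws per observation, (2) a single joint Gaussian draw of
the stacked coefficient vector from N(Lambda^-1 Z'(y−1/2), Lambda^-1) with
`Lambda = Z' diag(omega) Z + blockdiag(priors)`, (3) recentering, (4)
conjugate inverse-gamma variance updates with shapes a + rank(K)/2,
a + (n_prov − 1)/2 and a + n_prov/2. The PG(1, z) draws use Devroye's exact
alternating-series rejection sampler (numba-compiled; validated against the
moment identity E[PG(1,z)] = tanh(z/2)/(2z) and a sign-symmetry KS test).
The update kernel itself is validated by successive-conditional (prior
reproduction) simulation on a proper-prior configuration, and by agreement
with maximum likelihood when the smooth and spatial terms are switched off.

Numerical choices:

* The intrinsic priors leave exact flat directions (a constant can move
  freely between the intercept, the spline coefficients and s, since rows
  of the spline basis and of the province indicator matrix both sum to
  one). A diffuse ridge — precision 1/c on *every* coefficient — makes
  Lambda positive definite; the per-iteration recentering (s demeaned, the
  smooth's fitted values demeaned over the observed ages, both constants
  absorbed into the intercept) then pins the level allocation. The ridge
  corresponds to an extra N(0, 1e6) factor per coefficient and is
  statistically negligible.
* PG draws are floored at 1e-12; inverse-gamma scales at 1e-300.
* One SeedSequence per run spawns independent per-chain streams; the PG
  sampler takes an explicit integer sub-seed per iteration, so runs are
  reproducible draw-for-draw.
* Default chain settings: 12000 iterations, 2000 burn-in, thin 10, two
  chains — a paper-scale fit (n ≈ 7200, ~52 coefficients) runs in roughly
  two to three minutes on one CPU. Convergence is monitored with split-R̂
  per coefficient and Geyer initial-positive-sequence effective sample
  sizes.

## Reporting conventions

* Point estimate on the OR scale: exp(posterior mean of the log-odds
  effect); the posterior mean of exp is emitted alongside for transparency.
* Credible regions are equal-tailed (type-7 empirical quantiles), reported
  at 80% and 95%.
* Map classification: +1 / −1 when the CR at the requested nominal level
  (default 80%) excludes zero on the log-odds scale, else 0. Because CR80
  is nested in CR95, significance at 95% implies significance at 80%. The
  per-province posterior probability of a positive effect is also emitted;
  the CR-exclusion rule, not a tail-probability threshold, is the
  implemented definition.

## Synthetic data: what it emulates, what it does not

The generator draws records from the exact model above with fully known
truth, and `default_survey_config()` fixes the study conditions the package
is validated under: n = 7172 women; province shares and covariate mixes
chosen to be realistic for the surveyed population (the published tables
report outcome percentages per level, not level frequencies, so the joint
covariate structure is a declared modelling choice — covariates independent
given province, with an optional province-specific hook); an age
distribution placing ~20% of women at 15–24; a marginal prevalence
calibrated to 30.2% exactly, by bisecting the intercept against the
enumerated outcome probability (covariates are independent given province,
so the linear predictor's discrete distribution convolves in closed form);
a rural
log-OR of log 1.5 plus modest wealth/education/behaviour effects; a
monotone linear-decreasing age effect spanning 1.0 log-odds between ages 15
and 45 (which reproduces the observed ~8-point prevalence excess among the
young subset); and a fixed spatial vector of SD ≈ 0.31, positive (+0.4 to
+0.45) in Nord-Kivu, Sud-Kivu and Kasaï-Occidental, negative around the
capital, zero in Orientale.

What passing the recovery experiments does **not** show about real survey
data: the generator draws women independently, so it carries no multistage
cluster sampling, no design weights, no household correlation, no
informative missingness (records are complete by construction; the
completeness filter is exercised by masking in tests), and no
covariate-covariate dependence beyond province. Estimates on a real DHS
extract would additionally need design-based variance corrections that are
deliberately out of scope here.

## Adjacency is configuration

All spatial results are a function of the supplied edge list. The packaged
default is a pre-2015 11-province DRC contiguity list (20 edges); users
with authoritative boundary files should derive their own edge list and
pass it via `load_graph`. Disconnected graphs are rejected rather than
patched, because the sum-to-zero constraint is ambiguous across components.

## Classical stage choices

* IRLS (Newton) logistic fits with Wald intervals — matching the symmetric
  intervals of standard survey reports; profile likelihood is not used.
* Separation is detected (diverging coefficients or vanishing deviance)
  and raised, not silently truncated.
* The adjusted-model term lists are explicit configuration, defaulting to
  the factors that screen significant univariately in this setting:
  province, residence, education, age band and contraception for the full
  population; province, wealth and age band for the young subset.
* Univariate screen threshold: p < 0.05 two-sided. Chi-square tests use
  the Pearson statistic; Mann–Whitney uses midranks, tie-corrected
  variance and a continuity-corrected normal approximation (within 0.01 of
  exact enumeration by n, m ≈ 8, moderate p).

## Known limitations

* The map-table classification is a pointwise rule per province; no
  multiplicity adjustment across the 11 provinces is applied (matching the
  reporting convention it reproduces).
* The PG sampler updates all coefficients in one joint block; for models
  vastly larger than this package's target (hundreds of regions, several
  smooths) per-term blocking or sparse factorizations would be preferable.
* The young-population smooth spans only 10 ages; its default basis is
  reduced to 10 functions, and inference near the boundary ages is
  band-widened as usual for P-splines.
* Survey weights, cluster-robust variances and DHS recode-file ingestion
  are out of scope by design.

## Problem sizes used in the shipped validation

The recovery experiment refits the full model on 5 independently simulated
surveys of n = 7172 at the default chain settings; the sampler-limit and
prior-reproduction checks use n = 5000 and n = 40 respectively; oracle
comparisons (closed-form 2×2 odds ratios, exact Mann–Whitney enumeration,
pseudo-inverse ICAR covariance) run at sizes where the oracle is exact and
fast. The acceptance script performs one full simulate-and-refit cycle at
n = 7172.
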