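# Methods

## Generative model

A phase-I cohort of N subjects is followed to an administrative horizon τ.
Covariates are binary:

* confounder `x_conf ~ Bernoulli(p_conf)`, default p_conf = 0.5;
* risk factor `x_risk ~ Bernoulli(p_risk)`, default p_risk = 0.4;
* biomarker `P(x_bm = 1 | x_conf) = expit(a + b·x_conf)`, default a = −2,
  b = 1.7, giving a marginal prevalence of 27.2% ("common" biomarker); the
  rare-biomarker setting a = −4, b = 1.5 gives 4.7%;
* surrogate `P(x_surr = 1 | x_bm) = expit(c + d·x_bm)`; c and d are
  parameterized so that specificity = P(x_surr = 0 | x_bm = 0) and
  sensitivity = P(x_surr = 1 | x_bm = 1) are 0.7/0.7 by default
  (c = logit(0.3), d = logit(0.7) − logit(0.3)).

The event time follows a Weibull proportional-hazards model with shape
p = 0.9 and scale λ = 0.1: survival S(t | X) = exp(−λ t^p e^{β'X}), simulated
by inversion, `T = (−log U / (λ e^{β'X}))^{1/p}` with U ~ Uniform(0, 1).
The linear predictor includes biomarker, confounder and risk factor. Random
censoring is exponential with rate ρ ∈ {0, 0.1, 0.4} and is truncated at
τ = 2, so the stored censoring time is C = min(C_exp, τ) and the observed
data are Z = min(T, C), Δ = I(T < C). "Censored" in reported yields counts
only random censoring before min(T, τ); administrative censoring at τ is
always present. At ρ = 0.1 and 0.4 the random-censoring yields are ≈ 16% and
≈ 49% of subjects.

### Coefficient defaults and calibration

The biomarker effect defaults to β_BM = log 1.5, the moderate effect size
the benchmark scenarios target. The nuisance coefficients β_Conf and β_Risk
are not separately identified by any published value we reproduce, so the
default scenario calibrates them (equal to each other) so that the *expected*
number of events per cohort of N = 2000 at ρ = 0 is exactly 500, i.e. an
event fraction of 0.25. The calibration solves the closed-form 8-cell
expectation `Σ_cells P(cell)·(1 − exp(−λ τ^p e^η))` with `scipy.brentq`,
giving β_Conf = β_Risk ≈ 0.318 (hazard ratio ≈ 1.374). With ρ > 0 the
expected event fraction uses numerical integration of the Weibull density
against the exponential censoring survival. All coefficients can be
overridden per scenario.

### Replication count

The number of simulation replications for a target accuracy δ of the mean
coefficient estimate is Burton's `B = ceil((z_{1−α/2} √Var(β̂) / δ)²`;
with δ = 0.0046, Var = 0.011, α = 0.05 this gives 1997, conventionally
reported as 2000 at two significant figures. The package's own acceptance
battery uses B = 500 (Monte-Carlo SE on a power of ~70% is ≈ 2 points),
which keeps a full 12-design comparison under a minute on one CPU.

## Phase-II designs

Strata are the event indicator crossed with any subset of the phase-I
binaries. Sampling is always at end of follow-up: cases are subjects with
the event during follow-up, controls are event-free at τ.

* **SRS** — without replacement, π = n/N.
* **PPS** — proportional allocation n_h = N_h·n/N, integerized by
  largest-remainder apportionment (ties broken by stratum label order), SRS
  within stratum, π_h = n_h/N_h.
* **CC** — fixed total n, n/2 cases and n/2 controls; with extra strata each
  half is split *equally* across its substrata (balanced design). A cell
  smaller than its planned share is taken whole and the shortfall is
  redistributed equally among the unsaturated cells of the same half,
  iterating; a half that cannot fill its quota (e.g. fewer than n/2 cases)
  passes the shortfall to the other half, so the total n is always realized
  when n ≤ N. π is the empirical realized fraction per stratum.
* **NCC** — cases are all kept if n ≥ 2·ΣΔ, otherwise a simple random n/2 of
  them (case π = (n/2)/ΣΔ); each sampled case draws m controls without
  replacement from its risk set {j ≠ i : Z_j ≥ t_i}. Risk sets include
  subjects who later become cases. Duplicated selections collapse, so the
  realized size is at most (1 + m)·ΣΔ and typically falls short of the
  planned n (≈ 550 of 600 in the reference scenario with m = 1).
* **CM** — as NCC but controls come from the risk set of the *opposite*
  stratum of a binary surrogate, maximizing biomarker discordance within
  matched sets. An empty opposite risk set falls back to the case's own
  stratum and the sample is flagged; such draws are not represented in the
  inclusion-probability model, so flagged scenarios should be interpreted
  with care (they do not occur in the benchmark scenarios).

When cases are subsampled, controls are drawn only at sampled cases' event
times, keeping the planned 1:m ratio.

## Inclusion probabilities and weights

Stratified designs use empirical probabilities π̂_h = realized_h/N_h; the
weighted stratum counts then reproduce phase I exactly. NCC non-cases get
Samuelsen's product `π_j = 1 − ∏_{sampled cases, t_i ≤ Z_j} (1 − m/(R(t_i) − 1))`
with R(t) the overall number at risk; CM non-cases in stratum s use the
opposite-stratum analogue with R_s(t) and no −1 (the index case is not in
the control's stratum). Factors are floored at zero when a risk set is
smaller than m. Cases carry the case-sampling probability. Subjects the
design can never select (π = 0, e.g. sharing a stratum with every case under
CM) are excluded from fits with a logged count — infinite weights are
undefined. Probabilities are computed (and exported) for *all* subjects,
selected or not, which is what the Monte-Carlo oracle tests compare against
20,000 repeated draws.

Post-stratification rescales existing weights within each post-stratum
(event × surrogate by default) so weighted counts match phase-I counts; the
post-strata then serve as variance strata.

## Weighted Cox estimation and variance

The weighted Breslow partial likelihood is maximized by Newton–Raphson with
step-halving; convergence when max |score| < 1e−9 or the relative
log-likelihood change is < 1e−9, at most 50 iterations. Breslow tie handling
is used throughout so that integer weights are exactly equivalent to row
duplication (simulated times are continuous; ties have probability zero and
are broken by stable subject order). Monotone likelihoods (|β̂| > 30) and
singular information matrices are flagged on the result, not raised.

Variance is a two-phase linearization: V = I_w(β̂)^{-1} + V₂ with influence
terms d_i = I_w^{-1} w_i U_i built from the weighted score residuals U_i.

* Stratified without-replacement designs (SRS/PPS/CC):
  `V₂ = Σ_h (1 − f_h)·n_h/(n_h − 1)·Σ_{i∈h} (d_i − d̄_h)(d_i − d̄_h)'` with
  sampling fraction f_h = n_h/N_h; a census (f = 1) recovers the model-based
  variance exactly. Post-stratified CC uses the post-strata here.
* Risk-set designs (NCC/CM): the independent-inclusion (Poisson)
  approximation `V₂ = Σ_i (1 − π_i) d_i d_i'`. We initially evaluated the
  plain with-replacement sandwich `Σ d_i d_i'` and found it badly
  conservative in this setting — CI coverage near 100% and design effects
  below 1, inverting the known efficiency ordering of NCC/CM versus SRS —
  while the (1 − π) form restores nominal coverage (~95%) and design
  effects in line with published two-phase benchmarks. It ignores the
  negative dependence of without-replacement draws and is therefore still
  slightly conservative for CM.

The phase-I variance component is approximated by the inverse weighted
information; this reproduces the structure of survey two-phase linearization
without term-by-term equivalence to any particular package, and is validated
empirically through coverage. Wald tests and 95% CIs use the design-based SE
with normal quantiles.

## Performance measures

Over B replications of one scenario/design: bias, empirical SE (SD of β̂),
MSE = bias² + SE² (an exact identity, tested), coverage and mean length of
the 95% CI, power of the 5% Wald test, standardized bias = 100·bias/SE
(Burton's form), and mean realized n. Ratios use mean *model-based*
variances: design effect = mean V̂_SRS / mean V̂_design (values > 1 mean the
design beats SRS; the published tables follow this orientation), efficiency
vs full = mean V̂_full / mean V̂_design. Because the choice between
model-based and empirical variances in the benchmark tables is not
documented, the empirical-variance ratio is also exported
(`design_effect_empirical`), along with an MSE-ratio variant. Non-converged
replications are excluded and counted.

## Engine and reproducibility

One root `SeedSequence` per run spawns a substream per replication, which
spawns one stream for the cohort and one per design. Consequences, both
tested: identical outputs for identical seeds, cohorts shared across designs
within a replication (common random numbers sharpen design contrasts), and
cohorts unchanged when the design list changes. Failing design replications
are recorded as non-converged and the run continues. All outputs are plain
CSV plus a JSON manifest.

## What the generator does and does not emulate

The synthetic cohorts have purely binary covariates, proportional hazards
with time-constant coefficients, independent non-informative censoring and a
single event type. Real cohorts add continuous covariates, non-proportional
or time-varying effects, dependent censoring and competing risks — passing
tests here demonstrate correctness of the sampling and weighting machinery
under the stated model, not robustness to those violations. Multi-level
matching (m > 1) is supported structurally but the benchmarks exercise only
1:1 matching; case-cohort designs and pilot-data-optimal allocation are out
of scope.

## Known limitations

* The CM inclusion-probability model does not cover own-stratum fallback
  draws (flagged when they occur).
* The NCC/CM variance ignores without-replacement dependence (slightly
  conservative); design-effect comparisons between CM and surrogate-
  stratified CC are sensitive to this at the few-percent level — in our
  benchmark battery at heavy censoring the two designs' effects are within
  ~5% of each other, with the stratified-CC estimator slightly ahead.
* Empirical weights require every stratum with members to realize at least
  one selection; degenerate draws yield logged exclusions rather than
  errors.
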