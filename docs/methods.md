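# Methods

## Model and estimand

The package targets the two-stage analysis an IPD meta-analysis project
would eventually run: stage 1 fits, in each trial separately, the
interaction logistic regression

    logit Pr(y_ij = 1) = α_i + β_i x_ij + γ_i z_ij + λ_i x_ij z_ij,

stage 2 pools the interaction estimates λ̂_i by inverse-variance
meta-analysis. The planning question is: given the trials' aggregate data
and an assumed minimally important λ, what variance — and hence power —
would that pooled estimate have?

The bridge is the Fisher unit information matrix
I_i = E_{x,z}[w·XX′] with X = (1, x, z, xz)′ and Bernoulli weight
w = p(1−p) = e^η(1+e^η)⁻², giving the asymptotic
var(λ̂_i) = I_i⁻¹(4,4)/n_i. The expectation needs only the joint (x, z)
distribution — which aggregate data determine — and the four model
parameters.

## Parameter conventions

- The covariate is taken as mean-centered within each trial. Then α_i is
  approximated by the observed control-arm log-odds log(e_C/(n_C−e_C)) and
  β_i by the trial's overall log odds ratio, both computable from the four
  published counts. This is an approximation: the published counts are not
  stratified by the covariate, but under centering the overall summaries
  estimate the model's intercept and treatment effect at the covariate
  mean. For a binary covariate the closed form uses z ∈ {0, 1} uncentered;
  α/β are still set from overall aggregates, which we treat as the same
  approximation (the contribution of this choice is far below the printed
  precision of the worked examples).
- γ_i defaults to 0 (a prognostic effect is rarely known in advance);
  sensitivity analyses over γ are first-class (`run_sensitivity`).
- λ is common across trials by default; per-trial `lambda`/`gamma` columns
  in the input override it.
- Zero cells (no events, or all events, in an arm) make the log-odds
  undefined. A 0.5 continuity correction is available but **opt-in**
  (`--continuity`): silently modifying counts would change results without
  an audit trail, so the default is a fatal error naming the flag.
- Interaction input: `--ror R --per-units k` means exp(λ·k) = R, i.e.
  λ = log(R)/k per covariate unit. The bundled examples use R = 1.3 with
  k = 1 for sex and k = 10 for age ("30% per decade"), so the per-year
  age interaction is log(1.3)/10 ≈ 0.02624. Note this is close to, but
  not the same as, quoting "odds ratio 1.027 per year"
  (log 1.027 ≈ 0.02664); the reported example results use log(1.3)/10.

## Binary covariate: closed form

With x, z ∈ {0,1} the expectation runs over four cells. Each cell's XX′ is
a constant 0/1 pattern matrix (M₁–M₄ in `fisher_information`), so
I_i = Σ_cells w(η_cell)·M_cell·Pr(cell). The joint probabilities come from
the arm-size split and the per-arm covariate prevalence; if only an
overall prevalence is published, randomization justifies applying it to
both arms. Trials with no covariate data, or with prevalence 0 or 1,
yield a singular information matrix: they are retained with an infinite,
flagged variance and exactly zero weight, rather than dropped — reports
then show *why* the pooled power is what it is.

## Continuous covariate: population expectation

No closed form exists (w depends on z continuously), so the expectation is
computed over a generated (x, z) population matching the aggregates:

- **Monte Carlo** (default): N = 1,000,000 members per trial, split
  between arms in exact floor/remainder proportion (the allocation
  fraction is known, so randomizing it would only add noise), z drawn from
  the arm's assumed family — normal(mean, SD) or uniform matched to the
  same mean and SD (support mean ± √3·SD).
- **Quadrature** (`--method quadrature`): 64-node Gauss–Hermite (normal)
  or Gauss–Legendre (uniform) nodes per arm, arm-weighted. Deterministic;
  agrees with Monte Carlo at N = 10⁶ to well under 0.5% on var(λ̂) and is
  the faster choice when scripting sensitivity grids.

In both methods z is centered by the *analytic* trial-wide mean
(n_C·mean_C + n_T·mean_T)/n, not the realized sample mean — one less
source of Monte-Carlo noise. Outcome events are not simulated: α and β
fully determine the weight function, so generated y's would be unused.

At N = 10⁶ the Monte-Carlo standard error on a pooled power around 90% is
below 0.05 percentage points (the two example projects give e.g. 90.43 vs
90.42 across seeds), so printed-precision reproduction is stable for any
seed.

## Pooling, power, precision

- Common effect: var(λ̂) = (Σ 1/v_i)⁻¹ over finite v_i.
- Random effects: v_i → v_i + τ² first; τ is an *assumption* here (the
  package never estimates it — there are no data yet).
- Wald power: Φ(−z_{1−α/2} + λ/√v) + Φ(−z_{1−α/2} − λ/√v). At λ = 0 this
  is exactly α. Under heterogeneity, Φ and the critical value are replaced
  by a t-distribution on S−1 degrees of freedom, counting only informative
  (finite-variance) trials — non-informative trials cannot help estimate
  τ. This mirrors Hartung–Knapp-style acknowledgement that τ would be
  estimated in practice; it is conservative (t-power ≤ Wald power at
  τ = 0) and approximate for very small S with τ near 0, where a
  simulation-based approach would be preferable.
- Anticipated 95% CI: λ ± z_{1−α/2}·√var(λ̂), reported on the log scale
  and exponentiated. (The standard error, not the variance, scales the
  half-width; likewise the power formulas standardize by √var.)
- Per-trial weights: 100·(v_i+τ²)⁻¹/Σ_j(v_j+τ²)⁻¹, with flagged trials at
  exactly 0.

## Numerical choices

- Matrix inversion is a dense 4×4 solve; the matrix is declared singular
  when its reciprocal condition number (ratio of extreme singular values)
  falls below 1e-12, returning a flagged infinite variance rather than
  raising. The threshold is exposed as an argument.
- Logistic weights are computed via `scipy.special.expit` as p(1−p),
  avoiding overflow of e^η at extreme linear predictors.
- Per-trial Monte-Carlo seeds are spawned from one master seed
  (`numpy.random.default_rng`), so a whole run is reproducible from a
  single integer and trials remain independent streams.

## Validation design and what it shows

`synthetic_ipd` draws participant records from the same logistic model and
refits it by maximum likelihood (statsmodels Logit; observed-information
covariance). `variance_agreement_study` compares the analytic var(λ̂)
with the mean fitted variance over replicates: at n = 2000 the two agree
within 1% for binary and normal covariates, confirming the unit
information is the correct asymptotic object. Known small-sample caveat:
at n ≈ 200 with moderate effect sizes the mean *fitted* variance exceeds
the asymptotic value by roughly 5% (binary z) to 9% (normal z) — genuine
finite-sample bias of the observed-information variance, not Monte-Carlo
error. Anticipated powers for very small trials are therefore slightly
optimistic; at the trial sizes of the bundled examples the effect is
negligible.

The generator emulates a parallel-group trial with exact allocation and a
perfectly specified covariate distribution. Real data differ: covariates
are not exactly normal (the method's variance is then approximate, though
empirically robust), outcome misclassification and clustering are absent,
and published aggregates may not match the IPD eventually delivered.
Passing tests show the *calculation* is faithful to the model, not that
the model captures any particular real trial.

## Known limitations

- Single covariate of interest; no additional adjustment covariates, no
  non-linear interaction functions.
- No sparse-data corrections (Firth etc.) in the validation fitter.
- The anticipated power is conditional on the assumed λ, γ, τ and
  covariate distributions; `sensitivity` exists precisely because these
  are assumptions. τ in particular is hard to specify — the random-effects
  power should be read as a scenario, not a prediction.
- Trials are assumed internally valid two-arm RCTs; the calculator does
  not model within-trial confounding or missing covariate data beyond
  "trial reports nothing → zero weight".
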