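# Methods

## The estimand and the hypothesis

Consider a two-arm comparison with covariates `X`, treatment `A ∈ {0, 1}`
and either a continuous outcome `Y` (larger preferred) or a right-censored
time-to-event `(U, Δ)` with `U = min(T, C)`, `Δ = 1(T ≤ C)`.  With
`τ(x)` the conditional average treatment effect — a difference of
conditional means, or of conditional restricted mean survival times (RMST)
`E[min(T, L) | X]` up to a truncation time `L` — the test addresses

    H0: τ(x) ≤ 0 for all x     vs.     H1: τ(x) > 0 on a set of positive probability,

explicitly allowing `pr{τ(X) = 0} > 0` (the *exceptional law*), where
plug-in inference for the optimal rule is nonregular.  The test statistic is
built from the value difference `Ψ(d_opt) = V(d_opt) − V(0)` between the
optimal rule `d_opt(x) = 1{τ(x) > 0}` (ties go to control) and the
everyone-control rule: `Ψ = 0` under H0 and `Ψ > 0` under H1.

## Per-subject scores

For each subject a score is computed whose mean estimates `Ψ`.  Writing
`π_A = Aπ + (1−A)(1−π)`, `d = 1(τ̂ > 0)` and `w_d = 1{A = d}/π_A`,
`w_0 = 1(A = 0)/(1 − π)`:

* **ipw** (continuous): `w_d·Y − (w_d − 1)(Ĉ0 + τ̂ d) − w_0·Y` — an
  augmented estimator for `V(d_opt)` minus an unaugmented one for `V(0)`.
* **aipw**: adds `(w_0 − 1)·Ĉ0`, augmenting the control value as well.  For
  any subject with `τ̂ ≤ 0` this score is *identically zero* — under a
  regular null the statistic degenerates, which is why the half-augmented
  version is kept alongside.
* **ipws / aipws** (survival, RMST scale): the outcome terms are replaced by
  `ΔL·UL/K̂c(UL|X,A)` — inverse-probability-of-censoring weighting with
  `UL = min(U, L)`, `ΔL = Δ + (1−Δ)·1(U ≥ L)` — and the regime-mismatch
  augmentation term of **aipws** is multiplied by a subject-level
  perturbation `ζ_i ~ Exponential(1)` (mean one, drawn once per run).
  Without `ζ` the chunk-level estimates below can be exactly zero at the
  exceptional law, breaking the statistic's scaling.
* **caipws**: adds `(w_d − w_0)·∫₀ᴸ dM̂c(r)/K̂c(r)·m̂(r)`, the
  censoring-martingale augmentation, where `m̂(r) = Ê[min(T, L) | T ≥ r]`.
  It recovers information from censored, regime-consistent subjects, is the
  locally efficient choice and is doubly robust: it remains consistent if
  either {propensity, censoring model} or the conditional event-time model
  is correct.

The integral is evaluated in its two-term form
`(1−ΔL)·m̂(UL)/K̂c(UL) − Σ_{t_k ≤ UL} dΛ̂c(t_k)/K̂c(t_k)·m̂(t_k)`,
a finite sum over the fitted hazard's step points, with
`K̂c = exp(−Λ̂c)` evaluated *after* each jump.  The residual RMST uses
`m̂(r) = [Σ_{z ∈ (r, L]} z·(−ΔŜ(z)) + L·Ŝ(L)] / Ŝ(r)`, which always
lies in `[r, L]`.

The perturbation `ζ` multiplies only the regime-mismatch augmentation term,
the position it occupies in the half-augmented survival score; the
additive control augmentation and the censoring integrals are not
perturbed.  (Whether the control augmentation should also be perturbed is
not decidable from the published formulas; this choice keeps `ζ = 1`
reductions exact.)

## The one-step sequential statistic

The sample is split into an initial nuisance chunk `C0` of size
`ln = ⌊n/2⌋` (plus any remainder, preserving equal analysis-chunk sizes)
and `rn = ⌊(n − ln)/m⌋` chunks of size `m = 10`.  For chunk `j`, nuisances
are fit on the history `O*_{j−1}` and frozen; `Ψ̂_j` is the mean score over
the chunk and `σ̂_j` estimates its conditional SD from historical subjects
only, floored at `q_j = 10⁻³/j` (any positive vanishing sequence works; a
hyperbolic floor keeps early `σ̂_j⁻¹` finite without affecting the limit).
Then

    T = rn^{−1/2} Σ_j Ψ̂_j / σ̂_j,     p = 1 − Φ(T),  reject if T > z_{1−α},

which is asymptotically N(0, 1) under H0 *including at the exceptional
law*, because each summand is standardized by a history-measurable scale.
The weighted average `Ψ̂ = Σ σ̂_j⁻¹Ψ̂_j / Σ σ̂_j⁻¹` is reported as the
point estimate of `Ψ(d_opt)`.

Two allocation schemes are implemented:

* **SBT** (sequential blinded-treatment): chunks are a uniform random
  partition; `σ̂_j²` is the pooled population variance of the historical
  scores divided by `m`.
* **SAP-match**: each chunk holds `m·π` treated and `m(1−π)` control
  subjects (largest-remainder rounding across chunks when `m·π` is not an
  integer; the sample proportion `p̂` computed on the full sample replaces
  an unknown `π`); `σ̂_j²` is the arm-stratified variance
  `[π·V̂ar(S|A=1) + (1−π)·V̂ar(S|A=0)]/m`.  The stratified conditional
  variance never exceeds the pooled one — it removes the between-arm mean
  component — which is where SAP-match's power advantage for the
  half-augmented score comes from.

`refit_stride = k` refits the nuisances only every `k` chunks.  A fit based
on `O*_{j−k}` is still measurable with respect to `O*_{j−1}`, so validity
is unaffected; staleness can cost a little power.  The stride used is
echoed in every result.

## Nuisance estimation

* **Propensity**: mode `auto` uses the known randomization probability when
  the data carry one and unpenalized logistic regression otherwise.  With a
  known `π` every score above is exactly conditionally unbiased given the
  history, regardless of the quality of `Ĉ0`/`τ̂`; with an estimated
  propensity a finite-sample product bias (estimated-π error times
  outcome-model error) accumulates across chunks and visibly shifts the
  statistic's mean at moderate `n`.  Predictions are clipped to
  `[0.01, 0.99]`.
* **Outcome / CATE** (continuous): one random forest per arm;
  `τ̂ = f̂₁ − f̂₀` (a "two-learner").  Predictions *at the training rows
  themselves* are out-of-bag.  This matters: `σ̂_j` evaluates the score at
  historical (training) subjects, and in-sample forest predictions
  partially memorize `Y`, which deflates the apparent score variance and
  overdisperses `T` (null SD ≈ 1.2–1.4 without the correction, ≈ 1.0 with
  it).  The learner contract is pluggable — any object with
  `fit(history, rng) → NuisanceFit` can be registered — so smoother CATE
  learners (e.g. pooled/synthetic forests) can be swapped in.
* **Survival curves**: one random survival forest per arm;
  `Ĉ0(x) = ∫₀ᴸ Ŝ(t|x, 0) dt` on the forest's event-time grid
  (right-continuous step convention, half-open intervals), `τ̂` its arm
  difference.
* **Censoring**: Cox proportional hazards on `(X, A)` with `U` as time and
  `1 − Δ` as status, Breslow baseline; `K̂c = exp(−Λ̂c)` floored at 0.01
  (floor events are counted and reported; a run with more than 10% floored
  weight evaluations carries a warning).  With no censoring events the
  model degenerates to `K̂c ≡ 1` with a warning; if the Cox fit fails
  numerically, a covariate-free Nelson–Aalen censoring hazard is used.
* Survival denominators `Ŝ(r)` are floored at 10⁻⁴.

Defaults: 300 trees (80 in the scaled-down verification runs), leaf size 5
(continuous) / 15–30 (survival), all seeded; the master seed is split into
independent substreams for partitioning, `ζ` draws, nuisance fitting and
Monte Carlo replication, so changing one layer's draws does not shift the
others.

## Simulation designs (verification harness)

* **Model 1** (continuous): `Y = 3.18 + 0.2X1 + X2 + 0.5X3 +
  A·c·1(−0.5X2² + X4 > 0) + ε`, `ε ~ N(0, 0.25)` (variance 0.25 — the
  conventional reading of the parameterization), `X1–X3` standard normal,
  `X4, X5` Bernoulli(0.5); scheme 2 appends 20 noise covariates.
  Analytically `pr{τ(X) = 0} = 1 − 0.5·pr(χ²₁ < 2) ≈ 0.579`.  `c ≤ 0`
  puts the law in H0 (with `τ = 0` on a positive-probability set — the
  exceptional law — whenever `c ≠ 0` region logic leaves τ ≡ 0 mass),
  `c > 0` in H1.
* **AFT models** (survival): `log T = 1.75 + 0.5X1 + X1² + 0.3X2 + 0.2X3 +
  0.3X4 + 0.6X5 + c·A·1(X2 + 3X4 > 0) + e`, with `e ~ N(0, 0.25)`
  (Model 1, non-proportional hazards) or `e = log Exponential(1)`
  (Model 2, proportional hazards); `pr{τ = 0} = pr(X2 + 3X4 ≤ 0) ≈ 0.251`.
  Censoring: (a) `U(0, 50)`, (b) `U(0, 100)`, or (c) exponential with rate
  `exp(b0 + 0.1X1 + 0.2A)`.  The intercept `b0` is a calibration knob; its
  default −3.5 makes (c) censor more heavily by `L` than (b), the ordering
  the designs are meant to exhibit.  (Taken literally, an intercept of
  −13.5 would produce essentially no censoring.)  Default truncation times:
  `L = 42` under (b), `L = 33` under (c), otherwise the 0.85 empirical
  observed quantile (`choose_L`).
* Treatment: Bernoulli(π), exact-count `Σ A = nπ` (used with SAP-match in
  randomized designs), or the observational logistic model
  `π(X) = expit(−0.3 + 0.2X1 + 0.6X5)` (marginally ≈ 0.5).

Oracle learners expose the true `π`, `C0`, `τ`, `S`, `Kc` of these designs
(survival functions discretized on a 500-point grid), used for calibration
tests that isolate the sequential engine from estimation error.

What the generators do *not* emulate: covariate correlation, non-lognormal
event times, informative censoring, model misspecification beyond the
designed forms.  Passing tests therefore certify the procedure under the
stated designs, not robustness to arbitrary real data.

## Scaled-down verification sizes

The published study used 500 Monte Carlo replicates per condition with
n ∈ {600, 1000} and full-size forests.  The test suite reproduces the key
operating characteristics at reduced cost, as the package's own choice of
problem size: 120 replicates (null level, n = 600), 90 (power pattern,
n = 1000), 50–60 (censored pipeline, n = 600), with 80-tree forests,
60-tree survival forests and refit strides of 5–10; all comparisons carry
3-Monte-Carlo-SE tolerances around the published values, and power
orderings use one-sided binomial tests.  Full-fidelity runs are available
through the CLI (`subvaltest simulate --reps 500 ...`).

## Numerical conventions and edge cases

* Population (not Bessel-corrected) variances in `σ̂_j`, matching the
  estimator's definition.
* Ties `τ̂(x) = 0` assign control.
* Rows with any missing value among used columns are dropped and counted.
* `L` must leave at least one subject with `U ≥ L`; otherwise the data are
  rejected ("L violates positivity").
* Remainder subjects when `m ∤ (n − ln)` enlarge `C0`, keeping every
  analysis chunk at exactly `m`.
* With a frozen fit (`refit_stride = rn`) the per-subject scores are
  independent of chunk order, and `T` is invariant to permutations within
  chunks; `σ̂_j` still depends on chunk order through the membership of the
  growing history, so `T` itself is not exactly order-invariant — a
  property of the growing-history variance estimator, documented here and
  pinned by tests.

## Known limitations

* Two arms, one decision stage, no time-varying covariates.
* The CATE default is a two-learner forest; its sign accuracy on the
  `τ = 0` set is a coin flip by construction (any unbiased estimator's
  is), which costs no value but caps "sign agreement" diagnostics near
  0.71 under Model 1.
* No confidence interval for `Ψ(d_opt)` beyond the standardized statistic,
  and no subgroup identification after rejection.
* The uncensored AIPW statistic is degenerate under a *regular* null
  (`τ < 0` a.s.); the test remains valid (conservative) there via the
  variance floor.
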