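# Methods

This note documents the statistical model behind `mixcomplex`, the
numerical and design choices that were genuinely open, what the synthetic
generators do and do not emulate, and the known limitations.

## Mixture complexity

For a finite mixture f(x) = Σₖ ρₖ gₖ(x) with latent component label Z, the
mutual information I(Z; X) = H(Z) − H(Z|X) measures how much the observed
data tell us about the component label.  Its exponential counts the number
of component labels distinguishable from the data — a continuous cluster
count.  I(Z; X) has no closed form for Gaussian mixtures, so MC is the
plug-in estimate computed from the posterior responsibility matrix alone
(see README for the formula).  All entropies use natural logarithms; MC is
in nats and exp(MC) is the user-facing effective cluster count.

Key properties, all covered by tests:

* 0 ≤ MC ≤ log K, with 0 iff all responsibility rows coincide and log K
  iff assignments are hard and balanced;
* invariance under component duplication (splitting a column by shares
  s, 1−s) and under appending zero columns — MC does not care how the
  same distribution is parameterized;
* uniform weights are *exactly* the unweighted case (the implementation
  short-circuits constant weight vectors so no floating-point drift is
  introduced);
* consistency: as the fitted mixture approaches the truth, MC computed
  from estimated responsibilities approaches MC under the true model,
  even when the fitted K exceeds the true one.  The test suite checks
  this empirically (median error over 10 seeds decreasing across
  N = 200 / 2 000 / 20 000 on a well-separated two-component truth).

Numerical conventions: 0·log 0 := 0 entrywise in both entropy terms;
responsibilities are validated (entries in [0, 1], row sums within 1e-9 of
one) but never clamped — exact zeros are meaningful; the final MC is
snapped into [0, log K] only for residuals below 1e-12, so genuinely
degenerate inputs report exactly 0.

## Hierarchical decomposition

A row-stochastic K×L matrix Q softly assigns lower components to L upper
components.  MC then splits exactly:

```
MC(total)   = MC(interaction) + Σₗ Wₗ · MC(component l)
interaction = MC of the aggregated N×L matrix gamma @ Q
Wₗ          = Σₖ Q[k,l] ρ̃ₖ          (upper-component weight, Σₗ Wₗ = 1)
wₙ⁽ˡ⁾       = wₙ (gamma @ Q)[n,l]    (local data weights)
γ⁽ˡ⁾[n,k]   = Q[k,l] γ[n,k] / (gamma @ Q)[n,l]
```

Degenerate cases are defined by their limits: a point with zero aggregate
mass in group l gets a uniform local responsibility row (its local weight
is zero, so the choice is immaterial), and a group with Wₗ = 0 reports
MC(component l) = 0.  The identity is checked on random instances to
1e-10 and the nested (recursive) application reproduces the flat total.

## Per-step model selection (SDMS)

Per time step the candidate mixture sizes are {1..K_max} initially and
{K̂ₜ₋₁−1, K̂ₜ₋₁, K̂ₜ₋₁+1} ∩ [1, K_max] afterwards.  Each candidate is fitted
by EM and scored with a code length (nats):

| criterion | score |
|---|---|
| AIC       | −L_obs + D |
| AIC+comp  | −L_comp + D |
| BIC       | −L_obs + (D/2) log N |
| BIC+comp  | −L_comp + (D/2) log N |
| NML       | −L_comp + log C_mix(K, N) |
| DNML      | −L_comp + log C_mult(K, N) + Σₖ log C_gauss(Nₖ) |

L_obs is the observed log-likelihood; L_comp the complete log-likelihood
with MAP labels zₙ = argmaxₖ γₖ(xₙ) (ties to the lowest index); Nₖ are the
MAP cluster sizes.  D is the free-parameter count of a K-component
d-variate Gaussian mixture; the default (`standard`) is
(K−1) + K·d(d+3)/2.  A `param_count_mode="as_printed"` variant,
(K−1) + d(d+3)/2, is kept for comparability with descriptions that count
only one component's continuous parameters.

The transition cost codes staying with probability 1/2 and splits the
remaining 1/2 uniformly over the other admissible candidates (0 when only
one candidate exists; 0 at t = 1, where any constant would cancel).  Total
cost ties break toward the smaller K.

**EM.** Fitting delegates to scikit-learn's `GaussianMixture` (full
covariances, reg_covar 1e-6, tol 1e-4, ≤200 iterations, seeded k-means++
initialization).  `n_init` restarts are run explicitly and the restart
minimizing the *configured criterion* is kept — for complete-likelihood
criteria this can differ from the maximum-likelihood restart that a plain
`n_init` would select.  Everything is deterministic given the seed; child
seeds are drawn from a `numpy` generator seeded per step.

**Parametric complexities.**  The multinomial complexity C_mult(K, N) uses
the exact two-term recursion in K, validated against brute-force
enumeration over compositions.  The Gaussian complexity over an unbounded
domain diverges, so it is defined over an explicit bounded domain — the
mean in a Euclidean ball of radius R (default 1e4) and the covariance
through its Cholesky factor L, diagonal entries in
[√λ_min, √λ_max] and off-diagonals within ±√λ_max (defaults λ_min = 1e-2,
λ_max = R).  This domain makes the exact finite-n normalizer separable:

```
log C_gauss(n) = log V + (d/2) log(n/2π) + (d(n−1)/2) log(n/2) − nd/2
                 − log Γ_d((n−1)/2)
```

with V the domain volume above, derived from the sampling density of the
ML estimator (Gaussian mean / Wishart covariance).  For 1 ≤ n ≤ d the ML
covariance is singular and the exact form degenerates; those (rare, tiny
clusters) fall back to the Rissanen asymptotic (D_g/2) log(n/2π) + log V
with D_g = d(d+3)/2.  C_mix(K, N) (complete-likelihood NML of the whole
mixture) sums the per-clustering maximized likelihood over all cluster
size compositions, computed by a binomial recursion in K in log space and
validated against enumeration at small N.  The domain constants shift
every candidate's score by a K-proportional amount and therefore *do*
influence NML/DNML selection; they are deliberately explicit, logged in
run manifests, and configurable (`NMLHyperparams`).

## Stream tracking and its decomposition

Plain tracking is single-pass: SDMS per step (passing the previous K̂),
then MC from the selected model's responsibilities.  A step whose every
candidate fails to fit is recorded as a gap (NaN) and skipped; the next
step's candidates derive from the last successful K̂.

Decomposed tracking is two-pass: the upper components are assumed common
to all time steps, so after fitting, all per-step component means μ̂ₖ,ₜ
(weighted by their proportions ρ̂ₖ,ₜ) are clustered once with a weighted
fuzzy c-means into L centers, and each step's membership rows form that
step's Q.  The FCM loss is Σ ρₖ,ₜ Σₗ Q^m ‖μₖ,ₜ − μ̃ₗ‖²; updates alternate
the exact coordinate minimizers — centers as weighted u^m means and
memberships u ∝ ‖μ − μ̃ₗ‖^(−2/(m−1)).  (The membership update is the
stationary point of the loss; a version with the exponent's sign flipped,
which *increases* with distance, circulates in descriptions of this
algorithm and does not minimize the loss.)  Points coinciding with one or
more centers split membership equally among those centers.  Convergence:
loss improvement < 1e-8 or 300 iterations, loss provably nonincreasing.
Defaults L = 4, m = 1.5; both are user inputs, not selected automatically.

## Change alerts and evaluation

At t = 10..T the detector compares the medians (exact middle order
statistic of 5 values) of y[t−9..t−5] and y[t−4..t].  The continuous rule
(for MC series) fires when |median_early − median_late| > ε, default
ε = 0.01 — large enough to ignore estimation jitter, far below the unit
jumps of K so MC can alert earlier.  The absolute difference is the
default because changes can move MC in either direction; a `one_sided`
flag restricts to decreases.  The discrete rule (for K series) fires on
any difference.  After a raised alert, candidates within the next 4 steps
(strictly fewer than 5 since the last alert) are suppressed.

Against a change period starting at t = 51 with acceptable-alert window
ACCEPT = [51, 109] (the change period plus the detector's look-back
reach): Delay = min(t* − 51, 50) with t* the first alert in ACCEPT (50 if
none); FAR = (alerts outside ACCEPT within [10, T]) / (time points
outside ACCEPT within [10, T]).

## Synthetic benchmarks

The generators reproduce printed specifications exactly:

* **overlap example** — 600 2-D points, two unit Gaussians at distance α,
  balanced; **imbalance example** — means fixed 6 apart, sizes 300±α.
* **move stream** — 150 steps × 1000 3-D points, components of sizes
  333/333/334 at means 0/10/10+α(t) on the first axis, with α(t) = 0,
  then 0.12(t−50) for t = 51..100, then 6.
* **imbalance stream** — four components (sizes 250/250/250+α(t)/250−α(t),
  means 0/10/20/30) with α(t) = 0, then 5(t−51) for t = 51..100, then 250.
  As printed, α jumps from 245 at t = 100 to 250 at t = 101; this is kept
  verbatim.
* **hierarchy fixture** — two distant pairs of overlapping unit Gaussians
  (within-pair distance 1, between-pair 20) with a hard 2-group partition,
  exercising a large interaction term against small within-group terms.

Draws are independent across steps (each step has its own child seed from
one root seed, so any time subset regenerates bit-identically).  Reverse
direction benchmarks feed the *same* generated stream backwards.

What the generators do not emulate: real data's non-Gaussian components,
temporal dependence between steps, varying per-step sample sizes, and
cluster structure in more than one informative dimension.  Passing
benchmarks therefore demonstrates the machinery's behaviour under clean
Gaussian assumptions, not robustness to model misspecification.

## Problem sizes used in the test suite

The stream benchmark comparison in the test suite runs the full stream
conditions (T = 150, N = 1000, d = 3, K_max = 10, ε = 0.01) with BIC, two
regenerated streams per dataset, and 3 EM restarts per candidate — enough
to reproduce the sign-level findings (MC matches K on move-forward,
clearly leads K on move-reverse and imbalance-forward, FAR differences
~0) at desk scale.  Larger trial counts and the remaining criteria are
available via `run_benchmark` / `mixcomplex benchmark`.

## Known limitations

* MC inherits the model-selection step's biases: when K is underestimated
  early in a merging/separating transition, MC cannot see structure the
  fitted model does not represent (visible in the move-forward benchmark,
  where MC cannot lead K).
* NML/DNML scores depend on the bounded-domain hyperparameters; defaults
  are sensible for data on moderate scales but should be revisited for
  data far outside [−1e4, 1e4] or with variances below 1e-2.
* The fuzzy c-means clusters component *means* only; hierarchies defined
  by covariance shape or weight profile are out of reach.
* Decomposed tracking is offline (two passes); the per-step fits are kept
  in memory for the second pass.
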