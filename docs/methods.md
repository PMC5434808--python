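# Methods

This note documents the statistical model behind `bbmeta`, the estimators
and their numerical treatment, the simulation design, and known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model

For study *j* of *K*, arm counts are assumed independent beta-binomial
with a **common intra-class correlation** ρ:

    X₁ⱼ ~ BetaBinom(n₁ⱼ, p₁ⱼ, ρ),   X₂ⱼ ~ BetaBinom(n₂ⱼ, p₂ⱼ, ρ),

in the (π, ρ) parametrization π = α/(α+β), ρ = 1/(α+β+1), so that
E X = nπ and Var X = nπ(1−π)(1+(n−1)ρ).  Requiring a common ρ is the same
as requiring α+β to be shared by the two arms of a study.  The effect
measure is the log-odds-ratio; its delta-method variance inflates each
arm's binomial contribution by the design effect Cᵢⱼ = 1 + (nᵢⱼ−1)ρ:

    Var(θ̂ⱼ) = C₁ⱼ/(n₁ⱼp₁ⱼq₁ⱼ) + C₂ⱼ/(n₂ⱼp₂ⱼq₂ⱼ).                    (V)

Equivalently Var(θ̂ⱼ) = (vⱼ/Nⱼ)(1 + aⱼρ) with the fixed-effect scale
vⱼ/Nⱼ and an inflation coefficient aⱼ that grows linearly with study size.
We compute aⱼ in the numerically transparent form

    aⱼ = (t₁ⱼ + t₂ⱼ) / (t₁ⱼ/n₁ⱼ + t₂ⱼ/n₂ⱼ) − 1,   tᵢⱼ = 1/(pᵢⱼqᵢⱼ),

which is algebraically identical to the allocation-ratio form and reduces
to aⱼ = Nⱼ/2 − 1 for balanced studies.  The identity
(vⱼ/Nⱼ)(1+aⱼρ) ≡ (V) is enforced by tests at 1e-10 relative tolerance on
every fixture; this identity is the reason the package refuses the
superficially similar variant with the allocation ratio inverted (see
"worked example caveats" below).

The admissible range of ρ is the open interval
(max{−1/max(aⱼ), −1/(max(nᵢⱼ)−1)}, 1): below it some design effect or
weight denominator hits zero.  Negative ρ (underdispersion) is allowed and
reported, not clipped, unless the caller asks for truncation at zero.

On the τ² scale of the standard additive random-effects model, the
multiplicative model corresponds study-wise to
τⱼ² = [(n₁ⱼ−1)/(n₁ⱼp₁ⱼq₁ⱼ) + (n₂ⱼ−1)/(n₂ⱼp₂ⱼq₂ⱼ)]ρ (`tau2_equivalent`);
when that map is constant across studies the two models agree in their
first two moments, and the REML estimate of ρ maps onto the additive REML
τ̂² (tested to 1e-6 on a fixture constructed to satisfy the regime).

## Continuity correction

The default rule adds 0.5 to all four cells of a study **if and only if**
that study has an empty cell (`only-zero`); `always` and `never` are
available.  Applying the correction only where needed avoids biasing
non-sparse tables while keeping every downstream quantity finite.  All
variances, proportions and the (vⱼ, aⱼ) pair of a corrected study use the
corrected counts consistently, so the variance identity above survives
correction.  Two estimators bypass the rule by construction: the
Mantel-Haenszel pooled OR and the corrected-MH pooler are assembled in
their zero-safe product forms and consume raw counts (this is what makes
`pool_corrected_mh(·, 0)` equal the classical MH estimate *exactly*, also
on zero-cell data).  Inside the Breslow-Day statistic the 0.5 correction
is applied per study — to cells and margins — only for studies with an
empty cell, while the MH odds ratio it conditions on stays uncorrected.

## Estimators of ρ

All root-based estimators solve their estimating equation by Brent's
method on [ρ_min+ε, 1−ε], ε = 1e-8, xtol = 1e-10.  The statistics involved
(Q*(ρ), X²_BD(ρ)) are continuous and monotone non-increasing in ρ on
well-behaved data (asserted numerically on 200-point grids in the tests);
when the statistic is already below its target at ρ_min+ε the boundary is
returned with `at_boundary=True`, and symmetrically at 1.

* **Moment (M).**  ρ̂ = max[(Q − (K−1))/(K ā − ā_w), −1/max(aⱼ)] with
  ā = Σaⱼ/K and ā_w the FEM-weighted mean.  Closed form; Q < K−1 gives a
  negative estimate (possible underdispersion).
* **Mandel-Paule (MP).**  Root of Q*(ρ) = K−1, where Q*(ρ) uses weights
  wⱼ/(1+aⱼρ) and recomputes the weighted mean at each candidate ρ.
* **Corrected Mandel-Paule (cMP).**  Root of Q*(ρ) = E(Q), with E(Q) from
  the gamma approximation below.
* **REML.**  The mean profiles out of the restricted log-likelihood
  analytically (weighted mean at each ρ), leaving a one-dimensional
  stationarity condition solved by Brent; the score at the solution is
  checked below 1e-6.  When the profiled likelihood is monotone the better
  boundary is returned flagged.  Iteration start is deterministic.
* **Breslow-Day (BD).**  The expected treatment-arm count at the MH odds
  ratio solves a quadratic; the root strictly inside
  (max(0, m₁−n₂), min(n₁, m₁)) is selected (residual-minimizing tie-break
  if both qualify numerically; back-substitution residual < 1e-10 in
  tests).  The MH odds ratio is computed once per dataset and held fixed —
  only the variance is profiled in ρ.  If X²_BD(1) > K−1 the equation has
  no solution and ρ̂ = 1 is returned flagged, the statistic's lower limit
  being attained at ρ = 1.

## Gamma approximation to the distribution of Q

The χ²_{K−1} approximation to Cochran's Q is seriously conservative for
log-odds-ratios when event probabilities are far from one half, because
the weights are estimated and correlate with the estimated effects.  The
corrected mean and variance used by `cMP` and the gamma-band interval are

    (K−1) − E(Q) = 0.678 [(K−1) − E_th(Q)],
    Var(Q) = 4.74(K−1) − 12.17 E(Q) + 9.42 E(Q)²/(K−1),

with shape E(Q)²/Var(Q) and scale Var(Q)/E(Q).  E_th(Q) — the theoretical
approximation to the null mean of Q — sits behind a provider interface:

* `ExactMomentsEth` (default): fits the null (common LOR from the
  fixed-effect estimate; control proportions from the data; treatment
  proportions implied by the common LOR), computes per-study joint moments
  of the estimated weight and effect error **exactly** by enumerating the
  two binomial supports (truncated where the pmf falls below 1e-13, with
  the 0.5 rule applied to boundary cells), and assembles E(Q) through a
  second-order expansion of the weighted-mean term of Q.  The provider is
  validated in the tests against the simulated mean of Q.
* `NullEth`: E_th = K−1, which makes E(Q) = K−1 a fixed point and lets the
  linear correction be tested in isolation; with it, cMP coincides with MP
  exactly.

Neither provider consumes the ρ-corrected weights, so the gamma quantiles
are computed once at the null fit and held fixed along profile curves (the
interval metadata records this).  At matched moments (mean K−1, variance
1.99(K−1)) the gamma band nearly coincides with the χ² band; the 1.99 vs 2
difference keeps the coincidence approximate.

## Confidence intervals

Q-profile, gamma-profile and BD-profile intervals are the sets of ρ whose
statistic falls between the α/2 and 1−α/2 quantiles of the reference
distribution, with endpoints located by Brent's method; truncation at the
admissible range is flagged, and a confidence set with no admissible
member is reported as `empty` rather than raising.  As the level tends to
zero these intervals collapse to a point — the ρ at which the statistic
equals the reference *median*, which for skewed references differs
slightly from the point estimator's target K−1.  The REML interval is the
χ²₁/2 likelihood-drop set of the profiled restricted likelihood.

## Pooling

* **Inverse variance.**  Weights 1/Var(θ̂ⱼ) from (V) at the supplied ρ̂;
  normal CI on the log scale, exponentiated for the OR scale.  ρ = 0
  reproduces fixed-effect pooling.
* **Corrected MH.**  Weights WⱼC = [C₁ⱼ/n₁ⱼ + C₂ⱼ/n₂ⱼ]⁻¹(1−p̂₁ⱼ)p̂₂ⱼ;
  numerator and denominator are expanded so zero cells contribute zero
  instead of dividing by zero.  The variance display for this estimator in
  the source material is typographically ambiguous; we implement the
  Robins-Breslow-Greenland variance of the log pooled OR with
  overdispersion-corrected components

      Pⱼ = [C₁ⱼ(n₂ⱼ−x₂ⱼ) + C₂ⱼx₁ⱼ]/(C₁ⱼn₂ⱼ + C₂ⱼn₁ⱼ),  etc.,

  which reduce exactly to the classical RBG components at ρ = 0 — a hard
  reduction test.  As ρ → ρ_min the weights concentrate on the largest
  balanced studies and the estimate tends to the MH estimate of that
  subset (tested at ρ_min + 1e-6 to 1e-3).  Simulations show this pooler
  is markedly biased away from the null for large ρ and n, so IV is the
  default; cMH is retained for comparison.

## Simulation harness

`generate_dataset` draws equal arm sizes nⱼ ~ round(Normal(n, n/4))
left-truncated at 5 — we read "variance n/4" literally as the variance
(SD = √n/2) — control counts BetaBinom(nⱼ, p₂, ρ) and treatment counts
with p₁ = p₂e^θ/(1−p₂+p₂e^θ); ρ = 0 draws binomials.  Beta-binomial
sampling uses the conjugate two-stage construction
p ~ Beta(πs, (1−π)s), s = 1/ρ − 1, X ~ Binom(n, p), which matches the
target mean and variance exactly (and the full distribution, not just two
moments).  Replicates with empty cells follow the `only-zero` correction
rule and are counted, never discarded; estimator failures and boundary
hits are counted per cell and never abort a run.

Randomness: a single master seed, with `SeedSequence(seed,
spawn_key=(cell, replicate))` substreams, so any cell or replicate can be
rerun in isolation and grid results are independent of execution order.

The full published design — K ∈ {5,10,20,30,50,80},
n ∈ {10,…,1000}, ρ from 0 to 0.1 by 0.01 then 0.1 to 0.3 by 0.05
(enumerated literally, so ρ = 0.1 appears in both ranges and the grid has
6·10·16·4·3 cells), θ ∈ {0,1,2,3}, p₂ ∈ {0.1,0.2,0.4}, 10000 replicates —
is enumerable via `paper_grid()` and emitted by
`bbmeta simulate --paper-grid`, but is deliberately not run by default:
the packaged experiments use single cells at 500–1000 replicates, which
puts Monte-Carlo standard errors around 0.007 for coverage and is
sufficient for the qualitative conclusions (downward bias of ρ̂ growing
with ρ; near-nominal BD-profile coverage at moderate n; unbiased pooled
effect at θ = 0).

What the generator does *not* emulate: unequal arm sizes within a study,
study-level variation in ρ or in p₂, correlation between the two arms of
a study, and publication selection.  Passing simulation tests therefore
say nothing about robustness to those features of real data.

## Numerical and design notes

* Bias of the sample LOR under overdispersion (`lor_bias_analytic`)
  implements the leading-order expansion
  −(1−2p₁)C₁/(2n₁p₁q₁) + (1−2p₂)C₂/(2n₂p₂q₂); it cancels exactly for
  p₁ = p₂, n₁ = n₂ and is O(1) in n when ρ ≠ 0 — the structural reason the
  pooled OR acquires bias away from the null.
* On the OR scale the pooled estimate exp(θ̂) carries a convexity
  (Jensen) term ≈ exp(Var(θ̂)/2), a fixed offset at any replicate count;
  "no bias at θ = 0" is exact on the LOR scale and holds on the OR scale
  only where the pooled variance is small (large K·n).  The tests assert
  it accordingly.
* Counts are validated as exact integers (decimals rejected, not
  rounded); study order is preserved everywhere.
* All report output is rounded to 3 decimals; machine-readable CSV/JSON
  output keeps full precision.
* Default confidence level is 0.95 throughout.

## Worked example caveats

On the packaged nine-trial pre-eclampsia dataset the package reproduces
the published fixed-effect row, Cochran's Q, the standard additive-model
results, and the ρ profile intervals to the printed precision.  The
published table's remaining beta-binomial entries are internally
inconsistent with the printed formulas (they are reproducible only by
inverting the allocation ratio inside aⱼ, which breaks the variance
identity (V) that defines aⱼ; and the published BD point estimate is
inconsistent at the fourth decimal with its own published BD interval,
which we match).  `bbmeta` implements the printed formulas; the worked
example's affected entries differ from the published ones in the third
decimal, and the acceptance tests record exactly which.

## Known limitations

* Two-arm 2×2 tables only: no person-time, matched or multi-arm data.
* A single ρ shared by both arms and all studies; the one-arm
  overdispersion variant and bivariate beta-binomial extensions are out of
  scope.
* The gamma-approximation constants (0.678, 4.74, 12.17, 9.42) are taken
  as exact as published; they were calibrated against a different
  theoretical-mean approximation than our enumeration provider, so `cMP`
  inherits a small approximation mismatch (its variance formula is
  conservative at small n·p).
* Profile intervals assume monotonicity of the profiled statistic in ρ;
  pathological datasets violating it would yield intervals computed from
  the outermost crossings.
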