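# bbmeta

Meta-analysis of odds ratios under the **beta-binomial overdispersion
model**: estimation of the intra-class correlation (ICC) that drives
between-study heterogeneity, and pooling of odds ratios with
ICC-corrected weights.

## The problem

A meta-analysis of *K* comparative trials with binary outcomes reports, for
each study *j*, events *x₁ⱼ* of *n₁ⱼ* in the treatment arm and *x₂ⱼ* of
*n₂ⱼ* in the control arm.  The effect measure is the odds ratio
ψⱼ = p₁ⱼ(1−p₂ⱼ)/(p₂ⱼ(1−p₁ⱼ)) or its log θⱼ.  The standard random-effects
model adds a constant between-study variance τ² to each study's sampling
variance.  An alternative is *multiplicative* overdispersion: if the counts
in each arm are beta-binomial with a common intra-class correlation ρ —
BetaBinom(n, π, ρ) has mean *nπ* and variance *nπ(1−π)(1+(n−1)ρ)* — then
the variance of each study's log-odds-ratio is inflated arm-wise by the
design effects *Cᵢⱼ = 1 + (nᵢⱼ−1)ρ*:

```
Var(θ̂ⱼ) = C₁ⱼ/(n₁ⱼ p₁ⱼ q₁ⱼ) + C₂ⱼ/(n₂ⱼ p₂ⱼ q₂ⱼ)
         = (vⱼ/Nⱼ)(1 + aⱼ ρ),      aⱼ = Nⱼ/2 − 1 for balanced studies.
```

ρ is directly interpretable as an intra-cluster correlation (e.g.
clustering by healthcare provider) and is typically below 0.1 in
biomedical applications.

## What the package provides

Five estimators of ρ, each with a profile confidence interval:

| method | estimating equation | interval |
|--------|--------------------|----------|
| `M`    | moment: Q = K−1 + (K ā − ā_w)ρ | Q-profile (χ² band) |
| `MP`   | Mandel-Paule: Q*(ρ) = K−1 | Q-profile (χ² band) |
| `cMP`  | corrected MP: Q*(ρ) = E(Q) from a gamma approximation to Q | gamma-band profile |
| `REML` | restricted likelihood under the normal working model | χ²₁ likelihood-drop |
| `BD`   | inverted Breslow-Day test: X²_BD(ρ) = K−1 | BD-profile (χ² band) |

Here Q*(ρ) is Cochran's statistic with corrected weights
wⱼ/(1 + aⱼρ), and X²_BD(ρ) is the Breslow-Day homogeneity statistic with
design-effect-deflated cell variances.  The chi-square approximation to Q
is poor for log-odds-ratios, hence the gamma-based correction behind
`cMP`; `BD` and `cMP` complement each other (large and small studies
respectively).

Two poolers: ICC-corrected **inverse-variance** (`IV`, the recommended
default) and the **corrected Mantel-Haenszel** estimator (`cMH`) with an
overdispersion-adjusted Robins-Breslow-Greenland variance.  Both reduce
exactly to their classical fixed-effect forms at ρ = 0.  A beta-binomial
**simulation harness** reproduces bias/coverage experiments for all
estimators over a configurable grid.

## Worked example

The packaged dataset is the classic nine-trial meta-analysis of diuretics
for preventing pre-eclampsia (6942 patients), a standard benchmark with
marked heterogeneity in both incidence and effect size.

```python
from bbmeta import pre_eclampsia, study_effects, cochran_q, analyze

data = pre_eclampsia()
eff = study_effects(data)
print(round(cochran_q(eff), 3))        # 27.265 on K-1 = 8 df
icc, pooled = analyze(data, icc_method="BD", pool_method="IV")
print(round(icc.rho, 3))               # 0.018
print(round(pooled.psi, 3))            # 0.628
```

or from the shell:

```
$ bbmeta analyze diuretics.csv --icc all --pool both
model method    icc    L      U      LOR    L      U      OR     L      U
FEM             0.000                -0.398 -0.573 -0.223 0.672  0.564  0.800
BB    M&IV      0.007  0.002  0.095  -0.425 -0.779 -0.071 0.654  0.459  0.932
BB    M&cMH     0.007  0.002  0.095  -0.432 -0.775 -0.089 0.649  0.461  0.915
BB    MP&IV     0.016  0.002  0.095  -0.458 -0.910 -0.006 0.632  0.402  0.994
BB    MP&cMH    0.016  0.002  0.095  -0.465 -0.902 -0.029 0.628  0.406  0.972
BB    cMP&IV    0.017  0.003  0.094  -0.462 -0.924 0.001  0.630  0.397  1.001
BB    cMP&cMH   0.017  0.003  0.094  -0.469 -0.915 -0.022 0.626  0.400  0.978
BB    REML&IV   0.010  0.001  0.058  -0.434 -0.816 -0.052 0.648  0.442  0.949
BB    REML&cMH  0.010  0.001  0.058  -0.442 -0.811 -0.072 0.643  0.444  0.931
BB    BD&IV     0.018  0.003  0.107  -0.465 -0.938 0.008  0.628  0.391  1.008
BB    BD&cMH    0.018  0.003  0.107  -0.472 -0.929 -0.015 0.624  0.395  0.985
```

Reading the table: ignoring overdispersion (FEM) gives OR 0.672 with a
deceptively tight interval.  Every ICC estimator detects positive
overdispersion (ρ̂ between 0.007 and 0.018, intervals excluding 0), and
accounting for it moves the pooled OR down to ≈ 0.62–0.65 while widening
the interval — for the recommended Breslow-Day/inverse-variance pair,
OR 0.628 (0.391, 1.008).  Simulation: the corrected Mandel-Paule estimator
is preferable for small studies (n ≲ 100) and the Breslow-Day estimator
for large ones; the corrected MH pooler is noticeably biased away from the
null and is provided for comparison only.

Simulations run from a YAML grid config:

```bash
bbmeta simulate grid.yaml --seed 1 --reps 1000 --out results.csv
bbmeta simulate --paper-grid --out full_grid.yaml   # write the full
                                                    # published design (not run)
```

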