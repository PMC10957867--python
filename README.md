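# ivsem

Bayesian instrumental-variable structural-equation regression for testing
whether **grandparental investment moderates the effect of cumulative
adverse early-life experiences (AELEs) on children's emotional and
behavioral problems** (total SDQ score), together with a synthetic survey
generator so the whole pipeline is testable without access-restricted
survey data.

## The problem and the model

Children who face multiple adversities (a parent jailed, family
bereavement, financial shocks, …) show more emotional and behavioral
problems. Whether a grandparent's investment *causally* buffers that
effect cannot be read off a regular regression: investment is endogenous
(omitted family-level confounders, measurement error, possible reverse
causation). The package estimates the structural system

```
gi_c      = a10 + a1'z + a1e·aele_c            + e1      (first stage)
gi_x_aele = a20 + a2'z + a2e·aele_c            + e2      (first stage)
sdq       = b0 + b_gi·gi_c + b_int·gi_x_aele + b_ae·aele_c + e3
```

where `gi_c` is the grand-mean-centered investment composite (mean of four
Likert items, one reverse-scaled), `aele_c` the centered count of eight
binary adverse events, and `z` the six instruments: three
grandparent–grandchild living-distance dummies (reference: overseas) and
their products with `aele_c` — the natural instruments for the endogenous
interaction. The row-wise errors `(e1, e2, e3) ~ MVN(0, Ψ)` have free
covariances: `cov(e1, e3)` and `cov(e2, e3)` absorb all omitted
confounding, and their joint Wald test is the endogeneity check.

Estimation is by Gibbs sampling (N(0, 100²) coefficient priors,
least-informative proper inverse-Wishart on Ψ, 2 chains × 20,000
iterations with 10,000 burn-in by default), summarized by posterior
medians, 95% highest-posterior-density intervals and one-tailed
probabilities; closed-form 2SLS serves as the frequentist oracle.
Diagnostics cover instrument relevance (Wald→F, strong when F > 10),
exclusion (direct instrument→outcome paths in an alternative
identification mode), endogeneity, and Gelman–Rubin convergence.
Item-level missingness is handled by joint-normal multiple imputation
(m = 15) with pooling by posterior-draw concatenation.

## Worked example

```python
from ivsem import (SimulationConfig, ModelSpec, simulate_survey,
                   build_analysis_frame, gibbs_fit, instrument_strength,
                   simple_slopes)
from ivsem.diagnostics import endogeneity_test, relevance_f, psrf

cfg = SimulationConfig(n_children=1200, seed=42, missing_rate=0.0)
survey = simulate_survey(cfg)             # planted: 2.476, 3.196, -0.839
print("instrument correlation r = %.2f" % instrument_strength(survey))

frame = build_analysis_frame(survey)
fit = gibbs_fit(frame, ModelSpec(iterations=4000, burn_in=1500, seed=0))
print(fit.summary_.loc[["sdq_total~gi_c", "sdq_total~aele_c",
                        "sdq_total~gi_x_aele"],
                       ["median", "hpd_lower", "hpd_upper", "one_tailed_p"]])
```

prints

```
instrument correlation r = 0.70
                     median  hpd_lower  hpd_upper  one_tailed_p
sdq_total~gi_c        2.419      2.226      2.617           0.0
sdq_total~aele_c      3.228      3.141      3.321           0.0
sdq_total~gi_x_aele  -0.765     -0.897     -0.620           0.0
```

The planted effects (investment 2.476, adversity 3.196, interaction
−0.839 SDQ units) are recovered within posterior uncertainty despite the
planted confounding; the interaction's HPD excludes zero, i.e. each unit
of investment removes about 0.8 SDQ units from the per-event adversity
effect. Diagnostics and conditional ("simple") slopes:

```python
w = endogeneity_test(fit)          # Wald chi2(2) = 113.39, P = 0.000
rel = relevance_f(fit)             # F = 191.0 / 200.9 -> strong
print("max PSRF = %.3f" % psrf(fit.draws_).max)   # 1.001
ba = fit.draws_.select(["sdq_total~aele_c"])[:, 0]
bi = fit.draws_.select(["sdq_total~gi_x_aele"])[:, 0]
print(simple_slopes(ba, bi, [-1.5, 0.0, 1.4]))
```

```
   gi_c  slope  hpd_lower  hpd_upper
0  -1.5   4.38       4.13       4.61
1   0.0   3.23       3.14       3.32
2   1.4   2.16       1.94       2.35
```

At minimal investment every adverse event adds ≈ 4.4 SDQ units; at high
investment ≈ 2.2 — buffered, but not erased.

There is also a CLI (`ivsem simulate|preprocess|impute|fit|diagnose|report|all`)
running the same pipeline per grandparent type (MGM/MGF/PGM/PGF presets
spanning strong to weak instrument regimes).

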