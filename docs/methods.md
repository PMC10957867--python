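# Methods

## The estimand and the structural system

The scientific question is whether grandparental investment moderates the
effect of cumulative adverse early-life experiences (AELEs) on a child's
emotional and behavioral problems, measured by the total Strengths and
Difficulties Questionnaire (SDQ) score (sum of the four difficulty
subscales, range 0–40). Investment is endogenous — omitted family-level
confounders, measurement error in child-reported items, and possible
reverse causation all correlate it with the outcome error — so a regular
regression of SDQ on investment is not causally interpretable. The
package estimates a three-equation triangular system per child:

```
gi_c      = a10 + a1'z + a1e·aele_c                      + e1
gi_x_aele = a20 + a2'z + a2e·aele_c                      + e2
sdq       = b0 + b_gi·gi_c + b_int·gi_x_aele + b_ae·aele_c [+ g'd] + e3
```

* `gi_c` — grandparental-investment composite: the mean of four
  Likert-type items (contact frequency on 1–3; caretaking, dependability
  and financial help on 1–4, caretaking stored reverse-scaled and
  reversed as 5 − v during scoring), grand-mean centered. The 3-point
  item is averaged raw with the 4-point items (a rescale option exists
  but is off by default, matching the source procedure).
* `aele_c` — centered count (0–8) of eight binary adverse events.
* `z` — six instruments: three living-distance dummies `d`
  (same town / within 10 miles / further in the UK; overseas is the
  reference) and their products with `aele_c`. Distance is a plausible
  instrument because it strongly predicts investment but has no credible
  direct pathway to a child's SDQ; the products are the natural
  instruments for the endogenous interaction. The same instrument set
  identifies both endogenous predictors.
* `(e1, e2, e3) ~ MVN(0, Ψ)` row-wise. The system is triangular, so the
  Jacobian of the transformation from errors to observables is 1 and the
  residual vector carries the full likelihood.

Centering both moderator and exposure makes `b_ae` the adversity effect
at average investment and `b_int` the change in that effect per
investment unit; the conditional ("simple") slope at centered investment
`g` is `b_ae + b_int·g`.

Two mutually exclusive identification modes reflect that a model with
both free instrument→outcome effects and free instrument-side error
covariances is never identified:

* **covariance mode** (the estimation model): `g ≡ 0`; `Ψ` is a free 3×3
  covariance. The joint Wald test of `Ψ31 = Ψ32 = 0` is the endogeneity
  check — rejection means naive regression would be confounded.
* **direct mode** (the exclusion check): the three distance dummies get
  direct effects `g` on the outcome while `cov(e1,e3) = cov(e2,e3) = 0`;
  the joint Wald test of `g = 0` screens the exclusion restriction. The
  dummy×AELE products stay excluded — the dummies are the fundamental
  instruments, the products derived ones. Because this mode zeroes the
  endogeneity covariances, genuine confounding is absorbed into `g`:
  the screen is informative about the *combination* of exclusion and
  no-shared-causes, which is exactly as much as any observational design
  can deliver; the two assumptions are not separately testable.

## Estimation

**2SLS.** The closed-form two-stage least-squares solution
`β = (X'P_Z X)⁻¹ X'P_Z y` with asymptotic covariance
`σ²(X'P_Z X)⁻¹` is the frequentist oracle; it also reports the partial
first-stage F of the excluded instruments per endogenous predictor
(reduced model: intercept + exogenous covariates).

**Gibbs sampler.** Priors are independent N(0, prior_sd²) on every
regression coefficient (default SD 100 — effectively flat on the SDQ
scale) and inverse-Wishart on `Ψ`. The source procedure's improper
reference prior is replaced by its proper least-informative counterpart,
IW(identity, dim+1) per block (3×3 in covariance mode; 2×2 ⊕ 1×1 in
direct mode), which guarantees a valid conjugate Gibbs step; the
hyperparameters are exposed. The sampler alternates

1. the joint Gaussian full conditional of all coefficients given `Ψ`
   (precision `ΣⱼₖΩⱼₖXⱼ'Xₖ + I/prior_sd²`, with `Ω = Ψ⁻¹` and cached
   cross-product blocks — all three designs are fixed, so one iteration
   costs one small Cholesky plus residual updates), and
2. the conjugate inverse-Wishart full conditional
   `Ψ | θ ~ IW(Λ₀ + R'R, ν₀ + n)`, sampled by Bartlett decomposition,
   which is symmetric positive definite by construction (non-finite
   draws would be redrawn and counted; in practice the count is zero).

Defaults: 2 chains × 20,000 iterations, 10,000 burn-in each (20,000
retained draws). Chains start from equation-wise least squares with
chain-specific jitter so the convergence diagnostic sees distinct
starting points. All randomness flows from one integer seed through
`numpy.random.SeedSequence`; identical seed + data ⇒ identical draws.

**Summaries.** Posterior medians; 95% highest-posterior-density
intervals by the shortest-window rule over sorted draws (the window
holds exactly `ceil(0.95·n)` draws, which makes the interval invariant
under draw duplication — the property that makes pooling of identical
imputations exactly reproduce a single fit); one-tailed probabilities as
the share of draws on the side of zero opposite the median's sign, with
draws exactly at zero counted half.

## Diagnostics

* **Relevance** — joint Wald test of the six instrument coefficients in
  each first-stage equation, from the posterior mean and covariance of
  that block (a normal approximation to the joint posterior, and
  documented as approximate), converted to F = W/q and flagged strong
  when F > 10 (strictly greater). On complete data this agrees with the
  directly computed first-stage regression F within a few percent.
* **Endogeneity** — Wald test (df 2) of the two investment–outcome error
  covariances, covariance mode only.
* **Exclusion** — Wald test (df 3) of the direct distance→outcome
  effects, direct mode only.
* **Convergence** — original Gelman–Rubin potential scale reduction
  factor (between- vs within-chain variance; no rank normalization, no
  split chains, matching the era of tooling the procedure comes from; a
  split-chain variant is available behind an argument). Constant
  identical chains are reported on an explicit `degenerate` list rather
  than as NaN. Thresholds: < 1.1 good, < 1.2 acceptable.

## Multiple imputation

Missing investment and adversity items are imputed under an unrestricted
multivariate-normal model of all numeric analysis variables (outcome and
exclusion flags included, so the imputation model is congenial with the
analysis). A data-augmentation Gibbs sampler alternates the
normal–inverse-Wishart full conditional of (μ, Σ) with conditional-normal
draws of the missing cells per missingness pattern; completed datasets
are taken every 25 iterations after a 100-iteration warm-up. Ordinal
items are rounded and clipped to their ranges; observed cells are
restored verbatim. Default m = 15 keeps the Monte-Carlo inflation of
standard errors within about 5%.

Grand means for centering are computed once on the stacked imputed data
and applied to every imputed set, so "one investment unit" means the same
thing across imputations. Bayesian results are pooled by equal-weight
draw concatenation (the mixture a pooled credibility interval
summarizes); Rubin's rules are provided for the 2SLS path. The sampler
seed is a fixed model setting reused across imputations, which makes the
zero-missingness pooling identity exact.

**Known limitation.** A linear variance–covariance imputation model
cannot carry product-term information. With per-item 10% MCAR
missingness the pooled interaction estimate attenuates toward zero by
roughly 15% (about two posterior SDs at n = 1500): the adversity
binaries are only weakly inter-correlated, so an imputed cell is mostly
noise, and that noise enters the adversity count, the endogenous
interaction *and* its dummy×adversity instruments, so the IV step cannot
purge it. The same attenuation reproduces under an independent
chained-equations imputer, i.e. it is inherent to impute-then-transform
with weakly informative items, not an implementation artifact. Milder,
realistic item nonresponse (a few percent) leaves the interaction
essentially unchanged.

## The synthetic survey generator

The generator emulates the statistical structure the analysis assumes,
calibrated to the survey moments the method was developed against:

* distance uniform over four levels; a latent standard-normal confounder
  `U` loads on the investment propensity (loading 0.5) and the outcome
  error (loading `confounding/0.5`), so `confounding` is the
  latent-scale error covariance;
* investment propensity = 1.6 + distance effects + 0.5·U + N(0, 0.3);
  the four items are equal-width discretizations of noisy copies
  (item noise SD 0.3) onto their Likert ranges, the caretaking item
  stored reverse-scaled so downstream reversal is exercised; the default
  distance effects (1.62, 1.08, 0.54) give a proximity–composite
  correlation of ≈ 0.71 — the strong-instrument regime;
* the outcome is generated from the *item-based composite*, so the
  planted coefficients refer to the same composite the analysis
  estimates; SDQ = 12.75 + structural terms + confounder + N(0, 1.8),
  rounded and clipped to [0, 40] (the clip is treated as an observation
  floor/ceiling, not structure);
* adversity events are exchangeably correlated Bernoulli draws
  (beta-binomial mixing, per-event probability 0.19, intra-class
  correlation 0.0814) so the count has mean ≈ 1.52 and SD ≈ 1.39;
  independent events would give SD ≈ 1.11, understating how adversities
  cluster in children;
* item missingness is MCAR at `missing_rate` (default 5%, a typical
  item-nonresponse level; the source does not state its rate); a
  missing-at-random variant tied to the SDQ score sits behind
  `mar_on_sdq`. The outcome itself is never masked.

Defaults plant the maternal-grandmother effects (2.476, 3.196, −0.839
SDQ units) with `confounding = 0.6`, under which naive OLS overstates
the investment effect by ≈ 0.6 SDQ units while 2SLS and the Bayesian fit
recover the truth. Per-grandparent-type presets span the observed
instrument regimes (r ≈ 0.71 / 0.70 / 0.55 for MGM/MGF/PGM, and a
deliberately weak paternal-grandfather regime whose typical minimum
first-stage F ≈ 8 mirrors the weak-instrument flag; its r ≈ 0.23 —
a homogeneous generator cannot show r ≈ 0.46 and F ≈ 8 at n ≈ 817
simultaneously, and the preset favors the weak-F behavior the pipeline
flags) and the per-type sample sizes 1197/1100/950/817.

What passing tests on these data do **not** show: robustness to
exclusion violations (the generator's distance affects SDQ only through
investment unless a direct path is planted), to selection on having a
living grandparent (not modeled; the source design shares this), to
sibling/classroom clustering (none generated), or to non-MCAR/MAR
missingness.

## Numerical and scale choices

* Replicate studies (coverage, test calibration, power) use 2 chains ×
  1,100 iterations with 300 burn-in (1,600 retained draws) at n = 1,000:
  large enough that HPD endpoints are stable — the shortest-window rule
  is slightly narrow-biased at small draw counts — while keeping a
  200-replicate study within a couple of minutes on one CPU.
* Exclusion-screen calibration runs under `confounding = 0`, since with
  confounding on the direct-effect model correctly attributes the
  confounded association to `g` (see above); its power is assessed
  against a planted 2-SDQ-unit direct distance path.
* Rank deficiency of the instrument or design matrix is detected by QR
  and reported with the names of the offending columns. Degenerate
  inputs (constant adversity, all-missing items, fewer complete rows
  than a configurable minimum) raise early with specific messages.
* Wald tests use a Cholesky solve and fail loudly on non-positive-
  definite restricted covariance blocks; F = W/q is the documented
  Wald→F conversion (no small-sample degrees-of-freedom correction).
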