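# Methods

This note records the model, the calibration choices, and the numerical
decisions behind `misim`, in the order the simulation runs.

## Data-generating process (`misim.dgp`)

A cohort of size *n* is drawn as follows.

1. **Exposure and confounder.** A latent standard normal *L* is drawn and
   the exposure set to *E* = 1{*L* > z}, with z the upper-`p_exposure`
   quantile. The confounder is *X* = r·*L* + √(1−r²)·*W* with *W* an
   independent standard normal. The latent correlation r is solved in
   closed form from the target *Pearson* (point-biserial) correlation:
   corr(*X*, *E*) = r·φ(z)/√(p(1−p)), so r = 0.5013 for the default target
   0.4 at p = 0.5. Targets beyond the attainable point-biserial bound
   φ(z)/√(p(1−p)) raise a calibration error.
2. **Outcome.** *Y* ~ Bernoulli(expit(β₀ + β₁E + β₂X + β₃EX)) with default
   odds ratios exp(β₁)=2, exp(β₂)=1.5, exp(β₃)=1.2.
3. **Intercept calibration.** Because *X* is shifted within exposure groups
   (mean ∓0.4 under the defaults), the intercept that yields a stated
   baseline outcome probability is *not* the logit of that probability.
   The default β₀ is found by root-finding on the quadrature expression for
   Pr(*Y*=1|*E*=0) = ∫ expit(β₀+β₂x) f(x|E=0) dx, targeting 0.091. This
   gives exp(β₀) ≈ 0.1114 and implies Pr(*Y*=1|*E*=1) ≈ 0.2327 and a
   marginal prevalence Pr(*Y*=1) ≈ 0.1619. A naive β₀ = log(0.091) would
   instead yield Pr(*Y*=1|*E*=0) ≈ 0.076; the calibrated default is the
   only way the stated conditional probabilities are jointly attainable
   with the stated effect sizes. An explicit `beta0` bypasses calibration.
4. **Secondary outcome.** *Y′* is Bernoulli given *Y* alone, with
   conditionals (Pr(*Y′*=1|*Y*=1), Pr(*Y′*=1|*Y*=0)) chosen so the 2×2
   distribution of (*Y*, *Y′*) has a stated tetrachoric correlation
   (default 0.49) and a stated marginal Pr(*Y′*=1) (default: the model's
   own outcome prevalence, since no external value is implied by the
   design). The joint cell Pr(*Y*=1, *Y′*=1) is the upper-orthant
   probability of a bivariate normal with that correlation and thresholds
   from the margins, computed by stable 1-D quadrature (the frozen
   bivariate normal is singular near ρ = ±1). Conditioning on *Y* only
   makes *Y′* ⫫ (*X*, *E*) | *Y* hold by construction. For margins in
   (0,1) every ρ ∈ [−1,1] is feasible (the joint cell interpolates between
   the Fréchet bounds).
5. The empirical tetrachoric estimator inverts the same bivariate-normal
   cell equation at the observed margins by Brent root-finding (tolerance
   1e−8).

Reproducibility: the four random draws (latent, residual, outcome uniforms,
secondary uniforms) occur in fixed order from one `numpy` Generator, so a
(config, seed) pair is bit-reproducible.

## Amputation (`misim.amputation`)

Missingness masks for *X*, *Y*, *Y′* are independent Bernoulli draws; *E*
is never masked. Mechanisms:

* **MCAR** — constant probability equal to the level.
* **MAR** — expit(a + log(OR)·E), OR = 5 by default.
* **MNAR** — expit(a + log(OR)·value): for the binary outcomes this is the
  exposure-style two-point mixture with the variable's model prevalence;
  for *X* the OR applies per 1-SD unit (the only unit-free scale for a
  standardised covariate), and the expectation over the standard-normal
  marginal is computed by 96-node Gauss–Hermite quadrature.

In each case the intercept a is the Brent root (xtol 1e−14) of
E[Pr(missing)] = level, so the analytic expected missingness matches the
target to ~1e−10 at every mechanism/level pair; baseline probabilities are
therefore implied rather than free parameters. At level 0.4 with OR 5 and
a balanced driver, the baseline/exposed probabilities are the quadratic
roots 0.21789 / 0.58211. `level=0` is accepted as a degenerate
no-missingness scenario for null testing. Truth is retained next to the
masks; strategies receive only the masked (NaN) view.

## Chained-equations imputation (`misim.fcs_imputer`)

Proper FCS with two conditional families:

* continuous targets: Bayesian linear regression — least squares on the
  observed rows (normal equations with a ridge of 1e−6 on the Gram matrix
  for stabilisation), residual variance drawn from its scaled
  inverse-χ² posterior, coefficients from their conditional normal,
  values from the predictive normal;
* binary targets: ML logistic fit, one coefficient draw from the
  asymptotic normal approximation to the posterior, values as Bernoulli.
  This mirrors mainstream chained-equations implementations rather than
  exact-Bayesian logistic sampling.

Missing cells are initialised by resampling observed values with
replacement; targets are visited in the fixed order *X*, *Y*, *Y′*;
10 cycles per imputation and m = 10 imputations by default (configurable —
the design leaves both free, and these are conventional values for this
class of analysis). Imputation models are main-effects only, deliberately
*not* containing the E·X interaction of the substantive model, reflecting
common practice. Separation, a single observed class, non-convergence, or
coefficient blow-up (|β| > 40) raise an imputation error that callers turn
into a non-convergence flag; nothing is silently repaired. Mean-of-imputed
traces per cycle are kept as a drift diagnostic.

## Strategies (`misim.strategies`)

The substantive model is a logistic fit of *Y* on {*E*, *X*, *E·X*} with
Wald standard errors (on {*E*} alone for H). Strategy mapping:

| id | missing-*Y* rows | imputation targets | predictors of *X* | analysis |
|----|------------------|--------------------|-------------------|----------|
| A  | dropped (with missing-*X*) | — | — | single fit |
| B  | dropped first | *X* | *E* | pooled |
| C  | dropped first | *X* | *E*, *Y* | pooled |
| D  | kept, *Y* imputed | *X*, *Y* | *E*, *Y* | pooled |
| E  | as D, deleted after imputation | *X*, *Y* | *E*, *Y* | pooled |
| F  | dropped first | *X*, *Y′* | *E*, *Y*, *Y′* | pooled |
| G  | kept | *X*, *Y*, *Y′* | *E*, *Y*, *Y′* | pooled |
| H  | kept, *Y* imputed from *E* only | *Y* | — (no *X* anywhere) | pooled, *Y*~*E* |

The secondary outcome participates only in F and G (it is both a predictor
and an imputation target there); A–E and H ignore it. Strategy E pools the
post-deletion fits with the same m (impute, delete, analyse, pool — the
impute-then-delete order of operations). Complete-case status in A
requires observed *X* and *Y* only, since *Y′* is not in the analysis
model. Strategy H's ~−0.41 bias on β₁ is the marginal-versus-conditional
confounding gap, not an estimation failure.

Any imputation or analysis failure yields `converged=False` with a reason;
if some of the m per-imputation fits fail the strategy is flagged and the
surviving fits (≥2) are still pooled for inspection.

## Pooling (`misim.pooling`)

Classical Rubin's rules: pooled estimate = mean; total variance
T = W + (1+1/m)B; df = (m−1)(1 + W/((1+1/m)B))², with B = 0 snapped to
zero against floating-point residue and treated as df = ∞ (normal-based
interval). The Barnard–Rubin small-sample df is available behind a switch
but is not the default: at n ≥ 1000 the difference is negligible.

## Metrics (`misim.metrics`)

Mean bias uses the **truth − estimate** sign convention (so bias +0.1 on a
true log-OR of log 2 means estimates averaged log 1.81; −0.1 means
log 2.21). Mean absolute error, 95%-CI coverage and power (CI excludes 0)
complete the set. Metrics are computed over converged replications only;
`n_converged` and `n_reps` are reported per cell along with a Monte-Carlo
standard error for each metric (sd/√R for the means, binomial for the
proportions). MAE ≥ |bias| holds cell-wise by the triangle inequality and
is asserted in the tests.

## Runner and seeding (`misim.runner`)

Seeds are counter-based: a replication's `SeedSequence` is keyed by
(base seed, mechanism, level, n, replication index), then split into
generation / amputation / imputation substreams, and the imputation stream
further into one substream per strategy. Consequences, all tested: any
cell is recomputable in isolation; results are invariant to the worker
count (`joblib` parallelism) and to which other strategies run in the same
replication; all strategies within a replication see identical data
(paired comparisons, which shrink the Monte-Carlo variance of
between-strategy contrasts). Non-converged strategy runs are kept as
flagged rows, never redrawn — redrawing would condition the retained
samples on convergence and bias them.

## Problem sizes

Default replication counts follow the study design (R = 1000 per
scenario); the bundled checks run reduced but statistically decisive
versions chosen so each Monte-Carlo tolerance is several multiples of the
corresponding MC standard error: calibration on one n = 10⁶ cohort,
complete-case coverage at R = 500 (binomial SE ≈ 0.010), strategy-B bias
at R = 300 (SE ≈ 0.012), strategy-H bias at n = 10⁴, R = 100 (SE ≈ 0.005).

## What the generator does and does not emulate

It reproduces the study conditions exactly: one continuous confounder, one
binary exposure, rare-ish binary outcomes, a single secondary outcome
correlated only through *Y*, and clean logistic missingness with a single
driver per variable. Real cohorts violate most of this — many correlated
covariates with mixed types, missingness driven jointly by several
variables (including the MNAR-on-(Y,E) patterns the design deliberately
excludes), measurement error, and non-logistic outcome processes. Passing
tests therefore certify the machinery and the comparative behaviour of the
strategies under these stylised conditions, not performance guarantees on
any particular real dataset. The MAR design (missingness on exposure only)
also makes complete-case analysis unbiased here, which is not generally
true when missingness depends on the outcome.

## Known limitations

* Binary imputation draws use the asymptotic-normal posterior, so in tiny
  samples the between-imputation variance can be mildly optimistic.
* The continuous-outcome and second-covariate design variants are not
  implemented.
* Perfect-prediction repair (data augmentation) is intentionally absent;
  heavily depleted cells (n = 1000 at 80% missingness) therefore report
  non-convergence for some strategies, which is itself a tracked outcome.
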