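# Methods

## 1. Counterfactual framing

Let S ∈ {no/mild, moderate, severe} be the cognitive-impairment stratum
(BIMS 13–15 / 8–12 / 0–7, with CPS 0–2 / 3–4 / 5–6 as fallback when the
interview is not attempted). For each pain item Y we define the
*counterfactual imputable* Y\*:

- for residents in the no/mild stratum, Y\* equals the documented value;
- for residents in the moderate and severe strata, Y\* is missing by
  construction.

Multiply imputing Y\* conditional on covariates X yields, for each impaired
resident, a draw from the distribution of documented pain among unimpaired
residents with the same covariates. The quantity of interest is the pooled
delta Δ = documented − counterfactual (prevalence difference in percentage
points for binary/categorical items, mean difference for the numeric
rating). A negative Δ means pain would have been documented more often under
unimpaired assessment. The identifying assumption is the usual one for this
design: conditional on X, counterfactual pain is exchangeable across
cognition strata (pain biology does not itself depend on cognition given the
measured covariates).

### Observed-side defaulting

Assessment skip patterns leave detail items (frequency, intensity, effect on
function) blank when the presence item documents no pain. Before any
analysis, blank detail items are defaulted to "no pain"/0 whenever the
resident's own presence item — or, failing that, the staff assessment —
documents no pain. This makes the documented detail-item denominators
include pain-free residents, matching the convention of published assessment
tables, and removes spurious "missingness" that is really structural.

### The combined presence item

`comb_presence` is resident-reported pain presence with staff-observed pain
as fallback for residents unable to self-report (any observed pain behaviour
⇒ 1; staff assessed, no behaviour ⇒ 0; self-report takes precedence when
both exist). Its training sample therefore covers the *unable* residents of
the no/mild stratum — dementia-heavy and functionally dependent — which is
exactly the covariate region the impaired strata extrapolate into. It is the
recommended single imputable for presence-type deltas.

## 2. Imputation model

`fit_fcs` runs chained equations on an `ImputableFrame`. Conditional models:

- **binary** (`logistic`): Bayesian logistic regression. Ridge-stabilised
  IRLS (λ = max(ridge·n, 10⁻⁶)) to the MAP estimate, a coefficient draw
  β̃ ~ N(β̂, H⁻¹) via the Cholesky factor of the inverse Hessian, then
  Bernoulli draws from expit(Xβ̃) (linear predictor clipped at ±30).
- **categorical / binary** (`discriminant`): linear discriminant draws.
  Class means drawn from N(m_k, Σ/n_k), class probabilities from a
  Dirichlet(n_k + ½) posterior, pooled covariance ridge-stabilised;
  posterior class probabilities evaluated at the missing rows and the value
  sampled. As the training sample grows this converges to the Bayes rule
  (verified against the closed-form error rate in the test suite).
- **continuous** (`pmm`, default, or `bayes_linear`): Bayesian linear
  regression, with predictive-mean matching (5 donors) on the posterior-draw
  predictions so imputed values are always observed values.

### Sequential predictors

All imputables are missing *together* in the impaired strata (a block
pattern). With that pattern, the standard "every other variable predicts"
FCS recipe feeds each model the previous cycle's draws of co-missing items,
injecting chain noise that inflates between-imputation variance roughly
tenfold without adding information. We therefore default each imputable's
predictors to the covariates plus only the imputables *earlier in the cycle
order* — the canonical factorisation of the joint for a monotone/block
pattern. The default cycle order places each combined item directly after
its source item, so `comb_presence` conditions on `imp_presence` and the
covariates but not on downstream severity details.

### Logistic vs discriminant

In the training stratum the presence item logically determines the detail
and combined items on no-pain rows (quasi-separation). A logistic
posterior draw is unstable under separation — the Hessian flattens and
coefficient draws explode — while the discriminant draw remains sharp. The
pipeline therefore uses `discriminant` for every binary imputable that
conditions on an earlier imputable, and `logistic` only for the head item
(covariates-only model).

### Blocks and seeding

Assessments arrive in blocks (e.g. facility batches); `per_block_impute`
imputes each block independently. Every block's seed is derived from the
master seed and the block label via a BLAKE2b digest (stable across runs and
insertion order, always < 2³¹) and recorded in the run manifest, so a rerun
of the same configuration reproduces the output bundle byte for byte.
Observed cells are never modified — an invariant asserted in the tests.

## 3. Pooling and bias analysis

Per imputation, per stratum (and optionally per subgroup), the delta is
computed on the rows where the *documented* item has a valid response; the
M deltas are pooled by Rubin's rules: T = W + (1 + 1/M)B, Barnard–Rubin-type
df = (M − 1)(1 + W/((1 + 1/M)B))², with the B → 0 limit treated as a normal
CI. The total-variance identity and the hand-computable df oracle
(e.g. df = 6.125 for W = 0.01, B = 0.01, M = 3) are asserted exactly in the
tests.

Residual-bias bounds per binary delta:

- **E-value**: RR = (observed + |Δ|/100)/observed; E = RR + √(RR(RR − 1)).
  For the severe-stratum headline (observed 34.0%, Δ = −10.2) E = 1.92.
- **Rogan–Gladen correction**: corrected = (apparent + Sp − 1)/(Se + Sp − 1),
  flagged and clamped outside [0, 1].
- **Specificity threshold**: the Sp at which imputation false positives
  alone would explain the gap, Sp = 1 − (apparent − π·Se)/(1 − π); for the
  headline numbers with Se = 0.9 this is 0.794, below the 0.8 typically
  reported for calibrated pain models.

## 4. Synthetic generator and calibration

The generator draws covariates from stratum-specific margins (age, sex,
ADL dependence, arthritis, fracture, dementia, …), then a *shared*
covariate-conditional logistic model for counterfactual pain presence — the
same coefficients in every stratum, so strata differ in true pain only
through covariate mix. Details (frequency, verbal descriptor, numeric
rating, effect on function) follow proportional-odds / truncated-normal
models given presence. Misclassification is layered on top:

- **Inability to self-report**: a logistic model in dementia, age 85+, and
  ADL dependence with per-stratum intercepts; unable residents route to the
  staff channel.
- **Degradation**: a resident with counterfactual pain has the channel
  documented as "no pain" with stratum-specific probability q (one-
  directional; q = 0 in the no/mild stratum).

Calibration solves exactly, over the enumerated covariate cells, for the
pain-model intercept and the dementia and age-85+ coefficients, the
per-stratum inability intercepts, and the inability covariate-coupling
scale, to hit the target counterfactual prevalences among able and unable
residents and the inability rates; the degradation probabilities q then
follow in closed form from the documented-prevalence targets. The resulting
cohort reproduces the emulated admission-cohort margins: documented
resident-reported pain 66.0 / 48.8 / 34.0 % across strata at n = 100,000,
and planted counterfactual gaps of −10.2 (severe) and −4.5 (moderate)
points on the resident channel and −7.2 points on the severe staff channel.

Because the latent truth is retained, the generator supports

- **parameter recovery**: the pipeline recovers the planted deltas to within
  ±1 point (acceptance tests at n = 50,000, M = 10; per-seed Monte-Carlo SD
  ≈ 0.5–0.6 points, so the test averages three a-priori seeds);
- **null calibration**: with misclassification disabled, pooled CIs cover 0
  at the nominal rate (200 replicates at n = 2,000, M = 5).

### Sizing rationale

The headline-target script (`scripts/acceptance.py`) averages six
independent pipeline runs at n = 150,000: the staff-assessed severe subgroup
is only ~3.5% of a cohort, so a single cohort carries ~0.6 points of
sampling noise on the staff delta against a ±1-point tolerance; the average
reduces this to ~0.25. Ten FCS cycles are used there (a single imputable
with fully observed predictors converges in one cycle; the margin is for
safety). Each run takes ~10 s; the script completes in about two minutes.

## 5. Limitations

- The generator's stratum margins are independent within stratum (age × ADL
  × comorbidity interactions are not modelled), and some channel margins are
  renormalised to keep the inability and prevalence targets mutually
  consistent; cell-level joint distributions should not be over-interpreted.
- The moderate-stratum staff channel is calibrated through the shared pain
  model rather than to an independent target; its planted delta (≈ −9.6
  points) is steeper than the resident-channel moderate gap, and the
  no/mild staff-channel documented prevalence (~66%) sits above what a
  staff-only instrument would typically record, because the no/mild channel
  carries no degradation by construction.
- E-values and QBA bounds address unmeasured confounding and imputation
  misclassification separately; they do not compose into a joint bound.
- The exchangeability assumption is untestable from the data alone: if
  cognitive impairment suppresses pain biology itself (rather than its
  documentation), part of the delta is causal rather than misclassification.
- Recovery tolerances are Monte-Carlo-limited: single-seed runs at the
  acceptance sizes can miss the ±1-point window by chance (measured
  ~10–20% depending on the target), which is why the acceptance tests and
  the target script average independent seeds.
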