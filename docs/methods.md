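# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and the limits of what the tests establish.

## Estimands and estimator

The causal estimands are the marginal counterfactual prescribing
probabilities psi1 = E[Y(1)] and psi0 = E[Y(0)] over the episode
population, their difference (ATE), and the marginal odds ratio
OR = [psi1/(1-psi1)]/[psi0/(1-psi0)]. Identification assumes consistency /
no interference, exchangeability given the covariate set W, and positivity;
the package diagnoses the latter two (SMD balance tables with a 10%
noteworthy-imbalance threshold; propensity extremes) but cannot verify
exchangeability, which in the synthetic studies is true by construction
whenever the generator's shared practice random effect is absent from the
mode model.

TMLE proceeds in the standard way for a binary outcome: initial estimates
Q0(A, W) and g(W), a one-dimensional fluctuation with the signed clever
covariate H = A/g - (1-A)/(1-g) solved by Newton iteration on the score
(tolerance 1e-10, damped steps; non-convergence raises), plug-in targeted
means, and influence-curve inference:

    D1 = (A/g)(Y - Q*) + Q*_1 - psi1
    D0 = ((1-A)/(1-g))(Y - Q*) + Q*_0 - psi0
    D_ate = D1 - D0,  D_logOR = D1/[psi1(1-psi1)] - D0/[psi0(1-psi0)]

SE(theta) = sd(D_theta)/sqrt(n); 95% CIs use the 1.96 normal quantile, with
OR intervals formed on the log scale (delta method) and exponentiated, so
they are always positive and bracket the estimate. A practice-cluster
variance option sums influence-curve contributions within practice before
taking the variance; the default is the individual-level SE. The default fluctuation is the
one-dimensional submodel with the signed clever covariate; a per-arm
weighted intercept update (weights 1/g and 1/(1-g)) is available behind
the ``fluctuation="weighted"`` flag and solves the same score system —
the two agree closely at the scales exercised here.

Propensity scores are clipped to [0.005, 0.995] before the clever
covariate is formed. The bounds are deliberately loose — the positivity
report surfaces raw extremes rather than hiding them behind truncation —
and configurable. All probabilities are clipped to [1e-6, 1 - 1e-6]
before any logit transform.

## Superlearner

Both nuisance models use the same covariate set (the outcome model
additionally takes A) and the same fold structure: K = 10 folds assigned at
the practice level, so no practice is ever split across training and
validation, which respects intra-practice correlation. Outcome
stratification under clustering is done by sorting practices by outcome
prevalence, dealing them serpentine-style to folds, then rebalancing sizes
with moves that do not worsen the spread of fold prevalences. Patient-level
clustering is automatically nested because each patient belongs to exactly
one practice.

The metalearner is non-negative least squares on the out-of-fold prediction
matrix, normalized to sum to one (uniform fallback with a warning if the
solution is identically zero); the un-normalized solution is retained
because NNLS optimality statements hold for it exactly. A discrete
metalearner (all weight on the single best cross-validated learner) is
available for testing. A learner that fails on any fold is dropped entirely
with a warning.

The full library holds six families: plain logistic regression, additive
B-spline logistic regression (a generalised-additive-model surrogate),
random forest, histogram gradient boosting, an adaptive-splines learner
(B-spline basis expansion pruned by L1-penalised logistic regression), and
lasso logistic regression. Hyperparameters follow library conventions and
are exposed through the learner specs. A `fast` profile (logistic + lasso +
shallow gradient boosting) is used for simulation studies where hundreds of
full fits are needed.

## Synthetic data-generating process

Everything is driven by one structural model on the logit scale. For each
ARI index consultation, P(A=1|W) and P(Y=1|A,W) are logistic in a named
feature map: standardized age, child indicator (age < 16), sex, centred IMD
quintile, ethnicity-missing indicator, comorbidity flags, infection-subtype
indicators, centred regional COVID prevalence, and a latent practice-level
random effect shared by both models. Coefficients are free config
parameters; the defaults give remote consulting odds that rise for
URTI/sinusitis and adults and fall for otitis media, and prescribing odds
dominated by LRTI and otitis media — the qualitative pattern of real ARI
care — with a conditional treatment effect of 0.25 on the log-odds scale.

Covariate law: ~30% of patients are children (ages uniform 0.5–16; adults
uniform 16–88), sex balanced, IMD uniform over quintiles, ethnicity
categorical with an explicit missing level, comorbidity prevalences by
stratum. Each patient's ARI episode count is Poisson and independent of
covariates, so the episode-level covariate law equals the patient law plus
independent episode draws — this is what lets the Monte-Carlo truth oracle
(`true_marginal_effects`) draw from the same law directly and evaluate both
potential-outcome probabilities per draw. The regional prevalence series is
a deterministic weekly sinusoid (region-specific phase and level) so the
oracle can reproduce the carried-forward covariate exactly.

Realism features, each with a configurable rate: repeat same-episode
consultations within the 7-day window, mixed episodes (one opposite-mode
contact), `unknown` mode markers (classified as face-to-face downstream,
i.e. exposure misclassification), background non-ARI consultations and
pre-window antibiotic prescriptions (which feed the lookback and
practice-rate covariates), pre-window GP ARI history (kept at least 8 days
clear of the analysis window so it cannot chain into an in-window episode),
and small fractions of unrecorded sex / missing IMD. 365 days of pre-window
history are always generated so lookback covariates are computable at every
index date. All randomness flows from the root seed through named
`SeedSequence` spawns, one stream per generation stage; identical configs
give byte-identical tables.

What the generator does **not** emulate: free-text or codelist-level
clinical realism, calendar seasonality of ARI incidence, informative
registration churn, practice-level coding-quality differences, or any
attempt to match real marginal distributions numerically. Passing tests
therefore show that the estimator recovers a known truth under the stated
structural assumptions — not that it would be unbiased against violations
the generator does not produce (notably unmeasured confounding).

## Study designs used by the validation suite

- **Calibration design** (`calibration_config`): adult-only, no unknown or
  mixed modes, practice random effect in the outcome model only (sd 0.25),
  treatment coefficient 0.27052 — solved once by bisection against the
  truth oracle so the true marginal OR is 1.25 (true ATE ~0.0557). The
  random effect is excluded from the mode model deliberately: a calibration
  study must have an identified estimand, and a latent effect in both
  models would be unmeasured confounding that no estimator could remove.
- **Confounded null** (`confounded_null_config`): the same design with the
  treatment coefficient set to zero; shared covariates make the crude arm
  difference nonzero while the true ATE is exactly zero.
- **Double-robustness design** (`dr_config`): no random effect, strong
  shared coefficients (crude confounding bias ~0.2), sampled directly from
  the structural model; the correct parametric propensity model is then a
  logistic regression on the true features.

Problem sizes (chosen as a sensible simulation budget): coverage uses 200
generate-and-analyze replicates at ~2,000 episodes with the fast profile
and K = 10; parameter recovery one run at ~20,000 episodes; double
robustness one draw of 50,000 structural episodes with parametric nuisance
fits (misspecified = intercept-only / constant).

## Cohort and covariate conventions

- Episode grouping is **anchored**: a consultation joins an episode iff
  (date - index_date) < 7 days, so an episode spans at most 7 calendar
  days; a rolling-chain scheme is available (`scheme="rolling"`). Same-day
  records always share an episode.
- Unknown mode markers resolve to face-to-face at the record level; an
  episode is `mixed` iff both classified modes occur, and mixed episodes
  are analysed in arm 0 (a `drop_mixed` flag reruns without them).
- Child/adult boundary: child iff age at index < 16 years; age is kept
  fractional as a covariate.
- Y = 1 if any antibiotic prescription links by consultation ID to any
  grouped consultation, or shares a date with one.
- Lookback windows are half-open [index - w, index) for w in {7, 30, 365}
  days: the index consultation and same-day events never count themselves.
  The grid covers all/remote/face-to-face consultations, ARI consultations
  by mode, antibiotic prescriptions, and recorded-COVID flags (all three
  windows are emitted for the COVID flags).
- Practice rates are events per 10,000 registered patient-days over the 365
  days before the index, for antibiotic prescriptions and all
  consultations; zero patient-days is an error.
- The prevalence join is last-observation-carried-forward at weekly
  granularity; a region missing from the series is an error, never an
  imputation.
- Categorical encoding is one-hot against recorded reference levels with
  ethnicity missingness as an explicit level; nothing is imputed. Children
  carry a reduced comorbidity column set (asthma, skin condition).

## Degenerate inputs and tie-breaks

Zero pooled variance with unequal means makes the SMD infinite with a
warning; group counts below 10 suppress formatted summary cells without
altering the underlying numbers. A propensity at 0 or 1 is an error
upstream of the clever covariate. An all-zero NNLS solution falls back to
uniform weights with a warning. Empty cohort input yields empty output
rather than an error; a stratum with a single exposure arm is an error.

## Known limitations

- No CV-TMLE variant: initial estimates are full-data superlearner refits,
  as in the standard (non-cross-validated) TMLE template.
- Individual-level influence-curve SEs ignore residual within-practice
  correlation not captured by W; the cluster-robust option is provided but
  unvalidated against a gold standard.
- The generator's age-at-index drifts up to ~6 months from the age law used
  by the truth oracle (ages are anchored at the window midpoint); the
  induced truth error is negligible relative to Monte-Carlo error at the
  scales used.
- Exposure misclassification from unknown/mixed modes shifts the estimand
  away from the generator truth; calibration designs therefore switch those
  features off, and runs with them on should be read as descriptive.
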