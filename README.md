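# teletmle

Targeted maximum likelihood estimation (TMLE) of the causal effect of
consultation mode — remote versus face-to-face — on antibiotic prescribing
for acute respiratory infections (ARIs) in English primary care, packaged
as a tested, reusable analysis pipeline with a synthetic electronic
health-record (EHR) generator that knows its own ground truth.

## Who this is for

Epidemiologists and biostatisticians who want to (a) run the full
consultation-episode analysis — cohort construction, covariate engineering,
balance and positivity diagnostics, a practice-clustered cross-validated
superlearner, and doubly robust TMLE inference — on event-level primary-care
tables, and (b) validate that estimator end to end on synthetic data whose
true effect is known by construction. Real patient-level sources (such as
CPRD Aurum) are access-restricted, so the package ships a structural
generator that emulates their shape: patients nested in practices, repeated
consultations, ARI subtype codes (LRTI, URTI, sinusitis, otitis externa,
otitis media, COVID), remote / face-to-face / unknown mode markers,
confounded mode assignment, and a binary prescribing outcome.

## The model

The analysis unit is the **episode**: a patient's GP ARI consultations
within a 7-day period, grouped to the date of the first contact. The
exposure is A = 1 for a fully remote episode and A = 0 for face-to-face or
mixed episodes; the outcome Y = 1 if any antibiotic prescription links to
any grouped consultation (by linkage ID or same-date issue). With covariates
W (patient, clinician, practice, temporal), TMLE estimates the
counterfactual prescribing probabilities

    psi_a = E[ E(Y | A = a, W) ],   a in {0, 1}

via an initial superlearner fit Q0(A, W) = E[Y | A, W] and propensity
g(W) = P(A = 1 | W), fluctuated along the one-parameter submodel

    logit Q*(A, W) = logit Q0(A, W) + eps * H(A, W),
    H(A, W) = A / g(W) - (1 - A) / (1 - g(W)),

so that the efficient influence-function equation
(1/n) sum H_i (Y_i - Q*_i) = 0 holds. The targets are the average treatment
effect ATE = psi1 - psi0 and the marginal odds ratio
OR = [psi1 / (1 - psi1)] / [psi0 / (1 - psi0)], with standard errors from
the empirical influence curves and OR inference on the log scale.

Nuisance models are stacked with a superlearner: 10-fold cross-validation
clustered by GP practice (whole practices share a fold) and stratified by
the outcome, six learner families (logistic, additive splines, random
forest, gradient boosting, L1-pruned adaptive splines, lasso logistic), and
a non-negative least squares metalearner on the out-of-fold predictions.

## Worked example

```bash
teletmle run-all --out runs/demo --seed 5
```

runs the bundled demo generator (30 practices, 4,500 patients, ~1,150
eligible episodes) through the whole pipeline and prints:

```
[adult] n=810: 47.9% (95% CI: 43.5, 52.3) would have been prescribed antibiotics if all seen face-to-face vs 50.5% (95% CI: 46.4, 54.6) if seen remotely; ATE 2.6% (95% CI: -2.8, 8.0); OR 1.11 (95% CI: 0.89, 1.38).
[adult] propensity extremes: min 0.164, max 0.914.
[child] n=343: 35.9% (95% CI: 30.3, 41.5) would have been prescribed antibiotics if all seen face-to-face vs 39.5% (95% CI: 32.7, 46.2) if seen remotely; ATE 3.5% (95% CI: -4.0, 11.1); OR 1.16 (95% CI: 0.84, 1.60).
[child] propensity extremes: min 0.013, max 0.873.
```

Reading this: the two percentages per stratum are the targeted
counterfactual prescribing probabilities if every episode had been
face-to-face (psi0) or remote (psi1); their difference is the ATE and the
odds formed from them give the marginal OR. At this demo scale the
confidence intervals are wide; the run directory also contains the
episode table, attrition flow, covariate matrix and schema, the
standardized-mean-difference balance table, the positivity report, and a
JSON estimates file, and `truth.json` records the generator's true marginal
effects for comparison.

The same steps are available as library calls
(`generate_study`, `build_cohort`, `build_covariate_matrix`, `run_tmle`,
`simulate_calibration`) — see the module docstrings.

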