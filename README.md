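# rlderiv

Simulation and analysis tools for a question at the heart of
individual-differences ("computational psychiatry") model-based fMRI: **when a
GLM couples a Rescorla–Wagner reward-prediction-error (RPE) regressor to
neural data, what do individual differences in the fitted beta actually
reflect?**

The Rescorla–Wagner model has two parameters that shape the learning curve:

    RPE_t  = λ · outcome_t − Q_t
    Q_t+1  = Q_t + α · RPE_t

α (learning rate) sets how fast values approach asymptote; λ (reinforcement
efficacy) sets the asymptote itself, and hence the amplitude of elicited
RPEs. Simulations with this package show that the conventional RPE-modulator
beta tracks λ far more than α — and that adding the **gradient of the RPE
series over trials as a second regressor** yields a derivative beta that
tracks α specifically, giving each parameter its own neural readout.

The package provides, as library modules:

* `rl_core` — Rescorla–Wagner agents (Pavlovian and softmax-instrumental)
  with separable α and λ;
* `paradigms` — drifting-probability reward schedules and uniform sampling of
  per-participant generative parameters;
* `design_regressors` — event embedding on the 2-s sampling grid, model RPE
  regressors, the gradient and high/low derivative constructions,
  normalization;
* `bold_sim` — canonical (SPM double-gamma) HRF convolution, 1/f^a noise,
  SNR mixing into synthetic BOLD;
* `glm_fit` — subject-level OLS and exact-ML regression with AR(2) errors,
  BIC model comparison;
* `group_stats` — group regressions, (partial) correlations, d = 2r/√(1−r²),
  dependent-correlation z tests, ICC(3,1), BIC-preference logistic regression;
* `experiments` — the end-to-end simulation campaigns, plus a thin `rlderiv`
  CLI over them.

See `docs/methods.md` for the modeling conventions and their rationale.

## A worked example

`examples/double_dissociation.py` simulates 800 participants with α ~
U(0.2, 0.7), λ ~ U(0.75, 1.25) and drifting reward schedules, fits each
participant's noiseless RPE event series with an RPE (analysis α = 0.45) +
gradient-derivative GLM, then regresses each fitted beta on the generative
parameters:

```
predicting the rpe beta across participants:
predictor  coef      t    p  df
      lam  0.17  48.77 0.0 796
    alpha  0.04   9.92 0.0 796
    drift -0.02  -4.62 0.0 796

predicting the deriv beta across participants:
predictor  coef      t    p  df
      lam  0.00   2.66 0.01 796
    alpha  0.12 158.96 0.00 796
    drift -0.00  -1.73 0.08 796
```

The double dissociation is the headline: λ dominates the RPE beta
(t ≈ 49 vs ≈ 10 for α), while α dominates the derivative beta (t ≈ 159 vs
≈ 3 for λ). `examples/fmri_effect_sizes.py` repeats this under fMRI-like
conditions (HRF, 1/f noise, AR(2) fits) and prints duration-dependent effect
sizes, e.g. at 400 participants:

```
25 trials:  d(lambda <-> rpe beta) = 0.41   d(alpha <-> deriv beta) = 0.32
100 trials: d(lambda <-> rpe beta) = 1.07   d(alpha <-> deriv beta) = 0.98
```

— small-to-medium couplings at short runs that grow large with task duration.
`examples/test_retest_reliability.py` and `examples/toy_trajectories.py`
cover the reliability analysis and the 20-trial toy illustration. The same
campaigns are scriptable, e.g.:

```bash
rlderiv run fmri_durations --seed 3 --scale 0.1 --out out/
rlderiv fig1
```

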