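# Methods

`rlderiv` simulates and analyzes individual differences in reward prediction
error (RPE) signals as they would appear in model-based fMRI. This note
documents the model, the simulation conventions, the numerical choices, and
what the synthetic data do and do not capture.

## The learning model

Agents learn a scalar stimulus value Q by the Rescorla–Wagner rule with an
explicit reinforcement-efficacy parameter:

    RPE_t  = λ · outcome_t − Q_t
    Q_t+1  = Q_t + α · RPE_t

with binary outcomes (1 win / 0 no-win) and Q initialized at 0.5.

* **α (learning rate)**, dimensionless in [0, 1]; simulated range U(0.2, 0.7).
  Controls the *rate* of approach to asymptote — the shape of the learning
  curve. Below ~0.1 the RPE series is nearly collinear with the raw outcome
  series; above ~0.8 behavior approaches win-stay/lose-shift.
* **λ (reinforcement efficacy)**, positive; simulated range U(0.75, 1.25).
  Sets the asymptote and hence the *amplitude* of elicited RPEs. With Q₀
  fixed at 0.5 the RPE series is affine (asymptotically proportional) in λ.
* **Θ (inverse temperature)**, U(0, 5), softmax choice concentration in the
  two-option (instrumental) paradigm. Softmax probabilities are computed via
  the logistic of the scaled value difference, so large Θ·Q is exact.

In the instrumental agent only the chosen option's value is updated; the
unchosen value carries forward unchanged, and the trial's "neural" RPE is the
chosen option's prediction error. This is the most common convention; nothing
downstream depends on it strongly because the instrumental paradigm is only a
confirmation arm.

## Paradigms

A single cue (or two independent cues) is rewarded with probability 0.5 on
trial 1; the probability then follows a Gaussian random walk,
p[t+1] = clip(p[t] + drift·ε, 0, 1), ε ~ N(0, 1), with per-participant drift
rate U(0, 0.4). Clipping (rather than reflection) is used at the bounds; with
large drift rates the walk consequently spends time pinned at 0 or 1,
producing deterministic outcome stretches. This is one of several undetermined
conventions of the original design (see "Known limitations").

Outcome events occur every 14 s (ISI) and the signal is sampled every 2 s, so
a trial occupies 7 samples and a 200-trial run has 1400 samples. Trial t's
event amplitude sits at sample 7t; all other samples are exactly zero. Any
constant offset of event timing is equivalent under the GLM, so the simplest
convention is locked and tested.

## Regressors

The analysis-side RPE regressor uses λ = 1 and either a fixed learning rate
(0.2 for the baseline analyses, 0.45 for all derivative analyses) or a
per-participant estimate (truth + U(−e, e), e ∈ {0.05, 0.1}, clipped to
(0, 1]).

Two constructions capture the learning-curve-shape variance that a
mis-specified learning rate leaves behind:

* **gradient method** — the numerical gradient of the trial-level RPE values
  (central differences, one-sided at the ends). The gradient is computed on
  trial values *then* embedded on the sampling grid; the reverse order would
  differentiate the zero-padding instead of the learning curve, and is locked
  out by test.
* **high/low method** — mean and difference of the RPE series generated with
  α = 0.7 and α = 0.2; the difference is residualized on the mean (ordinary
  least squares with intercept) at the embedded-timeseries level, making the
  two regressors exactly orthogonal. Software-specific orthogonalization
  dialects are deliberately not modeled.

All parametric regressors are normalized to mean 0, SD 1 (population, 1/N
convention, for bit-reproducibility) before entering a GLM; in the fMRI-like
analyses they are HRF-convolved first and normalized after. The noiseless
ground-truth (dependent) series is *not* normalized: the association
structure of the betas is invariant to a per-participant rescaling of y, and
leaving y raw preserves λ's amplitude semantics.

## Synthetic BOLD

The ground-truth neural series (true-parameter RPE impulses on the grid) is
convolved with the canonical double-gamma HRF (response gamma delay 6 s,
undershoot delay 16 s, dispersions 1, undershoot ratio 1/6, 32 s support),
sampled on the acquisition grid. The kernel keeps SPM's native scaling — the
sampled kernel sums to 1 (peak ≈ 0.43 at dt = 2 s), which is exactly what
MATLAB's `spm_hrf(RT)` and nilearn's `spm_hrf` return. A per-subject HRF
amplitude multiplier (fixed 1, or U(0.5, 1.5) in the HRF-scaling analysis)
scales the kernel. Convolution is leading-aligned and truncated to the run
length; early-trial responses are partially represented exactly as in
standard GLM practice.

Noise is 1/f^a ("pink-like") Gaussian noise synthesized in the frequency
domain (complex Gaussian coefficients with amplitude f^(−a/2), DC bin zeroed)
and z-transformed to exactly mean 0 / SD 1 per run; a varies U(0.8, 1.2)
across participants. The noisy run is

    bold = √sn · signal + √(1 − sn) · noise,   sn = SNR / (1 + SNR)

with SNR ~ U(2, 4), so sn ∈ [0.667, 0.8]. sn is a *variance share*
(sn + (1 − sn) = 1), hence its square roots on the amplitude scale; with a
unit-variance signal the mixture would have unit variance. The convolved
signal is deliberately not re-standardized before mixing — λ and the HRF
scale must survive into the BOLD amplitude, which is the entire mechanism
coupling λ to the fitted RPE beta. This amplitude convention (SPM-native
kernel, sd-scale mixing) is the one under which the package's simulations
reproduce the published effect-size battery; the peak-normalized-kernel and
linear-weight alternatives produce effect sizes 2–3x too large at every task
duration and were rejected on that evidence.

## Subject-level GLMs

* Noiseless analyses: ordinary least squares with intercept (plus the RPE and,
  where applicable, derivative/outcome regressors).
* fMRI-like analyses: regression with AR(2) errors fit by exact Gaussian
  maximum likelihood — intercept, standardized linear trend, RPE, and
  (optionally) derivative regressors. The likelihood uses the stationary
  initial-condition Cholesky factor for the first two observations and
  quasi-differencing thereafter, profiled over the two AR partial
  autocorrelations (tanh-parameterized, hence automatically stationary) with
  Nelder–Mead (xatol 1e-5). Start values come from Yule–Walker on the OLS
  residuals; a failed fit is retried from the white-noise start and flagged if
  still unconverged (excluded from group analyses with a logged count;
  in practice exclusions are ~0 at the run lengths used). The implementation
  agrees with statsmodels SARIMAX (the same model) to ~1e-3 in log-likelihood
  in tests, and is ~25x faster, which is what makes 10,000+ fits per campaign
  feasible.

BIC is −2·loglik + k·ln(n) with k = regression coefficients (incl.
intercept) + AR coefficients + 1 for the innovation variance. k cancels in
all nested comparisons except the derivative column, so preference rates are
insensitive to the counting convention.

## Group statistics

Multiple regression t-values (statsmodels OLS) relate each beta to the
generative parameters. Effect sizes use d = 2r/√(1−r²). Dependent overlapping
correlations are compared with the Dunn–Clark z using the Hittner–May–Silver
back-transformed-mean-r covariance term (Steiger's 1980 variant is available
behind a flag). Partial correlations use double residualization (equivalent
to the recursive formula; asserted against pingouin in tests). Test–retest
reliability is Shrout–Fleiss ICC(3,1) — two-way mixed, consistency, single
measure — with the F-based 95% CI. The BIC-preference logistic regression
z-scores all main effects first and forms the |α−0.45| × SNR and
|α−0.45| × noise-exponent interactions as products of the z-scored mains
(the alternative — z-scoring the products — changes nothing qualitatively);
inference is by Wald z.

## Campaign problem sizes

Default campaigns use 5,000 participants per cell, as in the validation study.
The acceptance script (`scripts/acceptance.py`) fixes smaller sizes a priori
for the AR(2)-heavy cells — 1,000 participants for the 100-trial test–retest,
200/400-trial BIC, and 400-trial correlation cells; 5,000 for the cheap
25-trial and noiseless cells — trading Monte-Carlo error (~1/√n) for a
few-minute run. The half-sample invariance of the group statistics (point
estimates move by < 2 MC standard errors when n is halved) is what licenses
this.

## What the generator does and does not emulate

The synthetic data reproduce: trial-locked RPE responses with realistic
hemodynamics, 1/f-distributed noise with subject-varying autocorrelation and
SNR, subject-varying response amplitude (λ, HRF scale), and finite-length
runs. They do not include: visual/anticipatory/motor components (assumed
perfectly modeled out), scanner drifts beyond the 1/f model (assumed removed
by high-pass filtering), nonlinear or adaptive RPE coding (range adaptation,
asymmetric "dips"), uncertainty-modulated learning rates, volumetric
structure or voxel selection effects, and behavioral mis-specification of the
agent itself. Passing tests therefore demonstrate properties of the *method*
under the stated generative assumptions, not performance on real fMRI data.

## Known limitations

* Several conventions of the original design are undetermined (walk boundary
  handling, absolute signal scaling); the package locks the choices described
  above. Under them, the fMRI-like battery (effect sizes across durations,
  dependent-correlation contrasts, HRF-scaling recovery, reliability pattern)
  reproduces well, while the noiseless single-regressor baseline shows the
  right lambda-dominance qualitatively but with a smaller t-ratio than the
  published value, and the drift rate shows a small negative association with
  the RPE beta (a consequence of clipping: high-drift schedules spend trials
  at deterministic probabilities, compressing both the true and modeled
  RPEs). Test-retest ICCs come out ~0.05–0.10 above, and BIC preference rates
  ~1–3 percentage points below, the published values; these residuals pull in
  opposite directions, so they reflect an unmodeled structural detail rather
  than an amplitude miscalibration.
* The AR(2) error model is correctly specified for the generator only
  approximately (1/f noise is not an AR(2) process); this mirrors the original
  analysis choice and is part of what the simulations test.
* Probability walks with large drift are clipped, not reflected; outcome
  statistics near the bounds depend on this choice.
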