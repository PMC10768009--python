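"""Effect sizes under fMRI-like noise, and how task duration changes them.

Simulates noisy BOLD runs (HRF-convolved RPE responses + 1/f noise, SNR 2-4),
fits each participant with an AR(2)-error GLM (RPE + derivative + trend), and
reports the correlation-based effect sizes d = 2r/sqrt(1-r^2) linking the
generative parameters to the fitted betas at 25 vs 100 trials.
"""

from rlderiv import CampaignConfig, run_fmri

res = run_fmri(
    CampaignConfig(
        campaign="fmri_durations",
        n_participants=400,
        durations=(25, 100),
        master_seed=21,
    )
)
for duration in (25, 100):
    s = res[duration]["stats"]
    print(f"\n{duration} trials (n={s['n']}):")
    print(f"  d(lambda <-> rpe beta)      = {s['d']['lam_rpe']:.2f}")
    print(f"  d(alpha  <-> deriv beta)    = {s['d']['alpha_deriv']:.2f}")
    print(f"  z(lambda/rpe vs alpha/rpe)  = {s['z']['lam_vs_alpha_rpe']:.2f}")
print(
    "\nReading: both couplings strengthen with duration; even at 25 trials the"
    "\nlambda-RPE coupling exceeds the alpha-RPE coupling (positive z)."
)
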