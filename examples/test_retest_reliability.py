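"""Test-retest reliability of the RPE and derivative betas.

Each simulated participant runs two independent 100-trial blocks with
identical generative parameters; the AR(2) GLM is fit per block and ICC(3,1)
measures how consistently the betas rank participants across blocks. Despite
perfectly stable parameters, schedule randomness and scanner-like noise push
the ICCs into the 'poor' range - a caution for individual-differences fMRI.
"""

from rlderiv import CampaignConfig, run_test_retest

res = run_test_retest(
    CampaignConfig(campaign="test_retest", n_participants=300, n_trials=100, master_seed=31)
)
for name, (icc, (lo, hi)) in res["icc"].items():
    print(f"ICC(3,1) {name:18s} = {icc:5.2f}  [95% CI {lo:.2f}, {hi:.2f}]")
print(
    "\nReading: reliabilities sit far below the ~0.9 needed for psychometrics"
    "\neven though the generative parameters repeat exactly across blocks;"
    "\nomitting the derivative column barely changes the RPE beta's ICC."
)
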