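"""The core dissociation: lambda loads on the RPE beta, alpha on the
derivative beta.

Simulates 800 participants with individually varying learning rate (alpha),
reinforcement efficacy (lambda) and schedule drift; fits each participant's
noiseless RPE event series with an RPE (alpha=0.45) + gradient-derivative GLM;
then regresses each fitted beta on the generative parameters. Large |t| means
the parameter drives that beta.
"""

from rlderiv import CampaignConfig, run_derivative

res = run_derivative(
    CampaignConfig(campaign="derivative_gradient", n_participants=800, master_seed=11)
)
for beta_name in ("rpe", "deriv"):
    print(f"\npredicting the {beta_name} beta across participants:")
    print(res["group"][beta_name].round(2).to_string(index=False))
print(
    "\nReading: t(lambda -> rpe beta) is large while t(lambda -> deriv beta) ~ 0,"
    "\nand t(alpha -> deriv beta) is large: the derivative isolates the learning rate."
)
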