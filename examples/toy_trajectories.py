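"""The 20-trial toy experiment: how the learning rate shapes RPEs.

Nine unrewarded trials followed by eleven rewarded ones. Fast learners
(alpha 0.7) extinguish and re-acquire quickly, so their RPEs collapse toward
zero within a few trials; slow learners (alpha 0.2) keep producing sizable
RPEs. Adding/subtracting the gradient of the intermediate (alpha 0.45) RPE
curve reconstructs the fast/slow curves - the idea behind the derivative
regressor.
"""

from rlderiv import make_fig1_fixture

fixture = make_fig1_fixture()
print(fixture["trajectories"].round(4).to_string(index=False))
print()
rc = fixture["reconstructions"]
keep = rc["trial"] != 9  # the central difference straddles the block boundary
r_fast = rc.loc[keep, "rpe_plus_gradient"].corr(rc.loc[keep, "rpe_alpha_0.7"])
r_slow = rc.loc[keep, "rpe_minus_gradient"].corr(rc.loc[keep, "rpe_alpha_0.2"])
print(f"corr(rpe(0.45) + gradient, rpe(0.70)) = {r_fast:.3f}")
print(f"corr(rpe(0.45) - gradient, rpe(0.20)) = {r_slow:.3f}")
print("(> 0.9 means the gradient spans the learning-rate direction)")
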