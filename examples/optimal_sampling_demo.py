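"""Optimal number of samples under the trial economy.

For an exponentially decaying EE curve, computes the expected value
EV(s) = R0 - s*eta_s - EE(s)*eta_e at both sampling-cost levels and finds
the sample count s* that maximizes it.
"""

from circlequest import TrialEconomics, expected_value_curve, extraction_curve, optimal_samples

ee_curve = extraction_curve(ee_start=87.0, alpha=0.35, ee_inf=8.0, n_points=25)

for eta_s, label in [(1.0, "low cost"), (5.0, "high cost")]:
    econ = TrialEconomics(initial_reserve=130, sampling_cost=eta_s)
    ev = expected_value_curve(econ, ee_curve)
    s_star = optimal_samples(ev)
    print(f"{label} (eta_s={eta_s}): s* = {s_star}, EV(s*) = {ev[s_star]:.1f} credits")
# Raising the sampling cost moves the EV peak earlier: information is worth
# buying only while each sample's expected error reduction (times the
# 1.2 credit/px error cost) exceeds its price.
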