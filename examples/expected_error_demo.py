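"""Expected error (EE) of a dot configuration.

Builds an 8-dot stimulus (4 inside, 4 outside the hidden circle) for a
mid-range uncertainty band, then recomputes its EE from the dots alone by
folding them through the ideal-observer posterior.
"""

from circlequest import SearchSpace, ee, posterior_from_observations
from circlequest.schedules import EXP2_EE_BANDS, generate_passive_stimulus

space = SearchSpace()  # 1280 x 715 px, circle radius 130 px
band = EXP2_EE_BANDS[2]  # 57.5-58.9 px
stim = generate_passive_stimulus(space, band, seed=1)

belief = posterior_from_observations(space, stim.dots)
est = ee(belief)

print(f"requested EE band: {band[0]}-{band[1]} px")
print(f"recomputed EE:     {est.ee:.2f} px")
print(f"best placement:    ({est.centroid[0]:.1f}, {est.centroid[1]:.1f})")
print(f"candidate centers: {est.support_size}")
# EE is the posterior-weighted mean distance between the best placement
# (the posterior centroid) and the circle center; the candidate count is
# the number of grid centers still consistent with every dot.
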