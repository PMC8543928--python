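"""Robustness of a significant result to contrary evidence.

The published HR 0.13 (0.06, 0.30) is strongly significant. How extreme
would a contrary replication have to be to destroy its credibility?
"""

from bae import (
    Direction,
    EffectEstimate,
    Scale,
    Scenario,
    tipping_point,
    to_additive,
)

obs = to_additive(EffectEstimate(
    point=0.13, ci_lower=0.06, ci_upper=0.30, scale=Scale.HAZARD_RATIO
))
res = tipping_point(
    obs,
    direction=Direction.LESS_THAN_NULL,
    scenario=Scenario.OPPOSING,  # initial result is significant
)
print(f"opposing tipping point: HR {res.mu_star_reported:.2f} "
      f"(log scale {res.mu_star_additive:.4f})")

# A same-precision replication would have to observe a hazard ratio at or
# above this value — i.e. in the harmful direction — before the combined
# 95% credible interval reaches the null. The farther this sits beyond
# the null, the more robust the original finding.
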