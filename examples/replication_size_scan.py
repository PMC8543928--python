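"""How the required replication evidence shrinks with study size.

The sqrt(X) heuristic: a replication with X times more subjects observes
a standard error of SE/sqrt(X). Larger hypothetical studies carry more
weight in the posterior, so a less extreme result suffices to tip the
combined evidence into credibility.
"""

from bae import (
    Direction,
    EffectEstimate,
    Scale,
    Scenario,
    scale_prior_se,
    tipping_point,
    to_additive,
)

obs = to_additive(EffectEstimate(
    point=0.42, ci_lower=0.14, ci_upper=1.23, scale=Scale.HAZARD_RATIO
))

print("size multiplier X   replication SE   tipping point (HR)")
for x in (1, 2, 4, 9):
    prior_s = scale_prior_se(obs.se, x)
    res = tipping_point(
        obs,
        prior_s=prior_s,
        direction=Direction.LESS_THAN_NULL,
        scenario=Scenario.SUPPORTIVE,
    )
    print(f"{x:>17}   {prior_s:>14.4f}   {res.mu_star_reported:>18.2f}")

# The tipping point climbs toward the null HR of 1 as X grows: a bigger
# replication study needs to observe a less dramatic effect.
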