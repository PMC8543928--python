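"""Tipping-point analysis of a non-significant hazard ratio.

A small comparative-effectiveness cohort gives HR 0.42 with 95% CI
(0.14, 1.23) — not significant. How strong would a same-precision
replication have to be for the combined evidence to become credible?
"""

from bae import Direction, EffectEstimate, Scale, Scenario, tipping_point, to_additive

est = EffectEstimate(
    point=0.42, ci_lower=0.14, ci_upper=1.23, scale=Scale.HAZARD_RATIO
)
obs = to_additive(est)
print(f"log-scale estimate: beta = {obs.beta_hat:.4f}, SE = {obs.se:.4f}")

res = tipping_point(
    obs,
    direction=Direction.LESS_THAN_NULL,  # benefit means HR < 1
    scenario=Scenario.SUPPORTIVE,        # initial result is non-significant
)
print(f"tipping point: HR {res.mu_star_reported:.2f} "
      f"(log scale {res.mu_star_additive:.4f})")

# A replication with the same standard error observing this hazard ratio
# or anything smaller would push the combined posterior 95% credible
# interval entirely below the null HR of 1.
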