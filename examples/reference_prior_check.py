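"""Forward posterior check against a published study.

An earlier published analysis of the same comparison reported HR 0.13
with 95% CI (0.06, 0.30). Treating it as the prior and combining it with
our weak HR 0.42 (0.14, 1.23) estimate: is the pooled evidence credible?
"""

import math

from bae import (
    Direction,
    EffectEstimate,
    NormalPrior,
    Scale,
    Scenario,
    evidence_gap_report,
    tipping_point,
    to_additive,
)

obs = to_additive(EffectEstimate(
    point=0.42, ci_lower=0.14, ci_upper=1.23, scale=Scale.HAZARD_RATIO
))
published = to_additive(EffectEstimate(
    point=0.13, ci_lower=0.06, ci_upper=0.30, scale=Scale.HAZARD_RATIO
))

tip = tipping_point(
    obs, direction=Direction.LESS_THAN_NULL, scenario=Scenario.SUPPORTIVE
)
report = evidence_gap_report(
    obs,
    tip,
    [NormalPrior(mu=published.beta_hat, s=published.se)],
    plausible=True,  # analyst judgment: HRs beyond the tipping point are realistic
)
(check,) = report.checks
print(f"tipping point: HR {tip.mu_star_reported:.2f}")
print(f"posterior 95% CrI: HR ({math.exp(check.credible_lower):.2f}, "
      f"{math.exp(check.credible_upper):.2f})")
print(f"credible: {check.credible} ({check.credible_direction} direction); "
      f"prior mean beyond tipping point: {check.beyond_tipping}")
print()
print(report.interpretation)

# The published prior is both more extreme than the tipping point and more
# precise than our analysis, so the pooled 95% credible interval excludes
# the null: the evidence gap is closable.
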