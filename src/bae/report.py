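"""Assembled BAE reports: human-readable text and flat structured output.

A report regenerates entirely from its echoed inputs: the observed
estimate, scenario, direction, prior SD and credibility level fully
determine every number in it. The plot-data block carries point/interval
triplets (on both the additive and reporting scales) for the observed
estimate, the tipping-point hypothetical replication, and the posterior
that results from combining the two — the posterior interval touches the
null by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import norm

from .conjugate import NormalPrior, posterior_update
from .scales import EffectEstimate, NormalSummary, from_additive, to_additive
from .tipping import (
    Direction,
    EvidenceGapReport,
    Scenario,
    TippingResult,
    evidence_gap_report,
    scale_prior_se,
    tipping_point,
)

__all__ = ["IntervalTriplet", "BAEReport", "build_report"]


@dataclass(frozen=True)
class IntervalTriplet:
    """Point and interval on both scales, ready for interval plots."""

    label: str
    point_additive: float
    lower_additive: float
    upper_additive: float
    point_reported: float
    lower_reported: float
    upper_reported: float


def _triplet(label, point, lower, upper, scale) -> IntervalTriplet:
    return IntervalTriplet(
        label=label,
        point_additive=point,
        lower_additive=lower,
        upper_additive=upper,
        point_reported=from_additive(point, scale),
        lower_reported=from_additive(lower, scale),
        upper_reported=from_additive(upper, scale),
    )


@dataclass(frozen=True)
class BAEReport:
    """Complete BAE analysis of one effect estimate."""

    estimate: EffectEstimate
    obs: NormalSummary
    scenario: Scenario
    direction: Direction
    prior_s: float
    size_multiplier: float | None
    cred_level: float
    tipping: TippingResult
    gap: EvidenceGapReport
    plot_data: tuple[IntervalTriplet, ...]
    reference_estimates: tuple[EffectEstimate, ...] = field(default=())

    def to_dict(self) -> dict:
        """Flat key/value document; full precision on the additive scale,
        reporting-scale values additionally rounded to 2 decimals."""
        est = self.estimate
        d: dict = {
            "input_point": est.point,
            "input_scale": est.scale.value,
            "input_conf_level": est.conf_level,
            "scenario": self.scenario.value,
            "direction": self.direction.value,
            "cred_level": self.cred_level,
            "prior_s": self.prior_s,
            "beta_hat": self.obs.beta_hat,
            "se": self.obs.se,
            "tipping_point_additive": self.tipping.mu_star_additive,
            "tipping_point_reported": self.tipping.mu_star_reported,
            "tipping_point_reported_2dp": round(
                self.tipping.mu_star_reported, 2
            ),
            "interpretation": self.gap.interpretation,
        }
        if est.ci_lower is not None:
            d["input_ci_lower"] = est.ci_lower
            d["input_ci_upper"] = est.ci_upper
        if est.p_value is not None:
            d["input_p_value"] = est.p_value
        if est.se is not None:
            d["input_se"] = est.se
        if self.size_multiplier is not None:
            d["size_multiplier"] = self.size_multiplier
            d["prior_s_is_heuristic"] = True
        for t in self.plot_data:
            d[f"{t.label}_additive"] = t.point_additive
            d[f"{t.label}_additive_lower"] = t.lower_additive
            d[f"{t.label}_additive_upper"] = t.upper_additive
            d[f"{t.label}_reported"] = t.point_reported
            d[f"{t.label}_reported_lower"] = t.lower_reported
            d[f"{t.label}_reported_upper"] = t.upper_reported
        for i, chk in enumerate(self.gap.checks, start=1):
            d[f"reference_{i}_prior_mean_additive"] = chk.prior.mu
            d[f"reference_{i}_prior_s"] = chk.prior.s
            d[f"reference_{i}_posterior_mean"] = chk.posterior_mu
            d[f"reference_{i}_posterior_s"] = chk.posterior_s
            d[f"reference_{i}_credible_lower"] = chk.credible_lower
            d[f"reference_{i}_credible_upper"] = chk.credible_upper
            d[f"reference_{i}_credible"] = chk.credible
            d[f"reference_{i}_beyond_tipping"] = chk.beyond_tipping
        return d

    def to_text(self) -> str:
        est = self.estimate
        scale_name = est.scale.label
        lines = [
            "Bayesian Additional Evidence report",
            "=" * 35,
            f"Observed {scale_name}: {est.point}"
            + (
                f" ({est.conf_level:.0%} CI {est.ci_lower}, {est.ci_upper})"
                if est.ci_lower is not None
                else ""
            )
            + (f" (p = {est.p_value})" if est.p_value is not None else "")
            + (f" (SE = {est.se})" if est.se is not None else ""),
            f"Additive scale: beta = {self.obs.beta_hat:.6f}, "
            f"SE = {self.obs.se:.6f}",
            f"Scenario: {self.scenario.value}; direction of interest: "
            f"{self.direction.value}; credibility level "
            f"{self.cred_level:.0%}",
            f"Prior (replication) SD: {self.prior_s:.6f}"
            + (
                f" (observed SE scaled for a study {self.size_multiplier}x "
                "the size; approximate heuristic)"
                if self.size_multiplier is not None
                else ""
            ),
            "",
            f"Tipping point ({scale_name} scale): "
            f"{self.tipping.mu_star_reported:.2f}",
            f"Tipping point (additive scale): "
            f"{self.tipping.mu_star_additive:.6f}",
            "",
        ]
        for t in self.plot_data:
            lines.append(
                f"{t.label}: {scale_name} {t.point_reported:.2f} "
                f"({t.lower_reported:.2f}, {t.upper_reported:.2f}) "
                f"| additive {t.point_additive:.4f} "
                f"({t.lower_additive:.4f}, {t.upper_additive:.4f})"
            )
        if self.gap.checks:
            lines.append("")
            lines.append("Reference priors:")
            for i, chk in enumerate(self.gap.checks, start=1):
                rep = from_additive(chk.prior.mu, est.scale)
                verdict = (
                    f"credible ({chk.credible_direction})"
                    if chk.credible
                    else "not credible"
                )
                lines.append(
                    f"  [{i}] prior {scale_name} {rep:.2f} "
                    f"(SD {chk.prior.s:.4f}) -> posterior "
                    f"({chk.credible_lower:.4f}, {chk.credible_upper:.4f}): "
                    f"{verdict}; "
                    + (
                        "beyond the tipping point"
                        if chk.beyond_tipping
                        else "not beyond the tipping point"
                    )
                )
        lines += ["", self.gap.interpretation, ""]
        return "\n".join(lines)


def build_report(
    estimate: EffectEstimate,
    scenario: Scenario,
    direction: Direction,
    prior_s: float | None = None,
    size_multiplier: float | None = None,
    cred_level: float = 0.95,
    reference_estimates: list[EffectEstimate] | tuple[EffectEstimate, ...] = (),
    plausible: bool | None = None,
) -> BAEReport:
    """Run the full BAE pipeline on one reporting-scale estimate.

    ``prior_s`` and ``size_multiplier`` are mutually exclusive ways of
    setting the hypothetical replication's standard deviation; with
    neither, the observed standard error is used. Reference estimates
    (published studies on the same reporting scale) are converted and
    checked for forward posterior credibility.
    """
    if prior_s is not None and size_multiplier is not None:
        raise ValueError("give either prior_s or size_multiplier, not both")
    obs = to_additive(estimate)
    if size_multiplier is not None:
        prior_s = scale_prior_se(obs.se, size_multiplier)
    elif prior_s is None:
        prior_s = obs.se
    tip = tipping_point(
        obs,
        prior_s=prior_s,
        direction=direction,
        scenario=scenario,
        cred_level=cred_level,
    )
    reference_priors = []
    for ref in reference_estimates:
        ref_summary = to_additive(ref)
        reference_priors.append(
            NormalPrior(mu=ref_summary.beta_hat, s=ref_summary.se)
        )
    gap = evidence_gap_report(obs, tip, reference_priors, plausible=plausible)

    z = norm.ppf(1.0 - (1.0 - cred_level) / 2.0)
    scale = estimate.scale
    tip_prior = NormalPrior(mu=tip.mu_star_additive, s=prior_s)
    tip_post = posterior_update(obs, tip_prior, cred_level)
    plot_data = (
        _triplet(
            "observed",
            obs.beta_hat,
            obs.beta_hat - z * obs.se,
            obs.beta_hat + z * obs.se,
            scale,
        ),
        _triplet(
            "tipping_replication",
            tip.mu_star_additive,
            tip.mu_star_additive - z * prior_s,
            tip.mu_star_additive + z * prior_s,
            scale,
        ),
        _triplet(
            "posterior_at_tipping",
            tip_post.mu_p,
            tip_post.credible_lower,
            tip_post.credible_upper,
            scale,
        ),
    )
    # sanity: the posterior at the tipping point touches the null
    touch = (
        tip_post.credible_upper
        if direction is Direction.LESS_THAN_NULL
        else tip_post.credible_lower
    )
    assert math.isclose(touch, 0.0, abs_tol=1e-8)
    return BAEReport(
        estimate=estimate,
        obs=obs,
        scenario=Scenario(scenario),
        direction=Direction(direction),
        prior_s=prior_s,
        size_multiplier=size_multiplier,
        cred_level=cred_level,
        tipping=tip,
        gap=gap,
        plot_data=plot_data,
        reference_estimates=tuple(reference_estimates),
    )
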