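"""Bayesian Additional Evidence: the tipping-point inversion.

Given an observed estimate with standard error, BAE inverts the
normal-normal posterior update: holding the prior standard deviation fixed,
it searches over prior means for the tipping point ``mu_star`` at which the
posterior credible interval just touches the null. Because prior and data
are symmetric in the conjugate update, the prior mean stands for the
estimate a hypothetical replication study would report; the tipping point
is therefore the least extreme replication result that would make the
combined evidence credible (non-significant initial result, supportive
scenario) or the least extreme contrary result that would destroy
credibility (significant initial result, opposing scenario).

The search is implemented as bracketed root finding on the touching
credible limit as a function of the prior mean — the mechanism that
generalises to non-conjugate settings — and is cross-checked against the
closed-form linear solution that exists in the frozen normal-normal
plug-in model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

from scipy.optimize import brentq
from scipy.stats import norm

from .conjugate import NormalPrior, is_credible, posterior_update
from .scales import NormalSummary, from_additive

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "Scenario",
    "TippingResult",
    "ReferencePriorCheck",
    "EvidenceGapReport",
    "tipping_point",
    "closed_form_tipping",
    "scale_prior_se",
    "evidence_gap_report",
]

#: Absolute tolerance of the root solve on the prior-mean axis.
SOLVER_XTOL = 1e-12


class Direction(str, Enum):
    """Which side of the null holds the scientifically interesting effects.

    ``LESS_THAN_NULL`` means effects below 0 on the additive scale (ratio
    effects below 1) are of interest; the credible limit that touches the
    null is then the upper one. ``GREATER_THAN_NULL`` mirrors this.
    """

    LESS_THAN_NULL = "less_than_null"
    GREATER_THAN_NULL = "greater_than_null"


class Scenario(str, Enum):
    """Which of the two BAE questions is being asked.

    ``SUPPORTIVE``: the initial result is non-significant; how much
    additional supportive evidence would make it credible?
    ``OPPOSING``: the initial result is significant; how much contrary
    evidence would make it non-credible?
    """

    SUPPORTIVE = "supportive"
    OPPOSING = "opposing"


@dataclass(frozen=True)
class TippingResult:
    """The BAE tipping point with its scenario metadata.

    ``mu_star_additive`` is on the analysis (log) scale;
    ``mu_star_reported`` is back-transformed to the reporting scale of the
    observed estimate.
    """

    mu_star_additive: float
    mu_star_reported: float
    scenario: Scenario
    direction: Direction
    prior_s_used: float
    cred_level: float
    interpretation: str = ""


def _check_scenario(
    obs: NormalSummary, scenario: Scenario, cred_level: float
) -> None:
    """Enforce the scenario/significance match of the interpretation matrix."""
    lo, hi = obs.wald_interval(cred_level)
    significant = lo > 0.0 or hi < 0.0
    if scenario is Scenario.SUPPORTIVE and significant:
        raise ValueError(
            "supportive scenario requires a non-significant initial result "
            f"(the {cred_level:.0%} interval must include the null); the "
            "observed interval excludes it — use the opposing scenario to "
            "ask how much contrary evidence would destroy credibility"
        )
    if scenario is Scenario.OPPOSING and not significant:
        raise ValueError(
            "opposing scenario requires a significant initial result "
            f"(the {cred_level:.0%} interval must exclude the null); the "
            "observed interval includes it — use the supportive scenario to "
            "ask how much additional evidence would yield credibility"
        )


def _touching_limit(
    obs: NormalSummary, prior: NormalPrior, direction: Direction, cred_level: float
) -> float:
    """Credible-interval limit nearer the null for the given direction."""
    post = posterior_update(obs, prior, cred_level)
    if direction is Direction.LESS_THAN_NULL:
        return post.credible_upper
    return post.credible_lower


def closed_form_tipping(
    obs: NormalSummary,
    prior_s: float,
    direction: Direction,
    scenario: Scenario,
    cred_level: float = 0.95,
) -> float:
    """Closed-form tipping point on the additive scale.

    In the normal-normal plug-in model the posterior SD does not depend on
    the prior mean, so setting the touching credible limit to zero is a
    linear equation in the prior mean:

        mu_star = s^2 * (-/+ z/s_p - beta_hat/se^2)

    with the minus sign for ``LESS_THAN_NULL`` (upper limit touches) and
    the plus sign for ``GREATER_THAN_NULL``. Serves as the independent
    oracle for :func:`tipping_point`.
    """
    direction = Direction(direction)
    scenario = Scenario(scenario)
    if prior_s <= 0:
        raise ValueError(f"prior_s must be positive, got {prior_s}")
    _check_scenario(obs, scenario, cred_level)
    z = norm.ppf(1.0 - (1.0 - cred_level) / 2.0)
    s_p = math.sqrt(1.0 / (1.0 / obs.se**2 + 1.0 / prior_s**2))
    sign = -1.0 if direction is Direction.LESS_THAN_NULL else 1.0
    return prior_s**2 * (sign * z / s_p - obs.beta_hat / obs.se**2)


def tipping_point(
    obs: NormalSummary,
    prior_s: float | None = None,
    direction: Direction = Direction.LESS_THAN_NULL,
    scenario: Scenario = Scenario.SUPPORTIVE,
    cred_level: float = 0.95,
) -> TippingResult:
    """Locate the BAE tipping point by bracketed root finding.

    Parameters
    ----------
    obs
        Observed estimate on the additive scale.
    prior_s
        Prior (hypothetical replication) standard deviation. Defaults to
        ``obs.se``: a replication with the same precision as the initial
        analysis. Use :func:`scale_prior_se` to encode a larger or smaller
        hypothetical study.
    direction
        Side of the null holding the effects of interest; required
        scientific input, no universally sensible default exists (the
        package-level default of ``LESS_THAN_NULL`` matches benefit on
        ratio scales; the CLI demands it explicitly).
    scenario
        ``SUPPORTIVE`` for a non-significant initial result, ``OPPOSING``
        for a significant one; checked against the observed Wald interval.
    cred_level
        Credibility level of the posterior interval (and significance
        level of the scenario check), default 0.95.

    Returns
    -------
    TippingResult
        Tipping point on both scales with scenario metadata.
    """
    direction = Direction(direction)
    scenario = Scenario(scenario)
    if prior_s is None:
        prior_s = obs.se
    if prior_s <= 0:
        raise ValueError(f"prior_s must be positive, got {prior_s}")
    _check_scenario(obs, scenario, cred_level)

    def g(mu: float) -> float:
        return _touching_limit(
            obs, NormalPrior(mu=mu, s=prior_s), direction, cred_level
        )

    # g is strictly increasing in mu (slope s_p^2/s^2 > 0), so a sign
    # change always exists; expand the bracket geometrically until found.
    # A small prior SD relative to se can push the root far beyond any
    # fixed multiple of (|beta_hat|, se, prior_s).
    half_span = abs(obs.beta_hat) + 20.0 * max(obs.se, prior_s)
    for _ in range(80):
        if g(-half_span) < 0.0 < g(half_span):
            break
        half_span *= 2.0
    else:
        raise RuntimeError(
            "failed to bracket the tipping point; inputs may be degenerate"
        )
    mu_star = brentq(g, -half_span, half_span, xtol=SOLVER_XTOL)
    logger.info(
        "tipping point located at %.6g (additive scale), prior SD %.6g",
        mu_star,
        prior_s,
    )
    return TippingResult(
        mu_star_additive=mu_star,
        mu_star_reported=from_additive(mu_star, obs.scale_tag),
        scenario=scenario,
        direction=direction,
        prior_s_used=prior_s,
        cred_level=cred_level,
        interpretation=_interpretation(scenario, None),
    )


def scale_prior_se(se: float, size_multiplier: float) -> float:
    """Standard error of a hypothetical study ``size_multiplier`` times larger.

    Assuming the per-observation sampling SD stays constant as the sample
    size changes, a study with X times more subjects observes a standard
    error of ``se / sqrt(X)``. In models where the sampling SD depends on
    the effect itself (e.g. proportional-hazards fits) this holds only
    approximately; treat it as a heuristic.
    """
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if size_multiplier <= 0:
        raise ValueError(
            f"size_multiplier must be positive, got {size_multiplier}"
        )
    return se / math.sqrt(size_multiplier)


def _more_extreme(mu: float, mu_star: float, direction: Direction) -> bool:
    """Is ``mu`` beyond ``mu_star`` in the direction of interest?"""
    if direction is Direction.LESS_THAN_NULL:
        return mu < mu_star
    return mu > mu_star


def _interpretation(scenario: Scenario, plausible: bool | None) -> str:
    """Guidance text for the (scenario, plausibility) cell."""
    if scenario is Scenario.SUPPORTIVE:
        text = (
            "The initial analysis is not statistically significant. The "
            "tipping point is the least extreme estimate a follow-up study "
            "of the stated precision would need to observe for the combined "
            "evidence to reach posterior credibility; a tipping point close "
            "to the null means the current evidence is already strong."
        )
        if plausible is True:
            text += (
                " Effects beyond the tipping point are judged plausible: the "
                "observed data are useful and a follow-up study is warranted."
            )
        elif plausible is False:
            text += (
                " Effects beyond the tipping point are judged implausible: "
                "the evidence gap is too large to close with a comparable "
                "follow-up study."
            )
    else:
        text = (
            "The initial analysis is statistically significant. The tipping "
            "point is the least extreme contrary estimate that would render "
            "the combined evidence non-credible (prior means larger in "
            "magnitude than the tipping point yield non-credibility or "
            "credible evidence in the opposite direction); a tipping point "
            "far beyond the null on the contrary side means the current "
            "evidence is robust."
        )
        if plausible is True:
            text += (
                " Contrary effects beyond the tipping point are judged "
                "plausible: the current evidence is not strong enough on "
                "its own."
            )
        elif plausible is False:
            text += (
                " Contrary effects beyond the tipping point are judged "
                "implausible: the current evidence withstands realistic "
                "additional data."
            )
    return text


@dataclass(frozen=True)
class ReferencePriorCheck:
    """Forward posterior check of one reference prior against the data."""

    prior: NormalPrior
    posterior_mu: float
    posterior_s: float
    credible_lower: float
    credible_upper: float
    credible: bool
    credible_direction: str | None
    beyond_tipping: bool


@dataclass(frozen=True)
class EvidenceGapReport:
    """Tipping point plus forward checks of published reference priors.

    A reference prior (typically a published study's estimate and standard
    error) may yield posterior credibility even when its mean is not beyond
    the tipping point, if it is more precise than the hypothetical
    replication the tipping point assumed — the two flags are reported
    separately for that reason.
    """

    tipping: TippingResult
    checks: tuple[ReferencePriorCheck, ...]
    interpretation: str


def evidence_gap_report(
    obs: NormalSummary,
    tipping: TippingResult,
    reference_priors: list[NormalPrior] | tuple[NormalPrior, ...] = (),
    plausible: bool | None = None,
) -> EvidenceGapReport:
    """Assess reference priors against the observed data and tipping point.

    For each reference prior, reports whether combining it with ``obs``
    yields posterior credibility at the tipping result's level, and whether
    its mean lies beyond the tipping point in the direction of interest.
    ``plausible`` is the analyst's domain-knowledge judgment of whether
    effects beyond the tipping point are realistic; it is never computed.
    """
    checks = []
    for prior in reference_priors:
        post = posterior_update(obs, prior, tipping.cred_level)
        credible, cred_dir = is_credible(post)
        checks.append(
            ReferencePriorCheck(
                prior=prior,
                posterior_mu=post.mu_p,
                posterior_s=post.s_p,
                credible_lower=post.credible_lower,
                credible_upper=post.credible_upper,
                credible=credible,
                credible_direction=cred_dir,
                beyond_tipping=_more_extreme(
                    prior.mu, tipping.mu_star_additive, tipping.direction
                ),
            )
        )
    return EvidenceGapReport(
        tipping=tipping,
        checks=tuple(checks),
        interpretation=_interpretation(tipping.scenario, plausible),
    )
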