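"""Normal-normal conjugate posterior updating.

The forward direction of Bayes' theorem that the tipping-point inversion
undoes. With a normal likelihood ``beta_hat | beta ~ N(beta, se)`` and a
normal prior ``beta ~ N(mu, s)``, the posterior is normal with precision
equal to the sum of the prior and data precisions and mean equal to the
precision-weighted average of the two:

    s_p^2 = (1/se^2 + 1/s^2)^(-1)
    mu_p  = s_p^2 * (mu/s^2 + beta_hat/se^2)

The credible interval is ``mu_p ± z·s_p`` and is never wider than the Wald
interval built from the data alone. Prior and data enter symmetrically, so
either study in a pair may play the role of "prior".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .scales import NormalSummary

__all__ = ["NormalPrior", "PosteriorResult", "posterior_update", "is_credible"]


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior for the true effect, on the additive scale."""

    mu: float
    s: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"prior SD must be positive, got {self.s}")


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior summary with its central credible interval."""

    mu_p: float
    s_p: float
    credible_lower: float
    credible_upper: float
    cred_level: float

    def __post_init__(self) -> None:
        if self.s_p <= 0:
            raise ValueError(f"posterior SD must be positive, got {self.s_p}")
        if not 0.0 < self.cred_level < 1.0:
            raise ValueError(
                f"cred_level must be in (0, 1), got {self.cred_level}"
            )
        if self.credible_lower >= self.credible_upper:
            raise ValueError("credible interval limits out of order")


def posterior_update(
    obs: NormalSummary, prior: NormalPrior, cred_level: float = 0.95
) -> PosteriorResult:
    """Conjugate normal-normal update of ``prior`` by ``obs``.

    Parameters
    ----------
    obs
        Observed estimate and standard error on the additive scale.
    prior
        Normal prior (mean and SD) on the same scale.
    cred_level
        Level of the central credible interval, default 0.95.
    """
    if not 0.0 < cred_level < 1.0:
        raise ValueError(f"cred_level must be in (0, 1), got {cred_level}")
    prec = 1.0 / obs.se**2 + 1.0 / prior.s**2
    s_p = math.sqrt(1.0 / prec)
    mu_p = (prior.mu / prior.s**2 + obs.beta_hat / obs.se**2) / prec
    z = norm.ppf(1.0 - (1.0 - cred_level) / 2.0)
    return PosteriorResult(
        mu_p=mu_p,
        s_p=s_p,
        credible_lower=mu_p - z * s_p,
        credible_upper=mu_p + z * s_p,
        cred_level=cred_level,
    )


def is_credible(post: PosteriorResult) -> tuple[bool, str | None]:
    """Classify a posterior as credible evidence against the null.

    Returns ``(credible, direction)`` where ``credible`` is True iff the
    credible interval strictly excludes 0 on the additive scale, and
    ``direction`` is ``"negative"`` or ``"positive"`` (the sign of the
    posterior mean) when credible, else None. An interval whose limit
    touches 0 exactly is classified not credible: the tipping point is the
    boundary case, so only prior means strictly beyond it yield credibility.
    """
    if post.credible_upper < 0.0:
        return True, "negative"
    if post.credible_lower > 0.0:
        return True, "positive"
    return False, None
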