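"""Effect-scale handling: reporting scales vs the additive analysis scale.

Ratio effect measures (hazard ratios, odds ratios, risk ratios) are analysed
on their natural-log scale, where Wald machinery applies: the estimator is
asymptotically normal and a symmetric confidence interval maps to a standard
error by inverting ``point ± z·se``. The identity scale passes through
untouched. Every downstream computation in this package operates on
:class:`NormalSummary` objects living on the additive scale; this module is
the only place where scale conversion happens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "Scale",
    "EffectEstimate",
    "NormalSummary",
    "ci_to_se",
    "pvalue_to_se",
    "to_additive",
    "from_additive",
]


class Scale(str, Enum):
    """Reporting scale of an effect estimate.

    Ratio scales are log-transformed for analysis; their null value is 1
    (0 on the log scale). The identity scale is analysed as-is with null 0.
    """

    HAZARD_RATIO = "hazard_ratio"
    ODDS_RATIO = "odds_ratio"
    RISK_RATIO = "risk_ratio"
    IDENTITY = "identity"

    @property
    def is_ratio(self) -> bool:
        return self is not Scale.IDENTITY

    @property
    def null_value(self) -> float:
        """Null value on the reporting scale (1 for ratios, 0 otherwise)."""
        return 1.0 if self.is_ratio else 0.0

    @property
    def label(self) -> str:
        return self.value.replace("_", " ")


def _transform(x: float, scale: Scale) -> float:
    """Reporting scale -> additive scale (natural log on ratio scales)."""
    if scale.is_ratio:
        if x <= 0:
            raise ValueError(
                f"{scale.label} values must be positive, got {x}"
            )
        return math.log(x)
    return x


def from_additive(value: float, scale: Scale) -> float:
    """Map an additive-scale value back onto its reporting scale.

    Inverse of the analysis transform: ``exp`` on ratio scales, identity
    otherwise.
    """
    scale = Scale(scale)
    return math.exp(value) if scale.is_ratio else value


def ci_to_se(
    lower: float, upper: float, conf_level: float, scale: Scale
) -> float:
    """Recover the additive-scale standard error from a Wald interval.

    A two-sided interval at level ``conf_level`` spans ``2·z`` standard
    errors on the analysis scale, where ``z`` is the standard-normal
    quantile at ``1 − (1 − conf_level)/2``.

    Parameters
    ----------
    lower, upper
        Interval limits on the reporting scale.
    conf_level
        Two-sided confidence level, strictly in (0, 1).
    scale
        Reporting scale of the limits.
    """
    scale = Scale(scale)
    if not 0.0 < conf_level < 1.0:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    if scale.is_ratio and (lower <= 0 or upper <= 0):
        raise ValueError(
            f"{scale.label} interval limits must be positive, "
            f"got ({lower}, {upper})"
        )
    if lower >= upper:
        raise ValueError(
            f"interval limits must satisfy lower < upper, got ({lower}, {upper})"
        )
    z = norm.ppf(1.0 - (1.0 - conf_level) / 2.0)
    return (_transform(upper, scale) - _transform(lower, scale)) / (2.0 * z)


def pvalue_to_se(point: float, p_value: float, scale: Scale) -> float:
    """Recover the additive-scale standard error from a two-sided p-value.

    Inverts the Wald statistic ``z = |beta| / se``: the standard error is
    ``|beta| / Φ⁻¹(1 − p/2)`` where ``beta`` is the point estimate on the
    analysis scale. Undefined when the estimate sits exactly at the null.
    """
    scale = Scale(scale)
    if not 0.0 < p_value < 1.0:
        raise ValueError(f"p_value must be in (0, 1), got {p_value}")
    beta = _transform(point, scale)
    if beta == 0.0:
        raise ValueError(
            "point estimate equals the null value; the standard error "
            "cannot be recovered from a p-value"
        )
    # isf(p/2) == ppf(1 - p/2) but keeps precision for tiny p-values
    return abs(beta) / norm.isf(p_value / 2.0)


@dataclass(frozen=True)
class EffectEstimate:
    """A user-facing effect estimate on its reporting scale.

    Uncertainty may be supplied as a confidence interval, a two-sided
    p-value, or an additive-scale standard error. If both an interval and a
    p-value are given, the interval wins (it carries more information) and a
    warning is logged; any other combination of multiple sources is an
    error.

    Attributes
    ----------
    point
        Point estimate on ``scale`` (positive on ratio scales).
    ci_lower, ci_upper
        Optional confidence-interval limits on ``scale``.
    p_value
        Optional two-sided p-value against the null.
    se
        Optional standard error, already on the additive (log) scale.
    conf_level
        Level of the supplied interval, default 0.95.
    scale
        Reporting scale.
    """

    point: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    p_value: float | None = None
    se: float | None = None
    conf_level: float = 0.95
    scale: Scale = field(default=Scale.IDENTITY)

    def __post_init__(self) -> None:
        object.__setattr__(self, "scale", Scale(self.scale))
        if not 0.0 < self.conf_level < 1.0:
            raise ValueError(
                f"conf_level must be in (0, 1), got {self.conf_level}"
            )
        if (self.ci_lower is None) != (self.ci_upper is None):
            raise ValueError("ci_lower and ci_upper must be given together")
        has_ci = self.ci_lower is not None
        has_p = self.p_value is not None
        has_se = self.se is not None
        n_sources = has_ci + has_p + has_se
        if n_sources == 0:
            raise ValueError(
                "one of a confidence interval, a p-value or a standard "
                "error is required"
            )
        if n_sources > 1:
            if has_ci and has_p and not has_se:
                logger.warning(
                    "both a confidence interval and a p-value were "
                    "supplied; using the interval"
                )
            else:
                raise ValueError(
                    "supply only one uncertainty source (CI, p-value or SE)"
                )
        if self.scale.is_ratio and self.point <= 0:
            raise ValueError(
                f"{self.scale.label} point estimate must be positive, "
                f"got {self.point}"
            )
        if has_ci:
            if not self.ci_lower < self.point < self.ci_upper:
                raise ValueError(
                    "confidence interval must bracket the point estimate: "
                    f"need ci_lower < point < ci_upper, got "
                    f"({self.ci_lower}, {self.point}, {self.ci_upper})"
                )
        if has_p and not 0.0 < self.p_value < 1.0:
            raise ValueError(f"p_value must be in (0, 1), got {self.p_value}")
        if has_se and self.se <= 0:
            raise ValueError(f"se must be positive, got {self.se}")


@dataclass(frozen=True)
class NormalSummary:
    """An effect estimate on the additive analysis scale.

    ``se`` houses the composite sampling standard deviation of the
    estimator (the plug-in estimate of sigma/sqrt(n)); sample size and the
    per-observation sigma never appear separately.
    """

    beta_hat: float
    se: float
    scale_tag: Scale = Scale.IDENTITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "scale_tag", Scale(self.scale_tag))
        if self.se <= 0:
            raise ValueError(f"se must be positive, got {self.se}")

    def wald_interval(self, conf_level: float = 0.95) -> tuple[float, float]:
        """Frequentist interval ``beta_hat ± z·se`` on the additive scale."""
        z = norm.ppf(1.0 - (1.0 - conf_level) / 2.0)
        return self.beta_hat - z * self.se, self.beta_hat + z * self.se


def to_additive(est: EffectEstimate) -> NormalSummary:
    """Convert a reporting-scale estimate to an additive-scale summary.

    The point estimate is log-transformed on ratio scales; the standard
    error comes from whichever uncertainty source the estimate carries
    (interval inversion preferred over p-value inversion).
    """
    beta = _transform(est.point, est.scale)
    if est.ci_lower is not None:
        se = ci_to_se(est.ci_lower, est.ci_upper, est.conf_level, est.scale)
    elif est.p_value is not None:
        se = pvalue_to_se(est.point, est.p_value, est.scale)
    else:
        se = est.se
    return NormalSummary(beta_hat=beta, se=se, scale_tag=est.scale)
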