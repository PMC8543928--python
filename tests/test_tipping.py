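"""Tipping-point inversion: root search, closed-form oracle, properties."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from bae import (
    Direction,
    NormalPrior,
    NormalSummary,
    Scenario,
    closed_form_tipping,
    evidence_gap_report,
    is_credible,
    posterior_update,
    scale_prior_se,
    tipping_point,
)

Z95 = norm.ppf(0.975)
LESS = Direction.LESS_THAN_NULL
GREATER = Direction.GREATER_THAN_NULL
SUPP = Scenario.SUPPORTIVE
OPP = Scenario.OPPOSING


def _scenario_for(obs: NormalSummary, cred_level: float = 0.95) -> Scenario:
    lo, hi = obs.wald_interval(cred_level)
    return OPP if (lo > 0 or hi < 0) else SUPP


class TestWorkedExamples:
    """Published worked examples: a replication as precise as the initial
    study must observe roughly half the hazard to tip into credibility."""

    def test_hr_042_tipping_point(self, obs_042):
        res = tipping_point(obs_042, direction=LESS, scenario=SUPP)
        assert res.mu_star_additive == pytest.approx(
            -0.6691322885879171, abs=1e-9
        )
        assert res.mu_star_reported == pytest.approx(0.52, abs=0.015)

    def test_hr_031_tipping_point(self, obs_031):
        res = tipping_point(obs_031, direction=LESS, scenario=SUPP)
        assert res.mu_star_additive == pytest.approx(
            -0.5988861615589096, abs=1e-9
        )
        assert res.mu_star_reported == pytest.approx(0.54, abs=0.015)

    def test_null_centered_observation(self):
        """Equal-precision averaging forces mu* = -z*sqrt(2)*se exactly."""
        se = 0.7
        res = tipping_point(
            NormalSummary(0.0, se), direction=LESS, scenario=SUPP
        )
        assert res.mu_star_additive == pytest.approx(
            -Z95 * math.sqrt(2) * se, abs=1e-9
        )


class TestClosedForm:
    @pytest.mark.parametrize(
        "beta, se, prior_s, expected",
        [
            (-0.8675005677047231, 0.5543793260739757, 0.5543793260739757,
             -0.6691322885879171),
            (-1.171182981502945, 0.6385973946974433, 0.6385973946974433,
             -0.5988861615589096),
            (0.0, 1.0, 1.0, -Z95 * math.sqrt(2)),
        ],
    )
    def test_known_values(self, beta, se, prior_s, expected):
        obs = NormalSummary(beta, se)
        assert closed_form_tipping(obs, prior_s, LESS, SUPP) == pytest.approx(
            expected, abs=1e-10
        )

    def test_oracle_equivalence_randomized(self):
        """Root search and linear closed form agree to 1e-8 across a
        randomized grid covering both directions and both scenarios."""
        rng = np.random.default_rng(20211025)
        seen = set()
        for _ in range(300):
            beta = rng.uniform(-3, 3)
            se = rng.uniform(0.05, 2)
            prior_s = rng.uniform(0.05, 2)
            obs = NormalSummary(beta, se)
            scenario = _scenario_for(obs)
            for direction in (LESS, GREATER):
                seen.add((scenario, direction))
                root = tipping_point(
                    obs, prior_s, direction, scenario
                ).mu_star_additive
                closed = closed_form_tipping(obs, prior_s, direction, scenario)
                assert abs(root - closed) < 1e-8
        assert seen == {(s, d) for s in (SUPP, OPP) for d in (LESS, GREATER)}


class TestBoundaryBehaviour:
    def test_posterior_touches_null_at_tipping_point(self, obs_042):
        res = tipping_point(obs_042, direction=LESS, scenario=SUPP)
        post = posterior_update(
            obs_042, NormalPrior(res.mu_star_additive, res.prior_s_used)
        )
        assert abs(post.credible_upper) < 1e-8

    @pytest.mark.parametrize("direction", [LESS, GREATER])
    def test_credibility_flips_across_tipping_point(self, obs_042, direction):
        """Prior means strictly more extreme than mu* yield credibility;
        strictly less extreme ones do not."""
        obs = obs_042 if direction is LESS else NormalSummary(
            -obs_042.beta_hat, obs_042.se, obs_042.scale_tag
        )
        res = tipping_point(obs, direction=direction, scenario=SUPP)
        sign = -1.0 if direction is LESS else 1.0
        more = NormalPrior(res.mu_star_additive + sign * 1e-6, res.prior_s_used)
        less = NormalPrior(res.mu_star_additive - sign * 1e-6, res.prior_s_used)
        assert is_credible(posterior_update(obs, more))[0]
        assert not is_credible(posterior_update(obs, less))[0]

    def test_touching_limit_increasing_in_prior_mean(self, obs_042):
        """Uniqueness of mu*: the upper credible limit grows strictly with
        the prior mean."""
        prior_s = obs_042.se
        limits = [
            posterior_update(obs_042, NormalPrior(mu, prior_s)).credible_upper
            for mu in np.linspace(-4, 4, 41)
        ]
        assert all(a < b for a, b in zip(limits, limits[1:]))


class TestPriorScaling:
    @pytest.mark.parametrize(
        "se, x, expected",
        [(0.5544, 1, 0.5544), (0.5544, 4, 0.2772), (1.0, 2, 0.7071067811865475)],
    )
    def test_sqrt_scaling(self, se, x, expected):
        assert scale_prior_se(se, x) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("se, x", [(0.0, 2), (1.0, 0), (-1.0, 2)])
    def test_nonpositive_inputs_rejected(self, se, x):
        with pytest.raises(ValueError):
            scale_prior_se(se, x)

    def test_larger_replication_moves_tipping_toward_null(self, obs_042):
        """A more precise hypothetical replication needs a less extreme
        result: mu* strictly approaches the null as the study grows."""
        stars = [
            tipping_point(
                obs_042,
                prior_s=scale_prior_se(obs_042.se, x),
                direction=LESS,
                scenario=SUPP,
            ).mu_star_additive
            for x in (1, 2, 4, 9)
        ]
        assert all(s < 0 for s in stars)
        assert all(a < b for a, b in zip(stars, stars[1:]))


class TestSymmetry:
    @pytest.mark.parametrize("beta, se, prior_s", [
        (-0.8675, 0.5544, 0.5544),
        (0.4, 0.9, 0.3),
        (1.2, 0.5, 1.5),
    ])
    def test_negating_estimate_and_direction_negates_tipping(
        self, beta, se, prior_s
    ):
        obs = NormalSummary(beta, se)
        mirrored = NormalSummary(-beta, se)
        scenario = _scenario_for(obs)
        a = tipping_point(obs, prior_s, LESS, scenario).mu_star_additive
        b = tipping_point(mirrored, prior_s, GREATER, scenario).mu_star_additive
        assert a == pytest.approx(-b, abs=1e-9)


class TestScenarioPreconditions:
    def test_supportive_rejects_significant_input(self):
        obs = NormalSummary(-1.0, 0.2)  # interval far below the null
        with pytest.raises(ValueError, match="opposing scenario"):
            tipping_point(obs, direction=LESS, scenario=SUPP)

    def test_opposing_rejects_nonsignificant_input(self, obs_042):
        with pytest.raises(ValueError, match="supportive scenario"):
            tipping_point(obs_042, direction=LESS, scenario=OPP)

    def test_opposing_tipping_for_significant_result(self):
        """For a clearly significant protective effect, the contrary prior
        mean that destroys credibility lies on the other side of the null."""
        obs = NormalSummary(-1.0, 0.2)
        res = tipping_point(obs, direction=LESS, scenario=OPP)
        expected = 1.0 - Z95 * math.sqrt(2) * 0.2
        assert res.mu_star_additive == pytest.approx(expected, abs=1e-9)
        # a contrary prior beyond mu* removes credibility
        beyond = NormalPrior(res.mu_star_additive + 1e-4, 0.2)
        assert not is_credible(posterior_update(obs, beyond))[0]


class TestEvidenceGapReport:
    def test_published_prior_check(self, obs_042):
        tip = tipping_point(obs_042, direction=LESS, scenario=SUPP)
        prior = NormalPrior(math.log(0.13), 0.4105784405043004)
        report = evidence_gap_report(obs_042, tip, [prior])
        (chk,) = report.checks
        assert chk.credible and chk.credible_direction == "negative"
        assert chk.credible_upper == pytest.approx(-0.978147810, abs=1e-6)
        assert chk.beyond_tipping  # log 0.13 is far below mu*

    def test_null_centered_everything_not_credible(self):
        obs = NormalSummary(0.0, 1.0)
        tip = tipping_point(obs, direction=LESS, scenario=SUPP)
        report = evidence_gap_report(obs, tip, [NormalPrior(0.0, 1.0)])
        (chk,) = report.checks
        assert not chk.credible and not chk.beyond_tipping

    def test_empty_reference_list(self, obs_042):
        tip = tipping_point(obs_042, direction=LESS, scenario=SUPP)
        report = evidence_gap_report(obs_042, tip, [])
        assert report.checks == ()
        assert report.tipping is tip
        assert "not statistically significant" in report.interpretation

    def test_plausibility_flag_changes_conclusion_only(self, obs_042):
        tip = tipping_point(obs_042, direction=LESS, scenario=SUPP)
        yes = evidence_gap_report(obs_042, tip, [], plausible=True)
        no = evidence_gap_report(obs_042, tip, [], plausible=False)
        assert "follow-up study is warranted" in yes.interpretation
        assert "too large" in no.interpretation
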