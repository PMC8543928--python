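import pytest

from bae import EffectEstimate, Scale, to_additive


@pytest.fixture
def hr_042_ci():
    """Non-significant comparative-effectiveness estimate, CI form."""
    return EffectEstimate(
        point=0.42, ci_lower=0.14, ci_upper=1.23, scale=Scale.HAZARD_RATIO
    )


@pytest.fixture
def hr_031_ci():
    """Non-significant estimate from the companion summary, CI form."""
    return EffectEstimate(
        point=0.31, ci_lower=0.09, ci_upper=1.1, scale=Scale.HAZARD_RATIO
    )


@pytest.fixture
def hr_013_published():
    """Significant published estimate used as a reference prior."""
    return EffectEstimate(
        point=0.13, ci_lower=0.06, ci_upper=0.30, scale=Scale.HAZARD_RATIO
    )


@pytest.fixture
def obs_042(hr_042_ci):
    return to_additive(hr_042_ci)


@pytest.fixture
def obs_031(hr_031_ci):
    return to_additive(hr_031_ci)
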