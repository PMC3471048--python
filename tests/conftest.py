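import pytest

from dualthreshold import BenefitHarmProfile, DualWeights


@pytest.fixture
def pe_worst_profile() -> BenefitHarmProfile:
    """Pulmonary-embolism worst-case evidence, system I harm-dominant by 0.10."""
    return BenefitHarmProfile(b2=0.175, h2=0.05, b1=0.175, h1=0.275)


@pytest.fixture
def pe_weights() -> DualWeights:
    return DualWeights(gamma=0.77, k=1.0)


@pytest.fixture
def aml_pessimistic() -> BenefitHarmProfile:
    """AML transplant evidence with felt harm doubled to 0.32."""
    return BenefitHarmProfile(b2=0.12, h2=0.16, b1=0.12, h1=0.32)


@pytest.fixture
def aml_optimistic() -> BenefitHarmProfile:
    """AML transplant evidence with felt harm halved to 0.08."""
    return BenefitHarmProfile(b2=0.12, h2=0.16, b1=0.12, h1=0.08)
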