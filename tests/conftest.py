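import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pmpkit import DonorProfile, PerfusionSettings, Sex


@pytest.fixture
def male_donor() -> DonorProfile:
    return DonorProfile(sex=Sex.male, body_weight=80.0)


@pytest.fixture
def female_donor() -> DonorProfile:
    return DonorProfile(sex=Sex.female, body_weight=70.0)


@pytest.fixture
def settings_700() -> PerfusionSettings:
    return PerfusionSettings(cbf_setting=700.0, mean_aortic_pressure=75.0)
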