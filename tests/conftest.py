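import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """1 subject, 16 trials, 4 classes, default montage — no effects."""
    from mifeatlab import generate_dataset

    return generate_dataset(1, 16, [], seed=11)


@pytest.fixture(scope="session")
def effect_dataset():
    """1 subject, 288 trials with a 4x alpha-band effect on channels 8 and 12."""
    from mifeatlab import EffectSpec, generate_dataset

    eff = EffectSpec(class_id=1, channels=(8, 12), band=(8.0, 13.0), power_ratio=4.0)
    return generate_dataset(1, 288, [eff], seed=5)
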