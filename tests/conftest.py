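import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from morphosvm.cohort import CohortSpec, EffectSpec, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_signal_cohort():
    """Small cohort with one strongly planted GM effect: cheap enough for
    per-test LOOCV while still carrying reliably recoverable signal."""
    spec = CohortSpec(
        n_per_group={"BD": 5, "HC": 5},
        volume_shape=(8, 8, 8),
        effects=[EffectSpec(region_center=(4, 4, 4), region_radius=2.0,
                            effect_size=4.0)],
        seed=42,
    )
    return generate_cohort(spec)
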