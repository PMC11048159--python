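import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """Minimal fast generator config (20-min sessions, 3 per phase)."""
    from wristmetrics.synthetic import GeneratorConfig

    return GeneratorConfig(
        n_children=4,
        sessions_per_phase=3,
        session_len_s=1200,
        n_short_early_children=0,
        n_unaffected_missing_children=0,
        seed=11,
    )


@pytest.fixture
def deterministic_config():
    """Degenerate config: no noise or jitter, symmetric arms."""
    from wristmetrics.synthetic import GeneratorConfig

    return GeneratorConfig(
        n_children=1,
        sessions_per_phase=3,
        session_len_s=1200,
        asymmetry_scale=1.0,
        asymmetry_jitter_sd=0.0,
        active_time_ratio=1.0,
        active_ratio_jitter_sd=0.0,
        noise_cv=0.0,
        n_short_early_children=0,
        n_unaffected_missing_children=0,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
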