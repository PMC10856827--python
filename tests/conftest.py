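import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitrel import synth

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """A cheap cohort: 3 runners x 2 days x 1 surface, 10 strides at 120 Hz."""
    return synth.SimulationConfig(
        n_participants=3,
        n_days=2,
        surfaces=("asphalt",),
        strides_per_run=10,
        sample_rate=120.0,
        gate_noise_sd=0.0,
        stride_freq_within_sd=0.0,
        seed=42,
    )


def noise_free_variances(runner: float = 4.0) -> dict:
    """Variance components with runner-level spread only (exact-arithmetic cases)."""
    return {
        sig: synth.LevelVariances(runner=runner) for sig in synth.DEFAULT_VARIANCES
    }


@pytest.fixture
def noise_free_config():
    """All level/noise variances zero except runner spread: fully deterministic runs."""
    return synth.SimulationConfig(
        n_participants=3,
        n_days=2,
        surfaces=("asphalt",),
        strides_per_run=10,
        sample_rate=120.0,
        variance_components=noise_free_variances(),
        gate_noise_sd=0.0,
        stride_freq_within_sd=0.0,
        period_jitter_frac=0.0,
        seed=7,
    )
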