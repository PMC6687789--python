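import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vmclust import GeneratorConfig, ShapeLabel, generate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def balanced_cohort():
    """Six-family balanced synthetic cohort at the default noise regime."""
    groups = {("boy", "1"): 150, ("girl", "1"): 150}
    freqs = {g: {s: 1 / 6 for s in ShapeLabel} for g in groups}
    config = GeneratorConfig(group_sizes=groups, shape_freqs=freqs, seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noise-free cohort: families are exactly their templates."""
    groups = {("boy", "1"): 60}
    freqs = {("boy", "1"): {s: 1 / 6 for s in ShapeLabel}}
    config = GeneratorConfig(group_sizes=groups, shape_freqs=freqs, noise_sd=0.0, seed=5)
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
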