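import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tumblefit.dynamics import EquationParams, OblateGeometry
from tumblefit.preprocess import preprocess_series
from tumblefit.synthetic import ScenarioSpec, generate_ground_truth

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def platelet():
    """Default platelet geometry: a = 2 um, b = 0.5 um, e = 4."""
    return OblateGeometry(semi_major=2.0, semi_minor=0.5)


@pytest.fixture(scope="session")
def sphere():
    return OblateGeometry(semi_major=1.0, semi_minor=1.0)


@pytest.fixture(scope="session")
def joe_processed_stream():
    """Noise-free classical-dynamics stream, preprocessed, 12 time units."""
    scenario = ScenarioSpec(duration=12.0, seed=0)
    series = generate_ground_truth(scenario)
    return preprocess_series(series.samples)


@pytest.fixture(scope="session")
def angle_grid():
    return np.linspace(-2.0 * np.pi, 2.0 * np.pi, 541)
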