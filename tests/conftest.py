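import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kinpot import (
    AntioxidantSpec,
    ExperimentConfig,
    RateParameters,
    generate_trace,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> RateParameters:
    """Reference assay conditions: 0.1 M AAPH at 37 degC, Wi = 2e-7 M/s."""
    return RateParameters()


def noise_free_trace(antioxidants, duration=1800.0, t_add=300.0):
    cfg = ExperimentConfig(
        antioxidants=antioxidants,
        t_add=t_add,
        duration=duration,
        noise_sigma=0.0,
        drift_sigma=0.0,
    )
    trace, truth = generate_trace(cfg)
    return trace, truth


@pytest.fixture(scope="session")
def fast_trace_075():
    """0.075 mM fast antioxidant (ascorbate-like), noise-free."""
    return noise_free_trace([AntioxidantSpec("asc", 7.5e-5, 3.95e3, 2.0)])[0]


@pytest.fixture(scope="session")
def fast_trace_01():
    """0.1 mM fast antioxidant, noise-free, long run."""
    return noise_free_trace([AntioxidantSpec("asc", 1e-4, 3.95e3, 2.0)], 2400.0)[0]


@pytest.fixture(scope="session")
def slow_trace():
    """0.1 mM slow antioxidant (tocopherol-like), noise-free."""
    return noise_free_trace([AntioxidantSpec("toh", 1e-4, 7.5e2, 2.0)], 1500.0)[0]


@pytest.fixture(scope="session")
def control_trace():
    """No inhibitor: monotone potential rise."""
    return noise_free_trace([], 1800.0)[0]


@pytest.fixture(scope="session")
def mixture_trace():
    """Equimolar fast + slow mixture at 0.075 mM each, noise-free."""
    aos = [
        AntioxidantSpec("asc", 7.5e-5, 3.95e3, 2.0),
        AntioxidantSpec("toh", 7.5e-5, 7.5e2, 2.0),
    ]
    return noise_free_trace(aos, 3000.0)[0]
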