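import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bicelle_config():
    """Fast-running bicelle config used across spectra/CLI tests."""
    from bicellesim.config import (AcquisitionConfig, DynamicsConfig,
                                   GeometryConfig, GridConfig,
                                   SimulationConfig, TensorConfig)
    return SimulationConfig(
        nucleus="N14", orientation="parallel",
        tensor=TensorConfig(magnitude=15e3),
        geometry=GeometryConfig(kind="bicelle", b_nm=2.0, d_nm=1.8, q=2.0),
        dynamics=DynamicsConfig(relative_rate=1e6),
        acquisition=AcquisitionConfig(lb_hz=120.0, n_points=1024,
                                      zero_fill=4),
        grid=GridConfig(n_theta=60, n_phi=6))
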