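import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pfasmix import simulate as sim  # noqa: E402
from pfasmix import mixture as mx  # noqa: E402


@pytest.fixture(scope="session")
def presets():
    """Calibrated truth curves for the four PFAS."""
    return sim.default_presets()


@pytest.fixture(scope="session")
def preset_curves(presets):
    return {k: p.curve for k, p in presets.items()}


@pytest.fixture(scope="session")
def equipotent_design():
    """Fixed-ratio mixture at the component BMC10 values (78.5 µM basis)."""
    return mx.build_design(sim.REFERENCE_BMC10_UM, mixture_id="equipotent")


@pytest.fixture()
def zero_noise():
    return sim.NoiseModel(sigma_within=0.0, sigma_between=0.0, seed=0)


@pytest.fixture()
def default_noise():
    return sim.NoiseModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
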