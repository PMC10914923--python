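import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240305)


@pytest.fixture
def quiet_experiment():
    """Small noise-free experiment: exact arithmetic end to end."""
    from sangeredit.synthdata import EditSpec, TraceModel, simulate_experiment

    model = TraceModel(amplitude_cv=0.0, crosstalk=0.0, noise_sd=0.0)
    reference = "CTACTATCACT"
    edits = EditSpec(edits=[(3, 0.5)], edit_mode="A_to_G")
    return simulate_experiment(reference, edits, model,
                               n_sample=3, n_control=3, seed=0)
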