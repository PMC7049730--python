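import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def wildtype_apo_truth():
    """Two-conformer ground truth: closed 40.0 A / 15%, partially open 54.2 A / 85%."""
    from mrbiophys import ConformerTruth

    return ConformerTruth(((40.0, 0.15), (54.2, 0.85)))


@pytest.fixture
def noiseless():
    from mrbiophys import NoiseSpec

    return NoiseSpec("none")


@pytest.fixture
def biexp_trace():
    """Noiseless two-exponential decay with known components (no offset)."""
    from mrbiophys import DecayTrace

    t = np.linspace(0.0, 6000.0, 1200)
    amps, taus = np.array([0.4, 0.6]), np.array([400.0, 900.0])
    y = np.exp(-t[:, None] / taus[None, :]) @ amps
    return DecayTrace(t, y), amps, taus
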