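import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "fixed",
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("fixed")
except ImportError:  # pragma: no cover
    pass

from sleepssm import Hypnogram, Stage

STAGES = [Stage.W, Stage.N1, Stage.N2, Stage.N3, Stage.REM]


@pytest.fixture
def rng():
    return np.random.default_rng(20240119)


def random_hypnogram(rng, n_epochs, p_wake=0.3):
    """Random (non-Markov) hypnogram for accounting/property checks."""
    labels = rng.choice(
        [s.value for s in STAGES],
        size=n_epochs,
        p=[p_wake] + [(1 - p_wake) / 4] * 4,
    )
    return Hypnogram(tuple(Stage(s) for s in labels))
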