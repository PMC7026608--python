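import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from noeme.synthetic import StateSpec, generate_toy_ensemble

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TWO_STATE_SPECS = [
    StateSpec("syn25", 0.6, syn_residues=(2, 5)),
    StateSpec("anti", 0.4),
]


@pytest.fixture(scope="session")
def two_state():
    """Small two-state ensemble with labels: syn at residues 2+5 vs all-anti."""
    ensemble, labels = generate_toy_ensemble(7, TWO_STATE_SPECS, 30, seed=11)
    return ensemble, labels


@pytest.fixture(scope="session")
def two_state_large():
    ensemble, labels = generate_toy_ensemble(7, TWO_STATE_SPECS, 120, seed=5)
    return ensemble, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_snapshot(rng, n_residues=4, noise=0.3):
    """A geometrically jittered single snapshot for metric tests."""
    states = [StateSpec("s", 1.0, syn_residues=(2,))]
    ens, _ = generate_toy_ensemble(
        n_residues, states, 1, seed=int(rng.integers(2**31)), noise=noise
    )
    return ens[0]
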