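import numpy as np
import pytest

from brainmodes.decomposition import (
    ActivityMatrix,
    build_ensemble,
    decompose,
    zscore_time_courses,
)
from brainmodes.simulate import generate_basis, generate_session


@pytest.fixture(scope="session")
def small_basis():
    """50-node, 3-mode planted basis with 7 systems."""
    return generate_basis(50, 3, smoothness=10.0, seed=7)


@pytest.fixture(scope="session")
def default_basis():
    """Standard synthetic basis: 100 nodes, 5 planted modes."""
    return generate_basis(100, 5, smoothness=10.0, seed=1)


@pytest.fixture(scope="session")
def noisy_session(default_basis):
    return generate_session(default_basis, M=400, noise_sd=0.2, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_zscored_session(rng, n_nodes=8, n_time=20, label=""):
    X = rng.normal(size=(n_nodes, n_time))
    m = ActivityMatrix(
        values=X, node_ids=[f"n{i}" for i in range(n_nodes)], label=label
    )
    return zscore_time_courses(m)


@pytest.fixture()
def random_modeset(rng):
    sess = random_zscored_session(rng, n_nodes=6, n_time=30)
    ens = build_ensemble([sess])
    return decompose(ens), ens
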