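import numpy as np
import pytest

from tetrastab.core import ChainPairing
from tetrastab.saltbridge import enumerate_arrangements
from tetrastab.synthetic import ToyTetramerSpec, TrajectorySimConfig, make_toy_tetramer, simulate_trajectory


@pytest.fixture(scope="session")
def toy_spec():
    return ToyTetramerSpec()


@pytest.fixture(scope="session")
def tetramer(toy_spec):
    return make_toy_tetramer(toy_spec, seed=0)


@pytest.fixture(scope="session")
def pairing():
    return ChainPairing.from_string("A:B,C:D")


@pytest.fixture(scope="session")
def arrangements(pairing, tetramer):
    return enumerate_arrangements(pairing, 337, 352, tetramer)


@pytest.fixture(scope="session")
def stable_traj(tetramer, toy_spec):
    cfg = TrajectorySimConfig(n_frames=50, sigma=0.3, mode="stable", seed=11)
    traj, truth = simulate_trajectory(tetramer, cfg, toy_spec)
    return traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_points(rng, n, scale=5.0):
    """Well-spread random 3-D configuration (retries near-degenerate draws)."""
    while True:
        pts = rng.uniform(-scale, scale, size=(n, 3))
        centered = pts - pts.mean(axis=0)
        if np.linalg.eigvalsh(centered.T @ centered)[1] > 0.5:
            return pts
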