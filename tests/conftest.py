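import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from imerelax import EchoScheme, PoolSystem


@pytest.fixture(scope="session")
def echo_times_s() -> np.ndarray:
    """The 40-echo acquisition scheme, in seconds."""
    return EchoScheme().times_s()


@pytest.fixture(scope="session")
def worked_two_pool() -> PoolSystem:
    """The discussion's exchange example: T2 = 50/150 ms, 75/25 split,
    200 ms long-pool residence time."""
    return PoolSystem.two_pool(0.75, 0.05, 0.15, residence_long=0.2)


def random_balanced_system(rng: np.random.Generator, n_pools: int) -> PoolSystem:
    """Random detailed-balanced pool system with separated T2s."""
    fractions = rng.dirichlet(np.full(n_pools, 4.0))
    fractions = 0.1 + 0.9 * fractions / fractions.sum()  # keep pools non-tiny
    fractions = fractions / fractions.sum()
    t2 = np.sort(10 ** rng.uniform(np.log10(0.02), np.log10(0.25), n_pools))
    flux = np.zeros((n_pools, n_pools))
    for i in range(n_pools):
        for j in range(i + 1, n_pools):
            flux[i, j] = flux[j, i] = rng.uniform(0.0, 0.4)
    k = flux / fractions[:, None]  # k_ij = F_ij / f_i satisfies detailed balance
    np.fill_diagonal(k, 0.0)
    return PoolSystem(fractions=fractions, t2=t2, k=k)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> Path:
    """A small synthetic study bundle shared across pipeline tests."""
    from imerelax.synthetic import generate_study

    out = tmp_path_factory.mktemp("bundle") / "study"
    generate_study(
        {
            "n_animals": 2,
            "n_histology": 1,
            "n_voxels": 4,
            "histology": {"grid": [300, 400], "fov_um": [22.5, 30.0]},
        },
        seed=11,
        out_dir=out,
    )
    return out
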