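import numpy as np
import pytest

from whales3d import FixtureSpec, make_screening_fixture
from whales3d.structure_prep import HeavyAtomCloud


@pytest.fixture(scope="session")
def small_fixture():
    """60-molecule, 5-family, 2-target screening fixture."""
    return make_screening_fixture(
        FixtureSpec(seed=7, n_molecules=60, n_scaffold_families=5,
                    n_targets=2, actives_per_target=10)
    )


@pytest.fixture(scope="session")
def bench_fixture():
    """200-molecule, 2-target fixture at benchmark scale (20 actives each)."""
    return make_screening_fixture(
        FixtureSpec(seed=11, n_molecules=200, n_scaffold_families=5,
                    n_targets=2, actives_per_target=20)
    )


def random_cloud(n: int, seed: int, charged: bool = True) -> HeavyAtomCloud:
    """Seeded random heavy-atom cloud with nonzero weights."""
    rng = np.random.default_rng(seed)
    coords = 2.0 * rng.standard_normal((n, 3))
    if charged:
        charges = rng.uniform(-0.5, 0.5, size=n)
        charges[np.abs(charges) < 1e-3] = 0.1  # keep weights clearly nonzero
    else:
        charges = np.ones(n)
    return HeavyAtomCloud(
        mol_id=f"rnd{n}_{seed}", coords=coords, charges=charges,
        elements=["C"] * n,
    )


def random_rotation(seed: int) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
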