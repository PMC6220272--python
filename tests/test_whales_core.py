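"""Descriptor core: weighted covariance, ACM, profiles, 33-vector.

The ACM implementation is checked against a naive per-pair oracle that
solves a 3x3 least-squares system for each (atom, centre) pair instead of
forming a pseudo-inverse, and the covariance against term-by-term
accumulation of the weighted outer products.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whales3d import (
    acm_matrix,
    atom_centered_covariance,
    atomic_profiles,
    compute_whales,
    make_point_cloud,
    parse_and_sanitize,
    whales_from_cloud,
    whales_vector,
)
from whales3d.structure_prep import HeavyAtomCloud
from whales3d.whales_core import (
    ACMMatrix,
    DESCRIPTOR_NAMES,
    DegenerateCloudError,
)

from conftest import random_cloud, random_rotation


# ---------------------------------------------------------------------------
# independent oracles

def covariance_oracle(cloud: HeavyAtomCloud, j: int) -> np.ndarray:
    """Accumulate Sum |d_i| (x_i-x_j)(x_i-x_j)^T / Sum |d_i| term by term."""
    S = np.zeros((3, 3))
    wsum = 0.0
    for i in range(cloud.n_atoms):
        w = abs(cloud.charges[i])
        d = cloud.coords[i] - cloud.coords[j]
        S += w * np.outer(d, d)
        wsum += w
    return S / wsum


def acm_oracle(cloud: HeavyAtomCloud) -> np.ndarray:
    """Per-pair linear solve: ACM(i,j) = d^T y with S_w(j) y = d (least
    squares for rank-deficient S)."""
    n = cloud.n_atoms
    out = np.zeros((n, n))
    for j in range(n):
        S = covariance_oracle(cloud, j)
        for i in range(n):
            if i == j:
                continue
            d = cloud.coords[i] - cloud.coords[j]
            y, *_ = np.linalg.lstsq(S, d, rcond=None)
            out[i, j] = float(d @ y)
    return out


# ---------------------------------------------------------------------------

class TestCovariance:
    def test_two_atom_forced_value(self):
        cloud = HeavyAtomCloud(
            mol_id="pair",
            coords=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            charges=np.ones(2),
            elements=["C", "C"],
        )
        cov = atom_centered_covariance(cloud, 0)
        np.testing.assert_allclose(cov.S_w, np.diag([0.5, 0.0, 0.0]), atol=1e-15)

    def test_weight_rescaling_cancels(self):
        cloud = random_cloud(6, seed=3)
        scaled = HeavyAtomCloud(
            mol_id="x", coords=cloud.coords, charges=5.0 * cloud.charges,
            elements=cloud.elements,
        )
        for j in range(cloud.n_atoms):
            np.testing.assert_allclose(
                atom_centered_covariance(cloud, j).S_w,
                atom_centered_covariance(scaled, j).S_w,
                atol=1e-12,
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_accumulation_oracle(self, seed):
        cloud = random_cloud(6, seed=seed)
        for j in range(cloud.n_atoms):
            np.testing.assert_allclose(
                atom_centered_covariance(cloud, j).S_w,
                covariance_oracle(cloud, j),
                atol=1e-12,
            )

    def test_symmetric_and_psd(self):
        cloud = random_cloud(8, seed=9)
        for j in range(8):
            S = atom_centered_covariance(cloud, j).S_w
            np.testing.assert_allclose(S, S.T, atol=1e-12)
            assert np.linalg.eigvalsh(S).min() > -1e-12

    def test_zero_weights_degenerate(self):
        cloud = HeavyAtomCloud(
            mol_id="zero", coords=np.eye(3), charges=np.zeros(3),
            elements=["C"] * 3,
        )
        with pytest.raises(DegenerateCloudError, match="degenerate weights"):
            atom_centered_covariance(cloud, 0)


class TestACM:
    def test_diagonal_zero_entries_nonnegative(self):
        acm = acm_matrix(random_cloud(7, seed=1)).values
        np.testing.assert_array_equal(np.diag(acm), 0.0)
        assert (acm >= 0).all()

    def test_rigid_motion_invariance(self):
        cloud = random_cloud(7, seed=2)
        R = random_rotation(5)
        moved = HeavyAtomCloud(
            mol_id="x", coords=cloud.coords @ R.T + np.array([10.0, -3.0, 7.0]),
            charges=cloud.charges, elements=cloud.elements,
        )
        np.testing.assert_allclose(
            acm_matrix(cloud).values, acm_matrix(moved).values, atol=1e-8
        )

    def test_tetrahedron_off_diagonals_all_equal_oracle(self):
        cloud = make_point_cloud("tetrahedron", 4)
        acm = acm_matrix(cloud).values
        oracle = acm_oracle(cloud)
        np.testing.assert_allclose(acm, oracle, atol=1e-10)
        off = acm[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, off[0], atol=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_linear_solve_oracle(self, seed):
        n = 3 + seed % 6
        cloud = random_cloud(n, seed=100 + seed)
        np.testing.assert_allclose(
            acm_matrix(cloud).values, acm_oracle(cloud), atol=1e-10
        )

    @pytest.mark.parametrize("geometry", ["line", "plane"])
    def test_rank_deficient_geometries_match_oracle(self, geometry):
        cloud = make_point_cloud(geometry, 5, seed=4)
        np.testing.assert_allclose(
            acm_matrix(cloud).values, acm_oracle(cloud), atol=1e-8
        )

    def test_single_atom_undefined(self):
        cloud = HeavyAtomCloud(
            mol_id="lone", coords=np.zeros((1, 3)), charges=np.ones(1),
            elements=["C"],
        )
        with pytest.raises(DegenerateCloudError, match="ACM undefined"):
            acm_matrix(cloud)

    def test_sqrt_variant_is_elementwise_root(self):
        cloud = random_cloud(6, seed=6)
        np.testing.assert_allclose(
            acm_matrix(cloud, sqrt=True).values,
            np.sqrt(acm_matrix(cloud).values),
            atol=1e-12,
        )


class TestProfiles:
    def test_integer_matrix_hand_computed(self):
        A = np.array(
            [
                [0, 2, 6, 4],
                [1, 0, 3, 8],
                [5, 7, 0, 2],
                [9, 1, 4, 0],
            ],
            dtype=float,
        )
        prof = atomic_profiles(ACMMatrix(values=A), charges=np.ones(4))
        np.testing.assert_allclose(prof.remoteness, [4, 4, 14 / 3, 14 / 3])
        np.testing.assert_allclose(prof.isolation, [1, 1, 3, 2])
        np.testing.assert_allclose(
            prof.ratio, [1 / 4, 1 / 4, 3 / (14 / 3), 2 / (14 / 3)]
        )

    def test_all_positive_charges_nonnegative_profiles(self):
        cloud = random_cloud(6, seed=8, charged=False)
        prof = atomic_profiles(acm_matrix(cloud), cloud.charges)
        assert (prof.remoteness >= 0).all()
        assert (prof.isolation >= 0).all()
        assert (prof.ratio >= 0).all()

    def test_negative_atom_gets_negative_values(self):
        cloud = random_cloud(5, seed=12, charged=False)
        charges = cloud.charges.copy()
        charges[2] = -0.30
        acm = acm_matrix(
            HeavyAtomCloud(mol_id="x", coords=cloud.coords, charges=charges,
                           elements=cloud.elements)
        )
        prof = atomic_profiles(acm, charges)
        assert prof.sign_mask[2]
        assert prof.remoteness[2] <= 0
        assert prof.isolation[2] <= 0
        assert prof.ratio[2] <= 0

    def test_ratio_magnitude_identity(self):
        cloud = random_cloud(7, seed=13)
        prof = atomic_profiles(acm_matrix(cloud), cloud.charges)
        np.testing.assert_allclose(
            np.abs(prof.ratio),
            np.abs(prof.isolation) / np.abs(prof.remoteness),
            atol=1e-12,
        )

    def test_coincident_atoms_ratio_zero_with_warning(self):
        cloud = HeavyAtomCloud(
            mol_id="dup", coords=np.zeros((2, 3)), charges=np.ones(2),
            elements=["C", "C"],
        )
        with pytest.warns(UserWarning, match="zero remoteness"):
            prof = atomic_profiles(acm_matrix(cloud), cloud.charges)
        np.testing.assert_array_equal(prof.ratio, 0.0)


class TestWhalesVector:
    def test_equally_spaced_eleven_values(self):
        prof = atomic_profiles(
            acm_matrix(random_cloud(4, seed=1)), np.ones(4)
        )
        # overwrite with a crafted profile: {1..11} for every property
        crafted = type(prof)(
            remoteness=np.arange(1.0, 12.0),
            isolation=np.arange(1.0, 12.0),
            ratio=np.arange(1.0, 12.0),
            sign_mask=np.zeros(11, dtype=bool),
        )
        vec = whales_vector(crafted)
        np.testing.assert_allclose(vec.values[:11], np.arange(1.0, 12.0))

    def test_constant_profile_all_stats_equal(self):
        prof = atomic_profiles(
            acm_matrix(make_point_cloud("tetrahedron", 4)), np.ones(4)
        )
        vec = whales_vector(prof)
        # tetrahedron: every atom identical by symmetry -> each block constant
        for block in range(3):
            b = vec.values[11 * block : 11 * (block + 1)]
            np.testing.assert_allclose(b, b[0], atol=1e-10)

    def test_length_33_for_small_and_large(self):
        for n in (2, 200):
            vec = whales_from_cloud(random_cloud(n, seed=n))
            assert vec.values.shape == (33,)
            assert vec.names == DESCRIPTOR_NAMES

    def test_blocks_nondecreasing(self):
        vec = whales_from_cloud(random_cloud(15, seed=21))
        for block in range(3):
            b = vec.values[11 * block : 11 * (block + 1)]
            assert (np.diff(b) >= -1e-12).all()


class TestPipelineInvariances:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 12))
    def test_rigid_motion_and_weight_scale_invariance(self, seed, n):
        cloud = random_cloud(n, seed=seed)
        base = whales_from_cloud(cloud).values
        R = random_rotation(seed + 1)
        moved = HeavyAtomCloud(
            mol_id="x", coords=cloud.coords @ R.T + 3.0,
            charges=2.5 * cloud.charges, elements=cloud.elements,
        )
        np.testing.assert_allclose(whales_from_cloud(moved).values, base, atol=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 12))
    def test_atom_order_permutation_invariance(self, seed, n):
        cloud = random_cloud(n, seed=seed)
        perm = np.random.default_rng(seed).permutation(n)
        permuted = HeavyAtomCloud(
            mol_id="x", coords=cloud.coords[perm], charges=cloud.charges[perm],
            elements=[cloud.elements[i] for i in perm],
        )
        np.testing.assert_allclose(
            whales_from_cloud(permuted).values,
            whales_from_cloud(cloud).values,
            atol=1e-8,
        )

    def test_translation_invariance_with_input_coords(self):
        rec = parse_and_sanitize("CCO", "ethanol")
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [2.1, 1.2, 0.2]])
        a = compute_whales(rec, scheme="unit", coords=coords)
        b = compute_whales(rec, scheme="unit", coords=coords + 100.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)

    def test_charge_scheme_changes_polar_molecule_vector(self):
        rec = parse_and_sanitize("c1ccncc1", "pyridine")
        unit = compute_whales(rec, scheme="unit", seed=3)
        gm = compute_whales(rec, scheme="gasteiger_marsili", seed=3)
        assert not np.allclose(unit.values, gm.values)

    def test_deterministic_given_seed(self):
        rec = parse_and_sanitize("CC(=O)Nc1ccc(O)cc1", "paracetamol")
        a = compute_whales(rec, seed=5)
        b = compute_whales(rec, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
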