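"""WHALES descriptor core: charge-weighted covariance, atom-centred
Mahalanobis distances, atomic profiles, and the 33-value vector.

For each heavy atom j the charge-weighted covariance

    S_w(j) = sum_i |d_i| (x_i - x_j)(x_i - x_j)^T / sum_i |d_i|

defines a local metric; the atom-centred Mahalanobis (ACM) matrix holds the
quadratic forms ACM(i, j) = (x_i - x_j)^T S_w(j)^+ (x_i - x_j). Per-atom
remoteness (row average), isolation degree (column minimum) and their ratio —
sign-flipped for negatively charged atoms — are summarized by min, nine
deciles and max into 33 molecular-size-independent values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structure_prep import ChargeScheme, HeavyAtomCloud, MoleculeRecord, \
    assign_charges, embed_lowest_energy_conformer

#: relative singular-value cutoff for the pseudo-inverse of rank-deficient
#: covariances (planar / linear / two-atom geometries)
PINV_RCOND = 1e-8

#: column names of the 33-value descriptor, fixed block order
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    f"{block}_{stat}"
    for block in ("rem", "is", "ir")
    for stat in ["min", *[f"d{k}" for k in range(1, 10)], "max"]
)


class DegenerateCloudError(ValueError):
    """Cloud cannot support the descriptor (single atom or zero weights)."""


@dataclass(frozen=True)
class AtomCenteredCovariance:
    center_index: int
    S_w: np.ndarray  # (3, 3), symmetric PSD


@dataclass(frozen=True)
class ACMMatrix:
    """Column j holds distances from centre j to every atom; diagonal is 0.
    Not symmetric in general — each column uses its own local metric."""

    values: np.ndarray  # (n, n)


@dataclass(frozen=True)
class AtomProfile:
    remoteness: np.ndarray
    isolation: np.ndarray
    ratio: np.ndarray
    sign_mask: np.ndarray  # True where the atom carries negative charge


@dataclass(frozen=True)
class WhalesVector:
    values: np.ndarray  # (33,)
    names: tuple[str, ...] = DESCRIPTOR_NAMES


def _check_weights(charges: np.ndarray, mol_id: str = "") -> np.ndarray:
    w = np.abs(np.asarray(charges, dtype=float))
    if np.isnan(w).any():
        raise DegenerateCloudError(f"{mol_id}: charges unset (NaN)")
    # benzene-like symmetric molecules can fold to exactly zero per-atom
    # charge; a tiny tolerance also catches the float residue of that case
    if w.sum() < 1e-12:
        raise DegenerateCloudError(f"{mol_id}: degenerate weights (sum |delta| = 0)")
    return w


def atom_centered_covariance(cloud: HeavyAtomCloud, j: int) -> AtomCenteredCovariance:
    """Charge-weighted covariance of atom positions about centre ``j``."""
    if cloud.n_atoms < 2:
        raise DegenerateCloudError(f"{cloud.mol_id}: need >= 2 atoms")
    w = _check_weights(cloud.charges, cloud.mol_id)
    diff = cloud.coords - cloud.coords[j]  # (n, 3); row j is zero
    S = (diff.T * w) @ diff / w.sum()
    S = 0.5 * (S + S.T)  # symmetrize away accumulation noise
    return AtomCenteredCovariance(center_index=int(j), S_w=S)


def acm_matrix(cloud: HeavyAtomCloud, sqrt: bool = False) -> ACMMatrix:
    """Atom-centred Mahalanobis matrix; ``sqrt`` gives the rooted variant.

    Rank-deficient covariances (collinear or coplanar clouds) are handled by
    the Moore-Penrose pseudo-inverse with relative cutoff ``PINV_RCOND``.
    """
    n = cloud.n_atoms
    if n < 2:
        raise DegenerateCloudError(
            f"{cloud.mol_id}: single-atom molecule: ACM undefined"
        )
    w = _check_weights(cloud.charges, cloud.mol_id)
    x = cloud.coords
    out = np.empty((n, n))
    for j in range(n):
        diff = x - x[j]
        S = (diff.T * w) @ diff / w.sum()
        S_inv = np.linalg.pinv(0.5 * (S + S.T), rcond=PINV_RCOND, hermitian=True)
        q = np.einsum("ik,kl,il->i", diff, S_inv, diff)
        out[:, j] = np.maximum(q, 0.0)
    np.fill_diagonal(out, 0.0)
    if sqrt:
        out = np.sqrt(out)
    return ACMMatrix(values=out)


def atomic_profiles(acm: ACMMatrix, charges: np.ndarray) -> AtomProfile:
    """Remoteness (row average), isolation (column minimum) and their ratio,
    diagonal excluded; all three are negated for atoms with ``delta_i < 0``."""
    A = np.asarray(acm.values, dtype=float)
    n = A.shape[0]
    if n < 2 or A.shape[1] != n:
        raise DegenerateCloudError("ACM must be n x n with n >= 2")
    if not np.allclose(np.diag(A), 0.0):
        raise ValueError("ACM diagonal must be zero")
    off = ~np.eye(n, dtype=bool)
    rem = A.sum(axis=1) / (n - 1)  # diagonal is zero, so sum/(n-1) is the off-diagonal mean
    iso = np.where(off, A, np.inf).min(axis=0)
    sign_mask = np.asarray(charges, dtype=float) < 0.0
    sign = np.where(sign_mask, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(iso) / np.abs(rem)
    zero_rem = np.abs(rem) == 0.0
    if zero_rem.any():
        warnings.warn(
            "zero remoteness (coincident atoms): ratio set to 0", stacklevel=2
        )
        ratio[zero_rem] = 0.0
    return AtomProfile(
        remoteness=sign * rem,
        isolation=sign * iso,
        ratio=sign * ratio,
        sign_mask=sign_mask,
    )


def _block_stats(values: np.ndarray) -> np.ndarray:
    """min, deciles d1..d9 (linear-interpolation quantiles) and max."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateCloudError("empty profile")
    return np.percentile(v, np.arange(0, 101, 10), method="linear")


def whales_vector(profile: AtomProfile) -> WhalesVector:
    """Concatenate the 11 distribution statistics of remoteness, isolation
    and their ratio into the fixed-order 33-value descriptor."""
    values = np.concatenate(
        [
            _block_stats(profile.remoteness),
            _block_stats(profile.isolation),
            _block_stats(profile.ratio),
        ]
    )
    return WhalesVector(values=values)


def whales_from_cloud(cloud: HeavyAtomCloud, sqrt: bool = False) -> WhalesVector:
    """Descriptor from an already-charged cloud (covariance → ACM → profiles
    → statistics)."""
    acm = acm_matrix(cloud, sqrt=sqrt)
    profile = atomic_profiles(acm, cloud.charges)
    return whales_vector(profile)


def compute_whales(
    rec: MoleculeRecord,
    scheme: ChargeScheme | str = ChargeScheme.GASTEIGER_MARSILI,
    seed: int = 0,
    n_confs: int = 10,
    max_iters: int = 1000,
    fold_h_charges: bool = True,
    sqrt: bool = False,
    coords: Optional[np.ndarray] = None,
    charge_file=None,
) -> WhalesVector:
    """Full pipeline for one sanitized record: embed (or use supplied
    coordinates), charge, and reduce to the 33-value vector. Deterministic
    given ``seed``."""
    cloud = embed_lowest_energy_conformer(
        rec, n_confs=n_confs, max_iters=max_iters, seed=seed, coords=coords
    )
    cloud = assign_charges(
        cloud, scheme=scheme, charge_file=charge_file, fold_h_charges=fold_h_charges
    )
    return whales_from_cloud(cloud, sqrt=sqrt)
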