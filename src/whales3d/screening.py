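"""Similarity screening: Euclidean ranking on Gaussian-normalized descriptors
and reciprocal-rank fusion over multiple queries.

Each descriptor column is standardized to zero mean and unit (population)
standard deviation before distances are taken; zero-variance columns
contribute nothing but are kept so dimensionality and column order are stable.
Multi-query campaigns are fused by the sum of reciprocal ranks, which favours
compounds ranked early by at least one query.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .whales_core import DESCRIPTOR_NAMES, WhalesVector

#: columns with population std below this are treated as constant
ZERO_VARIANCE_TOL = 1e-12


@dataclass(frozen=True)
class DescriptorMatrix:
    mol_ids: tuple[str, ...]
    X: np.ndarray  # (m, p)
    column_names: tuple[str, ...] = DESCRIPTOR_NAMES

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "mol_ids", tuple(self.mol_ids))
        object.__setattr__(self, "column_names", tuple(self.column_names))
        if X.shape != (len(self.mol_ids), len(self.column_names)):
            raise ValueError(
                f"matrix shape {X.shape} inconsistent with {len(self.mol_ids)} ids "
                f"x {len(self.column_names)} columns"
            )
        if np.isnan(X).any():
            raise ValueError("descriptor matrix contains missing values")
        if len(set(self.mol_ids)) != len(self.mol_ids):
            raise ValueError("mol_ids are not unique")

    @classmethod
    def from_vectors(
        cls, items: Iterable[tuple[str, WhalesVector]]
    ) -> "DescriptorMatrix":
        items = list(items)
        if not items:
            raise ValueError("no descriptor vectors")
        return cls(
            mol_ids=tuple(mid for mid, _ in items),
            X=np.vstack([vec.values for _, vec in items]),
            column_names=items[0][1].names,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=list(self.mol_ids),
                            columns=list(self.column_names))


@dataclass(frozen=True)
class NormalizationStats:
    mean: np.ndarray
    std: np.ndarray
    zero_variance_mask: np.ndarray


@dataclass(frozen=True)
class RankedHitList:
    """Per-query ranking: (mol_id, distance, rank starting at 1), distances
    nondecreasing, distance ties broken by mol_id."""

    query_id: str
    entries: tuple[tuple[str, float, int], ...]

    def rank_of(self, mol_id: str) -> int:
        for mid, _, rank in self.entries:
            if mid == mol_id:
                return rank
        raise KeyError(mol_id)

    @property
    def mol_ids(self) -> tuple[str, ...]:
        return tuple(mid for mid, _, _ in self.entries)


@dataclass(frozen=True)
class FusedRanking:
    """(mol_id, sum of reciprocal per-query ranks), scores nonincreasing."""

    entries: tuple[tuple[str, float], ...]

    @property
    def mol_ids(self) -> tuple[str, ...]:
        return tuple(mid for mid, _ in self.entries)


def fit_normalization(lib: DescriptorMatrix) -> NormalizationStats:
    """Per-column mean and population standard deviation (divisor m)."""
    if lib.X.shape[0] < 2:
        raise ValueError("need at least 2 library molecules to fit normalization")
    mean = lib.X.mean(axis=0)
    std = lib.X.std(axis=0, ddof=0)
    return NormalizationStats(
        mean=mean, std=std, zero_variance_mask=std < ZERO_VARIANCE_TOL
    )


def _standardize(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    safe_std = np.where(stats.zero_variance_mask, 1.0, stats.std)
    Z = (X - stats.mean) / safe_std
    Z[..., stats.zero_variance_mask] = 0.0  # constant columns contribute nothing
    return Z


def rank_by_distance(
    query: WhalesVector | np.ndarray,
    lib: DescriptorMatrix,
    stats: NormalizationStats,
    query_id: str = "query",
    exclude_self: bool = False,
) -> RankedHitList:
    """Rank the library by Euclidean distance to the query in standardized
    descriptor space; ties broken lexicographically by mol_id."""
    q = query.values if isinstance(query, WhalesVector) else np.asarray(query, float)
    if q.shape != (lib.X.shape[1],):
        raise ValueError(
            f"query has {q.shape} values, library columns {lib.X.shape[1]}"
        )
    keep = np.ones(len(lib.mol_ids), dtype=bool)
    if exclude_self and query_id in lib.mol_ids:
        keep[lib.mol_ids.index(query_id)] = False
    ids = [mid for mid, k in zip(lib.mol_ids, keep) if k]
    Z = _standardize(lib.X[keep], stats)
    zq = _standardize(q, stats)
    dist = np.linalg.norm(Z - zq, axis=1)
    order = sorted(range(len(ids)), key=lambda i: (dist[i], ids[i]))
    entries = tuple(
        (ids[i], float(dist[i]), rank) for rank, i in enumerate(order, start=1)
    )
    return RankedHitList(query_id=query_id, entries=entries)


def fuse_reciprocal_ranks(lists: Sequence[RankedHitList]) -> FusedRanking:
    """Fuse per-query rankings by the sum of reciprocal ranks; sorted
    descending by score, score ties broken by mol_id."""
    if not lists:
        raise ValueError("no rankings to fuse")
    reference = set(lists[0].mol_ids)
    for hl in lists[1:]:
        other = set(hl.mol_ids)
        if other != reference:
            diff = sorted(reference.symmetric_difference(other))
            raise ValueError(f"inconsistent library sets across queries: {diff}")
    scores: dict[str, float] = {mid: 0.0 for mid in reference}
    for hl in lists:
        for mid, _, rank in hl.entries:
            scores[mid] += 1.0 / rank
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return FusedRanking(entries=tuple((mid, float(s)) for mid, s in ordered))
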