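"""Scaffold-hopping evaluation: Bemis-Murcko scaffolds, relative scaffold
diversity of actives (SD_A%), enrichment factors, the leave-one-active-out
retrospective benchmark, and Best/Worst-augmented PCA over descriptor sets.

SD_A% of a ranked list is 100 * ns / na, where na is the number of actives
in the top fraction (default 5%) and ns the number of unique Murcko
scaffolds among those actives: a high value means the actives that were
retrieved early are structurally diverse (scaffold hopping), a low value
means they share the query's framework.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .screening import (
    DescriptorMatrix,
    FusedRanking,
    RankedHitList,
    fit_normalization,
    rank_by_distance,
)
from .structure_prep import MoleculeRecord

#: scaffold key shared by all acyclic molecules (Murcko framework is empty)
ACYCLIC_SENTINEL = ""


@dataclass(frozen=True)
class ActivityTable:
    """(mol_id, target_id, label) rows; label is 'active' or 'inactive'."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"mol_id", "target_id", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"activity table needs columns {sorted(required)}")
        if df.duplicated(subset=["mol_id", "target_id"]).any():
            raise ValueError("duplicate (mol_id, target_id) rows")
        bad = set(df["label"]) - {"active", "inactive"}
        if bad:
            raise ValueError(f"unknown activity labels: {sorted(bad)}")

    def actives(self, target_id: str) -> list[str]:
        df = self.frame
        sel = (df["target_id"] == target_id) & (df["label"] == "active")
        return df.loc[sel, "mol_id"].tolist()

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.frame["target_id"].unique())

    @classmethod
    def from_rows(cls, rows: Sequence[tuple[str, str, str]]) -> "ActivityTable":
        return cls(pd.DataFrame(rows, columns=["mol_id", "target_id", "label"]))


def murcko_scaffold(rec: MoleculeRecord | str) -> str:
    """Canonical SMILES of the Bemis-Murcko framework (ring systems plus
    linkers, side chains removed); acyclic molecules share the empty
    sentinel key."""
    smiles = rec.smiles if isinstance(rec, MoleculeRecord) else rec
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
    return scaffold if scaffold else ACYCLIC_SENTINEL


def _top_ids(ranked: RankedHitList | FusedRanking, fraction: float) -> list[str]:
    ids = list(ranked.mol_ids)
    if not ids:
        raise ValueError("empty ranking")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n_top = max(1, math.floor(fraction * len(ids)))
    return ids[:n_top]


def sda_percent(
    ranked: RankedHitList | FusedRanking,
    activity: ActivityTable,
    scaffolds: Mapping[str, str],
    target_id: str,
    fraction: float = 0.05,
) -> Optional[float]:
    """Relative scaffold diversity of actives in the top ``fraction`` of the
    ranking: 100 * (unique active scaffolds) / (actives). None when the top
    segment contains no active (0/0)."""
    top = _top_ids(ranked, fraction)
    active_set = set(activity.actives(target_id))
    top_actives = [mid for mid in top if mid in active_set]
    if not top_actives:
        return None
    unique_scaffolds = {scaffolds[mid] for mid in top_actives}
    return 100.0 * len(unique_scaffolds) / len(top_actives)


def enrichment_factor(
    ranked: RankedHitList | FusedRanking,
    activity: ActivityTable,
    target_id: str,
    fraction: float = 0.01,
) -> float:
    """EF_f = (actives in top segment / segment size) / (actives / library).

    The library is whatever the ranking covers, so a self-excluded query is
    counted in neither numerator nor denominator.
    """
    top = _top_ids(ranked, fraction)
    ids = list(ranked.mol_ids)
    active_set = set(activity.actives(target_id)) & set(ids)
    if not active_set:
        raise ValueError(f"no actives for target {target_id!r} in the ranking")
    na_top = sum(1 for mid in top if mid in active_set)
    return (na_top / len(top)) / (len(active_set) / len(ids))


@dataclass(frozen=True)
class BenchmarkResult:
    """Long-format per-(target, descriptor-set) medians over the
    leave-one-active-out runs."""

    frame: pd.DataFrame  # columns: target_id, descriptor, sda_percent, ef, n_queries


def run_retrospective_benchmark(
    descriptors: Mapping[str, DescriptorMatrix],
    activity: ActivityTable,
    scaffolds: Mapping[str, str],
    min_actives: int = 20,
    fraction_sda: float = 0.05,
    fraction_ef: float = 0.01,
) -> BenchmarkResult:
    """Leave-one-active-out retrospective screen.

    For each target with at least ``min_actives`` annotated actives and each
    descriptor set, every active is used in turn as the query against the
    full library (self excluded); SD_A% and EF are computed per run and
    aggregated as the median over runs (runs with no retrieved active are
    excluded from the SD_A% median).
    """
    rows = []
    kept_any = False
    for name, lib in descriptors.items():
        stats = fit_normalization(lib)  # retrospective: queries are library members
        id_to_row = {mid: k for k, mid in enumerate(lib.mol_ids)}
        for target_id in activity.target_ids:
            actives = [a for a in activity.actives(target_id) if a in id_to_row]
            if len(actives) < min_actives:
                continue
            kept_any = True
            sda_runs, ef_runs = [], []
            for query_id in actives:
                ranked = rank_by_distance(
                    lib.X[id_to_row[query_id]], lib, stats,
                    query_id=query_id, exclude_self=True,
                )
                sda = sda_percent(ranked, activity, scaffolds, target_id,
                                  fraction=fraction_sda)
                if sda is not None:
                    sda_runs.append(sda)
                ef_runs.append(
                    enrichment_factor(ranked, activity, target_id,
                                      fraction=fraction_ef)
                )
            rows.append(
                {
                    "target_id": target_id,
                    "descriptor": name,
                    "sda_percent": float(np.median(sda_runs)) if sda_runs else np.nan,
                    "ef": float(np.median(ef_runs)),
                    "n_queries": len(actives),
                }
            )
    if not kept_any:
        raise ValueError(
            f"no target has >= {min_actives} annotated actives in the library"
        )
    return BenchmarkResult(frame=pd.DataFrame(rows))


def pca_compare(
    sda_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a descriptors-by-targets SD_A% table, augmented with per-target
    Best (column max) and Worst (column min) rows so the first component
    stretches along the worst-to-best direction.

    Columns are mean-centred (after augmentation) and decomposed by SVD;
    components are oriented so that the Best row's PC1 score is >= the Worst
    row's. Returns (scores, loadings, explained-variance fractions).
    """
    if sda_table.shape[0] < 2 or sda_table.shape[1] < 2:
        raise ValueError("need at least 2 descriptors and 2 targets")
    augmented = pd.concat(
        [
            sda_table,
            sda_table.max(axis=0).to_frame("Best").T,
            sda_table.min(axis=0).to_frame("Worst").T,
        ]
    )
    M = augmented.to_numpy(dtype=float)
    centred = M - M.mean(axis=0)
    if np.allclose(centred, 0.0):
        raise ValueError("no variance")
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    scores = U * s
    # orientation: Best >= Worst on PC1; remaining components keep SVD signs
    if scores[-2, 0] < scores[-1, 0]:
        scores[:, 0] *= -1.0
        Vt[0] *= -1.0
    explained = s**2 / np.sum(s**2)
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    scores_df = pd.DataFrame(scores, index=augmented.index, columns=comp_names)
    loadings_df = pd.DataFrame(Vt.T, index=sda_table.columns, columns=comp_names)
    return scores_df, loadings_df, explained
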