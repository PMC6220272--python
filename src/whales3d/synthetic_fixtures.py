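"""Synthetic inputs with known structure, for testing every other module
without external datasets.

Two kinds of fixture are produced:

* exact point clouds (tetrahedron, line, plane, random) that bypass
  embedding so the descriptor core can be checked on known geometries,
  including rank-deficient ones that exercise the pseudo-inverse;
* small SMILES screening libraries built from a catalogue of ring
  frameworks with enumerated acyclic substituents, so every molecule's
  Murcko scaffold family is known by construction, together with activity
  labels and planted descriptor matrices whose neighbourhood structure is
  controlled (clustered by scaffold family, or by activity irrespective of
  family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scaffold_metrics import ActivityTable
from .screening import DescriptorMatrix
from .structure_prep import HeavyAtomCloud, MoleculeRecord, parse_and_sanitize
from .whales_core import DESCRIPTOR_NAMES

# ring frameworks: family name, molecule template ({} takes an acyclic
# substituent prefix), and the family's canonical Murcko scaffold SMILES
FRAMEWORK_CATALOGUE: tuple[tuple[str, str, str], ...] = (
    ("benzene", "{}c1ccccc1", "c1ccccc1"),
    ("pyridine", "{}c1ccncc1", "c1ccncc1"),
    ("piperidine", "{}C1CCNCC1", "C1CCNCC1"),
    ("naphthalene", "{}c1ccc2ccccc2c1", "c1ccc2ccccc2c1"),
    ("biphenyl", "{}c1ccc(-c2ccccc2)cc1", "c1ccc(-c2ccccc2)cc1"),
    ("indole", "{}c1cc2ccccc2[nH]1", "c1ccc2[nH]ccc2c1"),
)


def _substituent_catalogue() -> list[str]:
    """Acyclic substituent prefixes (last atom attaches to the ring); being
    acyclic, none of them changes the Murcko framework."""
    subs = [""]
    subs += ["C" * k for k in range(1, 13)]          # alkyl
    subs += ["C" * k + "O" for k in range(1, 11)]    # alkoxy
    subs += ["C" * k + "N" for k in range(1, 9)]     # alkylamino
    subs += ["O", "N", "F", "Cl", "Br", "CS", "FC(F)(F)", "N#C", "OC(=O)",
             "CC(C)", "CC(C)(C)", "O=C", "OCC(=O)"]
    return subs


SUBSTITUENT_CATALOGUE: tuple[str, ...] = tuple(_substituent_catalogue())


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_molecules: int = 200
    n_scaffold_families: int = 5
    n_targets: int = 2
    actives_per_target: int = 20
    #: families each target's actives are drawn from (None: min(4, families));
    #: keeping this below n_scaffold_families plants sizeable analog series
    active_families_per_target: int | None = None
    noise_sd: float = 0.3  # descriptor-space jitter around planted centres

    def __post_init__(self) -> None:
        if min(self.n_molecules, self.n_scaffold_families, self.n_targets,
               self.actives_per_target) < 1:
            raise ValueError("all fixture counts must be positive")
        if self.actives_per_target * self.n_targets > self.n_molecules:
            raise ValueError("more requested actives than molecules")
        if self.n_scaffold_families > len(FRAMEWORK_CATALOGUE):
            raise ValueError(
                f"at most {len(FRAMEWORK_CATALOGUE)} scaffold families available"
            )


@dataclass(frozen=True)
class ScreeningFixture:
    spec: FixtureSpec
    records: tuple[MoleculeRecord, ...]
    activity: ActivityTable
    #: per-molecule family and scaffold, for asserting SD_A% counts
    manifest: pd.DataFrame  # columns: mol_id, family, scaffold_smiles

    @property
    def scaffolds(self) -> dict[str, str]:
        return dict(zip(self.manifest["mol_id"], self.manifest["scaffold_smiles"]))


def make_point_cloud(
    geometry: str,
    n: int,
    charges: np.ndarray | str = "unit",
    seed: int = 0,
    scale: float = 1.5,
) -> HeavyAtomCloud:
    """Exact heavy-atom cloud for a named geometry.

    tetrahedron (n must be 4): regular tetrahedron, pairwise equidistant;
    line: equally spaced collinear points (rank-1 covariance);
    plane: seeded Gaussian points in z = 0 (rank-2 covariance);
    random: seeded i.i.d. standard-normal points, scaled by ``scale``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    if geometry == "tetrahedron":
        if n != 4:
            raise ValueError("tetrahedron requires n = 4")
        coords = scale * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / math.sqrt(2)
    elif geometry == "line":
        coords = np.zeros((n, 3))
        coords[:, 0] = scale * np.arange(n)
    elif geometry == "plane":
        coords = np.zeros((n, 3))
        coords[:, :2] = scale * rng.standard_normal((n, 2))
    elif geometry == "random":
        coords = scale * rng.standard_normal((n, 3))
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    if isinstance(charges, str):
        if charges != "unit":
            raise ValueError(f"unknown charge spec {charges!r}")
        q = np.ones(n)
    else:
        q = np.asarray(charges, dtype=float)
        if q.shape != (n,):
            raise ValueError(f"need {n} charges, got {q.shape}")
    return HeavyAtomCloud(
        mol_id=f"{geometry}{n}", coords=coords, charges=q, elements=["C"] * n
    )


def make_conditioned_cloud(
    n: int,
    seed: int,
    max_condition: float = 100.0,
    charged: bool = True,
) -> HeavyAtomCloud:
    """Random cloud resampled until every atom-centred covariance has
    condition number <= ``max_condition``.

    Numerical-agreement checks of the Mahalanobis machinery are only
    well-posed away from the pseudo-inverse rank cutoff; this generator
    stays two orders of magnitude inside that regime (rank-deficient
    geometries are exercised separately via the line/plane fixtures).
    """
    if n < 4:
        raise ValueError("need n >= 4 for a generically full-rank covariance")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        coords = 2.0 * rng.standard_normal((n, 3))
        if charged:
            q = rng.uniform(-0.5, 0.5, size=n)
            q[np.abs(q) < 1e-3] = 0.1
        else:
            q = np.ones(n)
        w = np.abs(q)
        ok = True
        for j in range(n):
            d = coords - coords[j]
            S = (d.T * w) @ d / w.sum()
            s = np.linalg.svd(S, compute_uv=False)
            if s[0] / s[-1] > max_condition:
                ok = False
                break
        if ok:
            return HeavyAtomCloud(
                mol_id=f"cond{n}_{seed}", coords=coords, charges=q,
                elements=["C"] * n,
            )
    raise RuntimeError("failed to sample a well-conditioned cloud")


def make_screening_fixture(spec: FixtureSpec) -> ScreeningFixture:
    """Build a SMILES library with planted scaffold families plus activity
    labels.

    Molecule i belongs to family ``i mod n_scaffold_families`` and carries
    the next unused substituent of that family, so family membership (and
    hence the Murcko key) is known without computing anything. Each target's
    actives are a seeded draw without replacement from that target's
    designated families, split as evenly as possible, so every target has
    congeneric analog series of known size in known families.
    """
    families = FRAMEWORK_CATALOGUE[: spec.n_scaffold_families]
    per_family = math.ceil(spec.n_molecules / spec.n_scaffold_families)
    if per_family > len(SUBSTITUENT_CATALOGUE):
        raise ValueError(
            f"requested diversity exceeds catalogue size: need {per_family} "
            f"members per family, have {len(SUBSTITUENT_CATALOGUE)} substituents"
        )
    records, manifest_rows = [], []
    for i in range(spec.n_molecules):
        fam_name, template, scaffold = families[i % spec.n_scaffold_families]
        substituent = SUBSTITUENT_CATALOGUE[i // spec.n_scaffold_families]
        mol_id = f"m{i:04d}"
        rec = parse_and_sanitize(template.format(substituent), mol_id=mol_id)
        records.append(rec)
        manifest_rows.append(
            {"mol_id": mol_id, "family": fam_name, "scaffold_smiles": scaffold}
        )
    rng = np.random.default_rng(spec.seed)
    n_fam = spec.n_scaffold_families
    k_fams = spec.active_families_per_target or min(4, n_fam)
    members: dict[int, list[int]] = {f: [] for f in range(n_fam)}
    for i in range(spec.n_molecules):
        members[i % n_fam].append(i)
    draw_order = {f: list(rng.permutation(m)) for f, m in members.items()}
    active_of: dict[str, str] = {}
    for t in range(spec.n_targets):
        designated = [(t + k) % n_fam for k in range(k_fams)]
        base, extra = divmod(spec.actives_per_target, k_fams)
        for pos, f in enumerate(designated):
            for _ in range(base + (1 if pos < extra else 0)):
                if not draw_order[f]:
                    raise ValueError(
                        f"family {f} exhausted while assigning actives"
                    )
                i = draw_order[f].pop()
                active_of[records[i].id] = f"T{t}"
    activity_rows = [
        (rec.id, f"T{t}",
         "active" if active_of.get(rec.id) == f"T{t}" else "inactive")
        for rec in records
        for t in range(spec.n_targets)
    ]
    return ScreeningFixture(
        spec=spec,
        records=tuple(records),
        activity=ActivityTable.from_rows(activity_rows),
        manifest=pd.DataFrame(manifest_rows),
    )


def make_planted_descriptors(
    fixture: ScreeningFixture,
    mode: str,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> DescriptorMatrix:
    """Planted 33-column descriptor matrix with controlled neighbourhoods.

    mode='scaffold': molecules cluster by scaffold family, and co-actives of
    the same family form a tight analog subcluster within it — the
    scaffold-copying behaviour of fragment fingerprints, which retrieve the
    query's own congeneric series first. mode='activity': molecules cluster
    by which target they are active on, irrespective of framework — an
    idealized scaffold-blind descriptor.

    Cluster centres are dense ±1 sign patterns spanning every column (one
    pattern per family, one per target), so the planted separation survives
    per-column Gaussian normalization; Gaussian jitter of sd ``noise_sd`` is
    added around the centres.
    """
    spec = fixture.spec
    noise_sd = spec.noise_sd if noise_sd is None else noise_sd
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    p = len(DESCRIPTOR_NAMES)
    family_index = {
        name: k for k, (name, _, _) in enumerate(FRAMEWORK_CATALOGUE)
    }
    fam_pattern = rng.choice([-1.0, 1.0], size=(len(FRAMEWORK_CATALOGUE), p))
    target_pattern = rng.choice([-1.0, 1.0], size=(spec.n_targets, p))
    active_on = {
        row.mol_id: int(row.target_id[1:])
        for row in fixture.activity.frame.itertuples()
        if row.label == "active"
    }
    fam_of = dict(zip(fixture.manifest["mol_id"], fixture.manifest["family"]))
    X = np.zeros((len(fixture.records), p))
    for row, rec in enumerate(fixture.records):
        centre = np.zeros(p)
        if mode == "scaffold":
            centre += 10.0 * fam_pattern[family_index[fam_of[rec.id]]]
            if rec.id in active_on:  # analog-series offset within the family
                centre += 2.0 * target_pattern[active_on[rec.id]]
        elif mode == "activity":
            if rec.id in active_on:
                centre += 10.0 * target_pattern[active_on[rec.id]]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        X[row] = centre + noise_sd * rng.standard_normal(p)
    return DescriptorMatrix(
        mol_ids=tuple(rec.id for rec in fixture.records), X=X
    )


# ---------------------------------------------------------------------------
# File emission (same formats the main modules consume)

def write_fixture_files(fixture: ScreeningFixture, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "library": out / "library.smi",
        "activity": out / "activity.tsv",
        "manifest": out / "manifest.tsv",
    }
    paths["library"].write_text(
        "".join(f"{rec.smiles}\t{rec.id}\n" for rec in fixture.records)
    )
    fixture.activity.frame.to_csv(paths["activity"], sep="\t", index=False)
    fixture.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths
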