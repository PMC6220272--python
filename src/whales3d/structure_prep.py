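"""Molecule preparation: parsing, sanitization, 3D embedding and partial charges.

Turns raw SMILES/SDF input into a charged heavy-atom point cloud — the
coordinates ``x_i`` and weights ``delta_i`` that the descriptor core consumes.
Hydrogens are never part of the cloud; their Gasteiger charges can be folded
into the bonded heavy atom so the molecular charge distribution is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize


class MoleculePrepError(ValueError):
    """Raised when a record cannot be parsed, sanitized, embedded or charged."""


class ChargeScheme(str, Enum):
    GASTEIGER_MARSILI = "gasteiger_marsili"
    UNIT = "unit"
    EXTERNAL = "external"


@dataclass(frozen=True)
class MoleculeRecord:
    """A sanitized molecule: single organic fragment, canonical SMILES."""

    id: str
    smiles: str
    source: str = "smiles"  # "smiles" | "sdf"


@dataclass
class HeavyAtomCloud:
    """Heavy-atom 3D coordinates plus per-atom weights.

    coords are in Angstrom; charges in elementary-charge units (NaN until a
    charge scheme has been applied). ``elements`` never contains hydrogen.
    The embedded RDKit molecule (with explicit hydrogens) is kept privately so
    charge schemes that need connectivity can run after embedding.
    """

    mol_id: str
    coords: np.ndarray  # (n, 3)
    charges: np.ndarray  # (n,)
    elements: list[str]
    energy: Optional[float] = None
    _mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        if self.coords.shape[0] < 1:
            raise MoleculePrepError(f"{self.mol_id}: empty heavy-atom cloud")
        if self.charges.shape[0] != self.coords.shape[0]:
            raise MoleculePrepError(
                f"{self.mol_id}: {self.charges.shape[0]} charges for "
                f"{self.coords.shape[0]} atoms"
            )
        if "H" in self.elements:
            raise MoleculePrepError(f"{self.mol_id}: hydrogens are excluded from the cloud")


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def parse_and_sanitize(raw: str | Chem.Mol, mol_id: str = "mol") -> MoleculeRecord:
    """Parse a SMILES string (or an RDKit Mol from an SDF record), keep the
    largest organic fragment, neutralize representable charged groups and
    return the canonical-SMILES record.

    Raises :class:`MoleculePrepError` naming ``mol_id`` on unparseable input.
    """
    if isinstance(raw, Chem.Mol):
        mol = raw
        source = "sdf"
        if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            mol_id = mol.GetProp("_Name").strip()
    else:
        if not isinstance(raw, str) or not raw.strip():
            raise MoleculePrepError(f"{mol_id}: empty input")
        mol = Chem.MolFromSmiles(raw)
        source = "smiles"
    if mol is None:
        raise MoleculePrepError(f"{mol_id}: unparseable input {raw!r}")
    try:
        mol = _LARGEST_FRAGMENT.choose(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several internal exception types
        raise MoleculePrepError(f"{mol_id}: sanitization failed ({exc})") from exc
    if mol.GetNumHeavyAtoms() == 0:
        raise MoleculePrepError(f"{mol_id}: no heavy atoms after sanitization")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise MoleculePrepError(f"{mol_id}: no single dominant organic fragment")
    return MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(mol), source=source)


def embed_lowest_energy_conformer(
    rec: MoleculeRecord,
    n_confs: int = 10,
    max_iters: int = 1000,
    seed: int = 0,
    coords: Optional[np.ndarray] = None,
) -> HeavyAtomCloud:
    """Generate ``n_confs`` ETKDG conformers from random starting coordinates,
    MMFF94-minimize each for up to ``max_iters`` iterations, and return the
    heavy-atom cloud of the lowest-energy conformer (ties: lowest index).

    ``coords`` bypasses embedding with user-supplied heavy-atom coordinates
    (pre-embedded SDF input). Charges are left unset (NaN).
    """
    mol = Chem.MolFromSmiles(rec.smiles)
    if mol is None:
        raise MoleculePrepError(f"{rec.id}: stored SMILES no longer parses")
    if coords is not None:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if coords.shape[0] != mol.GetNumHeavyAtoms():
            raise MoleculePrepError(
                f"{rec.id}: {coords.shape[0]} coordinates for "
                f"{mol.GetNumHeavyAtoms()} heavy atoms"
            )
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        return HeavyAtomCloud(
            mol_id=rec.id,
            coords=coords,
            charges=np.full(coords.shape[0], np.nan),
            elements=elements,
            _mol=Chem.AddHs(mol),
        )
    if n_confs < 1:
        raise MoleculePrepError(f"{rec.id}: n_confs must be >= 1")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = True
    params.useBasicKnowledge = True
    params.useExpTorsionAnglePrefs = True
    params.pruneRmsThresh = -1.0
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=int(n_confs), params=params)
    if len(conf_ids) == 0:
        raise MoleculePrepError(f"{rec.id}: 3D embedding failed")
    if AllChem.MMFFHasAllMoleculeParams(molh):
        results = AllChem.MMFFOptimizeMoleculeConfs(
            molh, mmffVariant="MMFF94", maxIters=int(max_iters)
        )
        energies = [e for _not_converged, e in results]
    else:
        raise MoleculePrepError(f"{rec.id}: MMFF94 parameters unavailable")
    best = int(np.argmin(energies))  # argmin takes the first (lowest-index) tie
    conf = molh.GetConformer(conf_ids[best])
    pos = conf.GetPositions()
    heavy = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
    return HeavyAtomCloud(
        mol_id=rec.id,
        coords=pos[heavy],
        charges=np.full(len(heavy), np.nan),
        elements=[molh.GetAtomWithIdx(i).GetSymbol() for i in heavy],
        energy=float(energies[best]),
        _mol=molh,
    )


def read_external_charges(path: str | Path) -> dict[str, dict[int, float]]:
    """Read a tab-separated external charge file (mol_id, atom_index, charge).

    atom_index is 0-based over heavy atoms after hydrogen removal.
    """
    table: dict[str, dict[int, float]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise MoleculePrepError(
                f"{path}:{line_no}: expected 3 tab-separated fields, got {len(parts)}"
            )
        mol_id, idx_s, q_s = parts
        table.setdefault(mol_id, {})[int(idx_s)] = float(q_s)
    return table


def assign_charges(
    cloud: HeavyAtomCloud,
    scheme: ChargeScheme | str = ChargeScheme.GASTEIGER_MARSILI,
    charge_file: Optional[str | Path] = None,
    external_charges: Optional[dict[str, dict[int, float]]] = None,
    fold_h_charges: bool = True,
) -> HeavyAtomCloud:
    """Fill per-atom weights ``delta_i`` according to the chosen scheme.

    unit
        every ``delta_i = 1`` exactly — the pure-shape variant.
    gasteiger_marsili
        iterative partial-equalization charges on the full molecule (explicit
        hydrogens included); with ``fold_h_charges`` each hydrogen's charge is
        added to its bonded heavy atom before the hydrogens are dropped, which
        conserves the total molecular charge.
    external
        per-atom charges read from ``charge_file`` (or a pre-parsed
        ``external_charges`` mapping), keyed by (mol_id, heavy-atom index).
    """
    scheme = ChargeScheme(scheme)
    n = cloud.n_atoms
    if scheme is ChargeScheme.UNIT:
        charges = np.ones(n)
    elif scheme is ChargeScheme.GASTEIGER_MARSILI:
        molh = cloud._mol
        if molh is None:
            raise MoleculePrepError(
                f"{cloud.mol_id}: gasteiger_marsili needs the embedded molecule"
            )
        AllChem.ComputeGasteigerCharges(molh)
        atom_q = np.array(
            [a.GetDoubleProp("_GasteigerCharge") for a in molh.GetAtoms()]
        )
        heavy = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
        heavy_pos = {idx: k for k, idx in enumerate(heavy)}
        charges = atom_q[heavy].copy()
        if fold_h_charges:
            for atom in molh.GetAtoms():
                if atom.GetAtomicNum() == 1:
                    nbrs = atom.GetNeighbors()
                    if nbrs:  # bare H atom (e.g. H2) has no heavy neighbour
                        charges[heavy_pos[nbrs[0].GetIdx()]] += atom_q[atom.GetIdx()]
        if len(charges) != n:
            raise MoleculePrepError(
                f"{cloud.mol_id}: embedded molecule has {len(charges)} heavy atoms, "
                f"cloud has {n}"
            )
        has_heteroatoms = any(e not in ("C",) for e in cloud.elements)
        if has_heteroatoms and np.allclose(charges, 0.0):
            warnings.warn(
                f"{cloud.mol_id}: all-zero Gasteiger charges on a heteroatom-bearing "
                "molecule — likely a sanitization fault",
                stacklevel=2,
            )
    else:  # EXTERNAL
        if external_charges is None:
            if charge_file is None:
                raise MoleculePrepError(
                    f"{cloud.mol_id}: external scheme requires a charge file"
                )
            external_charges = read_external_charges(charge_file)
        per_mol = external_charges.get(cloud.mol_id)
        if per_mol is None:
            raise MoleculePrepError(f"{cloud.mol_id}: no external charges supplied")
        charges = np.empty(n)
        for i in range(n):
            if i not in per_mol:
                raise MoleculePrepError(
                    f"({cloud.mol_id}, {i}): missing external charge"
                )
            charges[i] = per_mol[i]
        out_of_range = sorted(set(per_mol) - set(range(n)))
        if out_of_range:
            raise MoleculePrepError(
                f"({cloud.mol_id}, {out_of_range[0]}): atom index out of range "
                f"(molecule has {n} heavy atoms)"
            )
    return replace(cloud, charges=charges)


# ---------------------------------------------------------------------------
# File-level input helpers

def read_smiles_file(path: str | Path) -> Iterator[MoleculeRecord]:
    """Yield sanitized records from a SMILES file (one per line, optional
    tab-separated id). Unparseable lines raise with the offending id."""
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 else f"line{line_no}"
        yield parse_and_sanitize(smiles, mol_id=mol_id)


def read_sdf_file(path: str | Path) -> Iterator[tuple[MoleculeRecord, Optional[np.ndarray]]]:
    """Yield (record, coords-or-None) from an SDF; coords are the heavy-atom
    positions when the record carries a 3D conformer."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for rec_no, mol in enumerate(supplier):
        if mol is None:
            raise MoleculePrepError(f"{path}: record {rec_no} unparseable")
        rec = parse_and_sanitize(mol, mol_id=f"sdf{rec_no}")
        coords = None
        if mol.GetNumConformers() and mol.GetConformer().Is3D():
            coords = mol.GetConformer().GetPositions()
        yield rec, coords


def load_records(
    path: str | Path,
) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Load a SMILES library leniently: unparseable records are returned as
    (mol_id, reason) rejects instead of aborting the run."""
    records: list[MoleculeRecord] = []
    rejects: list[tuple[str, str]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        mol_id = parts[1].strip() if len(parts) > 1 else f"line{line_no}"
        try:
            records.append(parse_and_sanitize(parts[0].strip(), mol_id=mol_id))
        except MoleculePrepError as exc:
            rejects.append((mol_id, str(exc)))
    return records, rejects


def prepare_library(
    records: Iterable[MoleculeRecord],
    scheme: ChargeScheme | str = ChargeScheme.GASTEIGER_MARSILI,
    n_confs: int = 10,
    max_iters: int = 1000,
    seed: int = 0,
    charge_file: Optional[str | Path] = None,
    fold_h_charges: bool = True,
) -> tuple[list[HeavyAtomCloud], list[tuple[str, str]]]:
    """Embed and charge a library; failed molecules go to the rejects list as
    (mol_id, reason) pairs, never silently dropped."""
    external = read_external_charges(charge_file) if charge_file else None
    clouds: list[HeavyAtomCloud] = []
    rejects: list[tuple[str, str]] = []
    for rec in records:
        try:
            cloud = embed_lowest_energy_conformer(
                rec, n_confs=n_confs, max_iters=max_iters, seed=seed
            )
            cloud = assign_charges(
                cloud, scheme=scheme, external_charges=external,
                fold_h_charges=fold_h_charges,
            )
            clouds.append(cloud)
        except MoleculePrepError as exc:
            rejects.append((rec.id, str(exc)))
    return clouds, rejects
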