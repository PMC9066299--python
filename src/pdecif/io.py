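"""Reading protein PDB files, ligand MOL/SDF files and complex index files.

Protein structures are read through Biopython's PDB parser; only ``ATOM``
records survive (no HETATM, no waters, no hydrogens), only the first model
of a multi-model file is kept, and alternate locations other than blank/'A'
are dropped.  Ligands are read through RDKit with hydrogens retained, since
the typing scheme needs explicit hydrogen counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from rdkit import Chem

from .errors import EmptyStructureError, StructureParseError

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class ProteinAtomRecord:
    """One retained heavy atom from a protein ``ATOM`` record."""

    residue_name: str
    atom_name: str
    chain_id: str
    coords: np.ndarray
    is_heavy: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be a finite 3-vector")
        if not self.residue_name or not self.atom_name:
            raise ValueError("residue and atom names must be non-empty")


@dataclass
class LigandMol:
    """A parsed ligand: an RDKit molecule with hydrogens and 3-D coordinates."""

    mol: Chem.Mol
    name: str = ""

    @property
    def heavy_atom_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    def coords(self, atom_index: int) -> np.ndarray:
        pos = self.mol.GetConformer().GetAtomPosition(int(atom_index))
        return np.array([pos.x, pos.y, pos.z], dtype=float)


@dataclass
class ComplexEntry:
    """Index row pairing a protein file, a ligand file and a pK affinity label."""

    complex_id: str
    protein_path: Path
    ligand_path: Path
    affinity: float

    def __post_init__(self) -> None:
        self.protein_path = Path(self.protein_path)
        self.ligand_path = Path(self.ligand_path)
        self.affinity = float(self.affinity)
        if not np.isfinite(self.affinity):
            raise ValueError(f"non-finite affinity for complex {self.complex_id!r}")


def read_protein(path: str | Path) -> list[ProteinAtomRecord]:
    """Read the retained heavy atoms of a protein PDB file.

    Keeps heavy atoms of ``ATOM`` records from the first model, with altloc
    blank or 'A'.  Hydrogens, waters and all HETATM records are dropped.
    All chains are retained (long-range pair counting is uncapped, so no
    distance pre-filter is applied at read time).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # malformed coordinates etc.
            raise StructureParseError(f"cannot parse PDB file {path}: {exc}") from exc
    records: list[ProteinAtomRecord] = []
    models = list(structure.get_models())
    if models:
        model = models[0]  # first model only
        for chain in model:
            for residue in chain:
                hetfield = residue.id[0]
                if hetfield != " ":
                    continue  # HETATM (incl. waters flagged 'W')
                if residue.get_resname().strip() in _WATER_NAMES:
                    continue
                for atom in residue.get_unpacked_list():
                    if atom.get_altloc() not in (" ", "A"):
                        continue
                    element = (atom.element or "").strip().upper()
                    if element == "H" or atom.get_name().startswith("H"):
                        continue
                    records.append(
                        ProteinAtomRecord(
                            residue_name=residue.get_resname().strip(),
                            atom_name=atom.get_name().strip(),
                            chain_id=chain.id,
                            coords=atom.get_coord(),
                        )
                    )
    if not records:
        raise EmptyStructureError(f"no retained protein heavy atoms in {path}")
    return records


def write_protein(records: list[ProteinAtomRecord]) -> str:
    """Serialize retained records back to minimal PDB ``ATOM`` text.

    Round-trips through :func:`read_protein` on the retained fields.
    """
    lines = []
    for i, rec in enumerate(records, start=1):
        name = rec.atom_name
        # PDB v3.3 column rules: 1-3 char names start in column 14
        padded = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = rec.coords
        element = name[0]
        lines.append(
            f"ATOM  {i % 100000:5d} {padded:<4s} {rec.residue_name:<3s} "
            f"{rec.chain_id[:1] or 'A'}{(i % 10000) or 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2s}"
        )
    return "\n".join(lines) + "\nEND\n"


def read_ligand(path: str | Path) -> LigandMol:
    """Read the first molecule of a MOL/SDF file, hydrogens retained.

    Aromaticity is perceived with RDKit's default model during
    sanitization; this same model backs atom typing, so ligand and protein
    aromaticity are judged consistently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mol = None
    for candidate in supplier:
        if candidate is not None:
            mol = candidate
            break
    if mol is None:
        raise StructureParseError(f"RDKit cannot parse ligand file {path}")
    if not any(a.GetAtomicNum() > 1 for a in mol.GetAtoms()):
        raise EmptyStructureError(f"ligand {path} has no heavy atoms")
    if mol.GetNumConformers() == 0:
        raise StructureParseError(f"ligand {path} carries no coordinates")
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
    return LigandMol(mol=mol, name=name or path.stem)


def load_index(path: str | Path) -> list[ComplexEntry]:
    """Load a comma- or tab-separated complex index with a header row.

    Expected columns: complex id, protein path, ligand path, affinity (pK).
    Referenced structure files are *not* opened here; unreadable structures
    surface later, at featurization time.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise StructureParseError(f"cannot parse index file {path}: {exc}") from exc
    if frame.shape[1] < 4:
        raise StructureParseError(f"index {path} needs >=4 columns, has {frame.shape[1]}")
    frame.columns = ["complex_id", "protein_path", "ligand_path", "affinity"] + list(
        frame.columns[4:]
    )
    entries = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            affinity = float(row.affinity)
        except (TypeError, ValueError) as exc:
            raise StructureParseError(
                f"row {row_number} of {path}: non-numeric affinity {row.affinity!r}"
            ) from exc
        entries.append(
            ComplexEntry(
                complex_id=str(row.complex_id),
                protein_path=path.parent / str(row.protein_path),
                ligand_path=path.parent / str(row.ligand_path),
                affinity=affinity,
            )
        )
    ids = [e.complex_id for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise StructureParseError(f"duplicate complex ids in {path}: {dupes}")
    return entries
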