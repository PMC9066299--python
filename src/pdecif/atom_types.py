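"""ECIF atom-environment typing.

An ECIF atom type is the semicolon-joined string of six atomic environment
properties: element symbol, explicit valence (sum of bond orders, bonds to
hydrogen included), number of attached heavy atoms, number of attached
hydrogens, aromaticity (0/1) and ring membership (0/1).  Ligand atoms are
typed from the perceived RDKit molecular graph; protein atoms are typed by
exact lookup of the (residue name, PDB atom name) key in a table built from
amino-acid topology templates.

The typing conventions are documented in detail in ``docs/methods.md``:
aromaticity is RDKit's default model, ring membership means membership in
any SSSR ring, side chains are typed in their dominant physiological
protonation state (anionic carboxylates, cationic Lys/Arg, neutral aromatic
His with the proton on ND1, thiol Cys), and the guanidinium group of Arg is
typed in its symmetric delocalized form with all three C-N bonds at order 2.
Under these conventions the protein table realizes exactly the scheme's 22
distinct protein atom types; the ligand side uses the scheme's fixed 70-type
vocabulary shipped as a data file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

from rdkit import Chem

from .errors import VocabularyError

logger = logging.getLogger(__name__)

N_PROTEIN_TYPES = 22
N_LIGAND_TYPES = 70


@dataclass(frozen=True, order=True)
class EcifAtomType:
    """Six-property atom-environment descriptor, e.g. ``C;4;3;0;0;0``."""

    symbol: str
    explicit_valence: int
    heavy_degree: int
    h_count: int
    is_aromatic: int
    in_ring: int

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("empty element symbol")
        if self.heavy_degree + self.h_count > self.explicit_valence:
            raise ValueError(
                f"inconsistent environment: degree {self.heavy_degree} + "
                f"H count {self.h_count} exceeds valence {self.explicit_valence}"
            )
        if self.is_aromatic not in (0, 1) or self.in_ring not in (0, 1):
            raise ValueError("aromatic/ring flags must be 0 or 1")

    def __str__(self) -> str:
        return ";".join(
            str(x)
            for x in (
                self.symbol,
                self.explicit_valence,
                self.heavy_degree,
                self.h_count,
                self.is_aromatic,
                self.in_ring,
            )
        )

    @classmethod
    def from_string(cls, s: str) -> "EcifAtomType":
        parts = s.split(";")
        if len(parts) != 6:
            raise ValueError(f"not a valid 6-field atom type string: {s!r}")
        return cls(parts[0], *(int(p) for p in parts[1:]))


def type_ligand_atom(mol: Chem.Mol, atom_index: int) -> EcifAtomType:
    """Type one heavy atom of an RDKit molecule from its perceived environment.

    Hydrogens (explicit or implicit) contribute to the valence and H-count
    properties but may not themselves be typed.
    """
    atom = mol.GetAtomWithIdx(int(atom_index))
    if atom.GetAtomicNum() == 1:
        raise ValueError(f"atom {atom_index} is a hydrogen and cannot be typed")
    heavy_degree = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
    return EcifAtomType(
        symbol=atom.GetSymbol(),
        explicit_valence=int(atom.GetTotalValence()),
        heavy_degree=heavy_degree,
        h_count=int(atom.GetTotalNumHs(includeNeighbors=True)),
        is_aromatic=int(atom.GetIsAromatic()),
        in_ring=int(atom.IsInRing()),
    )


# ---------------------------------------------------------------------------
# Protein residue topology templates
#
# Each residue lists its side-chain heavy atoms as
#   (name, element, n_hydrogens, aromatic_flag, ring_flag)
# and its side-chain bonds as (atom_a, atom_b, bond_order).  Aromatic rings
# are written in one Kekule structure; the aromatic flag carries the
# aromaticity information, and valences are the Kekule bond-order sums.
# Backbone atoms are shared and typed in mid-chain context: the virtual
# neighbours "-C" (preceding carbonyl carbon) and "+N" (following amide
# nitrogen) count toward degree and valence but are never typed themselves.
# ---------------------------------------------------------------------------

_BB_ATOMS = [
    ("N", "N", 1, 0, 0),
    ("CA", "C", 1, 0, 0),
    ("C", "C", 0, 0, 0),
    ("O", "O", 0, 0, 0),
]
_BB_BONDS = [("-C", "N", 1), ("N", "CA", 1), ("CA", "C", 1), ("C", "O", 2), ("C", "+N", 1)]

# fmt: off
_SIDECHAINS: dict[str, tuple[list, list]] = {
    "GLY": ([], []),
    "ALA": ([("CB", "C", 3, 0, 0)], []),
    "VAL": ([("CB", "C", 1, 0, 0), ("CG1", "C", 3, 0, 0), ("CG2", "C", 3, 0, 0)],
            [("CB", "CG1", 1), ("CB", "CG2", 1)]),
    "LEU": ([("CB", "C", 2, 0, 0), ("CG", "C", 1, 0, 0),
             ("CD1", "C", 3, 0, 0), ("CD2", "C", 3, 0, 0)],
            [("CB", "CG", 1), ("CG", "CD1", 1), ("CG", "CD2", 1)]),
    "ILE": ([("CB", "C", 1, 0, 0), ("CG1", "C", 2, 0, 0),
             ("CG2", "C", 3, 0, 0), ("CD1", "C", 3, 0, 0)],
            [("CB", "CG1", 1), ("CB", "CG2", 1), ("CG1", "CD1", 1)]),
    "PRO": ([("CB", "C", 2, 0, 1), ("CG", "C", 2, 0, 1), ("CD", "C", 2, 0, 1)],
            [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "N", 1)]),
    "SER": ([("CB", "C", 2, 0, 0), ("OG", "O", 1, 0, 0)], [("CB", "OG", 1)]),
    "THR": ([("CB", "C", 1, 0, 0), ("OG1", "O", 1, 0, 0), ("CG2", "C", 3, 0, 0)],
            [("CB", "OG1", 1), ("CB", "CG2", 1)]),
    "CYS": ([("CB", "C", 2, 0, 0), ("SG", "S", 1, 0, 0)], [("CB", "SG", 1)]),
    "MET": ([("CB", "C", 2, 0, 0), ("CG", "C", 2, 0, 0),
             ("SD", "S", 0, 0, 0), ("CE", "C", 3, 0, 0)],
            [("CB", "CG", 1), ("CG", "SD", 1), ("SD", "CE", 1)]),
    "ASN": ([("CB", "C", 2, 0, 0), ("CG", "C", 0, 0, 0),
             ("OD1", "O", 0, 0, 0), ("ND2", "N", 2, 0, 0)],
            [("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "ND2", 1)]),
    "GLN": ([("CB", "C", 2, 0, 0), ("CG", "C", 2, 0, 0), ("CD", "C", 0, 0, 0),
             ("OE1", "O", 0, 0, 0), ("NE2", "N", 2, 0, 0)],
            [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "OE1", 2), ("CD", "NE2", 1)]),
    "ASP": ([("CB", "C", 2, 0, 0), ("CG", "C", 0, 0, 0),
             ("OD1", "O", 0, 0, 0), ("OD2", "O", 0, 0, 0)],
            [("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "OD2", 1)]),
    "GLU": ([("CB", "C", 2, 0, 0), ("CG", "C", 2, 0, 0), ("CD", "C", 0, 0, 0),
             ("OE1", "O", 0, 0, 0), ("OE2", "O", 0, 0, 0)],
            [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "OE1", 2), ("CD", "OE2", 1)]),
    "LYS": ([("CB", "C", 2, 0, 0), ("CG", "C", 2, 0, 0), ("CD", "C", 2, 0, 0),
             ("CE", "C", 2, 0, 0), ("NZ", "N", 3, 0, 0)],
            [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "CE", 1), ("CE", "NZ", 1)]),
    # Arg guanidinium: symmetric delocalized cation, all three C-N bonds order 2.
    "ARG": ([("CB", "C", 2, 0, 0), ("CG", "C", 2, 0, 0), ("CD", "C", 2, 0, 0),
             ("NE", "N", 1, 0, 0), ("CZ", "C", 0, 0, 0),
             ("NH1", "N", 2, 0, 0), ("NH2", "N", 2, 0, 0)],
            [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "NE", 1),
             ("NE", "CZ", 2), ("CZ", "NH1", 2), ("CZ", "NH2", 2)]),
    "PHE": ([("CB", "C", 2, 0, 0), ("CG", "C", 0, 1, 1),
             ("CD1", "C", 1, 1, 1), ("CD2", "C", 1, 1, 1),
             ("CE1", "C", 1, 1, 1), ("CE2", "C", 1, 1, 1), ("CZ", "C", 1, 1, 1)],
            [("CB", "CG", 1), ("CG", "CD1", 2), ("CD1", "CE1", 1), ("CE1", "CZ", 2),
             ("CZ", "CE2", 1), ("CE2", "CD2", 2), ("CD2", "CG", 1)]),
    "TYR": ([("CB", "C", 2, 0, 0), ("CG", "C", 0, 1, 1),
             ("CD1", "C", 1, 1, 1), ("CD2", "C", 1, 1, 1),
             ("CE1", "C", 1, 1, 1), ("CE2", "C", 1, 1, 1),
             ("CZ", "C", 0, 1, 1), ("OH", "O", 1, 0, 0)],
            [("CB", "CG", 1), ("CG", "CD1", 2), ("CD1", "CE1", 1), ("CE1", "CZ", 2),
             ("CZ", "CE2", 1), ("CE2", "CD2", 2), ("CD2", "CG", 1), ("CZ", "OH", 1)]),
    # His: neutral aromatic tautomer with the proton on ND1.
    "HIS": ([("CB", "C", 2, 0, 0), ("CG", "C", 0, 1, 1),
             ("ND1", "N", 1, 1, 1), ("CE1", "C", 1, 1, 1),
             ("NE2", "N", 0, 1, 1), ("CD2", "C", 1, 1, 1)],
            [("CB", "CG", 1), ("CG", "ND1", 1), ("ND1", "CE1", 1),
             ("CE1", "NE2", 2), ("NE2", "CD2", 1), ("CD2", "CG", 2)]),
    "TRP": ([("CB", "C", 2, 0, 0), ("CG", "C", 0, 1, 1),
             ("CD1", "C", 1, 1, 1), ("NE1", "N", 1, 1, 1),
             ("CE2", "C", 0, 1, 1), ("CD2", "C", 0, 1, 1),
             ("CE3", "C", 1, 1, 1), ("CZ3", "C", 1, 1, 1),
             ("CH2", "C", 1, 1, 1), ("CZ2", "C", 1, 1, 1)],
            [("CB", "CG", 1), ("CG", "CD1", 2), ("CD1", "NE1", 1), ("NE1", "CE2", 1),
             ("CE2", "CD2", 1), ("CD2", "CG", 1), ("CD2", "CE3", 2), ("CE3", "CZ3", 1),
             ("CZ3", "CH2", 2), ("CH2", "CZ2", 1), ("CZ2", "CE2", 2)]),
}
# fmt: on

STANDARD_RESIDUES = tuple(sorted(_SIDECHAINS))


def _type_residue(residue: str) -> dict[str, EcifAtomType]:
    side_atoms, side_bonds = _SIDECHAINS[residue]
    atoms = {name: (elem, h, ar, rg) for name, elem, h, ar, rg in _BB_ATOMS + side_atoms}
    if residue == "GLY":
        atoms["CA"] = ("C", 2, 0, 0)
    if residue == "PRO":
        atoms["N"] = ("N", 0, 0, 1)
        atoms["CA"] = ("C", 1, 0, 1)
    bonds = list(_BB_BONDS) + list(side_bonds)
    if side_atoms and any(n == "CB" for n, *_ in side_atoms):
        bonds.append(("CA", "CB", 1))
    valence = {name: h for name, (_, h, _, _) in atoms.items()}
    degree = {name: 0 for name in atoms}
    for a, b, order in bonds:
        for x, y in ((a, b), (b, a)):
            if x in valence:
                valence[x] += order
                degree[x] += 1  # context atoms -C/+N count toward degree
    table = {}
    for name, (elem, h, ar, rg) in atoms.items():
        table[name] = EcifAtomType(elem, valence[name], degree[name], h, ar, rg)
    # C-terminal carboxylate oxygen: typed as a carbonyl-like oxygen.
    table["OXT"] = EcifAtomType("O", 2, 1, 0, 0, 0)
    return table


class ProteinTypeTable:
    """Exact (residue name, atom name) -> ECIF type lookup for protein atoms.

    Covers every heavy atom of the 20 standard amino acids plus the terminal
    OXT oxygen.  Lookups outside the table return ``None``; callers skip (and
    may log) such atoms, because the descriptor space is defined only over
    the scheme's fixed protein vocabulary.
    """

    def __init__(self, mapping: dict[tuple[str, str], EcifAtomType]):
        self._mapping = dict(mapping)
        values = self.distinct_types()
        if len(values) != N_PROTEIN_TYPES:
            raise VocabularyError(
                f"protein type table has {len(values)} distinct types, "
                f"expected {N_PROTEIN_TYPES}"
            )

    def get(self, residue_name: str, atom_name: str) -> EcifAtomType | None:
        return self._mapping.get((residue_name.strip().upper(), atom_name.strip().upper()))

    def __len__(self) -> int:
        return len(self._mapping)

    def items(self):
        return self._mapping.items()

    def distinct_types(self) -> list[str]:
        """Sorted list of the distinct canonical type strings in the table."""
        return sorted({str(t) for t in self._mapping.values()})


def build_protein_type_table() -> ProteinTypeTable:
    """Construct the protein typing table from the residue topology templates."""
    mapping: dict[tuple[str, str], EcifAtomType] = {}
    for residue in STANDARD_RESIDUES:
        for atom_name, atype in _type_residue(residue).items():
            mapping[(residue, atom_name)] = atype
    return ProteinTypeTable(mapping)


def _read_data_lines(filename: str) -> list[str]:
    text = resources.files("pdecif.data").joinpath(filename).read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def load_ligand_vocabulary() -> list[str]:
    """The ordered 70-entry ligand atom-type vocabulary (shipped data file)."""
    vocab = _read_data_lines("ligand_atom_types.txt")
    if len(vocab) != N_LIGAND_TYPES or len(set(vocab)) != N_LIGAND_TYPES:
        raise VocabularyError(
            f"ligand vocabulary must contain {N_LIGAND_TYPES} unique entries, "
            f"got {len(vocab)}"
        )
    for entry in vocab:
        EcifAtomType.from_string(entry)  # grammar check
    return vocab


def load_protein_vocabulary() -> list[str]:
    """The ordered 22-entry protein atom-type vocabulary (shipped data file)."""
    vocab = _read_data_lines("protein_atom_types.txt")
    built = build_protein_type_table().distinct_types()
    if vocab != built:
        raise VocabularyError("shipped protein vocabulary disagrees with built table")
    return vocab
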