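"""Synthetic protein-ligand complexes and regression datasets.

Every downstream module is testable without external structure downloads:
this module emits parseable PDB/SDF text for toy complexes assembled from
hand-audited fragments — GLY/ALA/ASN residues on the protein side, acetone,
benzene and ethanol (with explicit hydrogens) on the ligand side — placed
either at explicit coordinates or uniformly at random inside a sphere.
Alongside the files it emits a ground-truth table listing every typed
heavy-atom pair with its exact distance; pair counting must reproduce the
double-loop counts over that table, which is the principal oracle of the
test suite.

Synthetic regression datasets (planted informative columns + Gaussian
noise) back the grid-search and Boruta behaviour tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .atom_types import build_protein_type_table, load_ligand_vocabulary, type_ligand_atom
from .errors import GenerationError
from .io import LigandMol, ProteinAtomRecord, read_ligand, write_protein

# --------------------------------------------------------------------------
# Fragment templates (local coordinates, Angstroms)
# --------------------------------------------------------------------------

_RESIDUE_COORDS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "GLY": [
        ("N", (-0.525, 1.362, 0.000)),
        ("CA", (0.000, 0.000, 0.000)),
        ("C", (1.526, 0.000, 0.000)),
        ("O", (2.153, 1.062, 0.000)),
    ],
    "ALA": [
        ("N", (-0.525, 1.362, 0.000)),
        ("CA", (0.000, 0.000, 0.000)),
        ("C", (1.526, 0.000, 0.000)),
        ("O", (2.153, 1.062, 0.000)),
        ("CB", (-0.507, -0.779, -1.207)),
    ],
    "ASN": [
        ("N", (-0.525, 1.362, 0.000)),
        ("CA", (0.000, 0.000, 0.000)),
        ("C", (1.526, 0.000, 0.000)),
        ("O", (2.153, 1.062, 0.000)),
        ("CB", (-0.507, -0.779, -1.207)),
        ("CG", (-0.394, -0.110, -2.566)),
        ("OD1", (0.711, 0.232, -2.987)),
        ("ND2", (-1.480, 0.110, -3.306)),
    ],
}
_OXT_COORD = ("OXT", (2.103, -1.155, 0.000))

# Ligand templates: (element, (x, y, z)) and bonds (i, j, order), 0-based.
_LIGAND_TEMPLATES: dict[str, tuple[list, list]] = {
    "acetone": (
        [
            ("C", (0.000, 0.000, 0.000)),
            ("O", (0.000, 1.229, 0.000)),
            ("C", (1.287, -0.755, 0.000)),
            ("C", (-1.287, -0.755, 0.000)),
            ("H", (1.553, -1.123, 0.990)),
            ("H", (2.095, -0.121, -0.370)),
            ("H", (1.155, -1.610, -0.668)),
            ("H", (-1.553, -1.123, 0.990)),
            ("H", (-2.095, -0.121, -0.370)),
            ("H", (-1.155, -1.610, -0.668)),
        ],
        [(0, 1, 2), (0, 2, 1), (0, 3, 1), (2, 4, 1), (2, 5, 1), (2, 6, 1),
         (3, 7, 1), (3, 8, 1), (3, 9, 1)],
    ),
    "benzene": (
        [("C", (1.395 * math.cos(math.radians(60 * k)),
                1.395 * math.sin(math.radians(60 * k)), 0.0)) for k in range(6)]
        + [("H", (2.485 * math.cos(math.radians(60 * k)),
                  2.485 * math.sin(math.radians(60 * k)), 0.0)) for k in range(6)],
        [(0, 1, 2), (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 0, 1)]
        + [(k, k + 6, 1) for k in range(6)],
    ),
    "ethanol": (
        [
            ("C", (0.000, 0.000, 0.000)),
            ("C", (1.512, 0.000, 0.000)),
            ("O", (2.057, 1.298, 0.000)),
            ("H", (-0.380, -0.520, 0.890)),
            ("H", (-0.380, -0.520, -0.890)),
            ("H", (-0.380, 1.030, 0.000)),
            ("H", (1.890, -0.520, 0.880)),
            ("H", (1.890, -0.520, -0.880)),
            ("H", (3.020, 1.230, 0.000)),
        ],
        [(0, 1, 1), (1, 2, 1), (0, 3, 1), (0, 4, 1), (0, 5, 1),
         (1, 6, 1), (1, 7, 1), (2, 8, 1)],
    ),
}

LIGAND_TEMPLATE_NAMES = tuple(sorted(_LIGAND_TEMPLATES))
RESIDUE_TEMPLATE_NAMES = tuple(sorted(_RESIDUE_COORDS))


def _molblock(name: str, atoms: list, bonds: list) -> str:
    lines = [name, f"  pdecif{'':12}3D", "pdecif synthetic fixture"]
    lines.append(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for elem, (x, y, z) in atoms:
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {elem:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def _rotation_matrix(rng: np.random.RandomState) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass
class SyntheticComplexSpec:
    """Recipe for one toy complex.

    Either give explicit ``placements`` — a list of
    ``(kind, name, (x, y, z))`` with kind ``"residue"`` (name may carry a
    ``+OXT`` suffix), ``"atom"`` (``"RES:ATOM"``, a single protein atom) or
    ``"ligand"`` — placed without rotation, or give target atom counts and a
    placement radius for seeded random assembly from the fragment templates.
    """

    n_protein_atoms: int = 20
    n_ligand_atoms: int = 8
    radius: float = 8.0
    seed: int = 0
    placements: list | None = None
    min_separation: float = 0.5


@dataclass
class SyntheticComplex:
    """Emitted fixture: PDB text, SDF text and the ground-truth pair table."""

    pdb_text: str
    sdf_text: str
    ground_truth: pd.DataFrame
    protein_records: list[ProteinAtomRecord]
    ligand: LigandMol


def _compose_exact(target: int, sizes: dict[str, int], rng: np.random.RandomState) -> list[str]:
    """Random exact composition of `target` from template sizes (DP + random walk)."""
    names = sorted(sizes)
    reachable = {0: None}
    frontier = [0]
    while frontier:
        new = []
        for total in frontier:
            for nm in names:
                t = total + sizes[nm]
                if t <= target and t not in reachable:
                    reachable[t] = None
                    new.append(t)
        frontier = new
    if target not in reachable:
        raise GenerationError(
            f"cannot compose exactly {target} atoms from fragment sizes {sizes}"
        )
    # walk back from target, choosing uniformly among feasible fragments
    chosen, remaining = [], target
    while remaining > 0:
        options = [nm for nm in names if remaining - sizes[nm] in reachable]
        nm = options[rng.randint(len(options))]
        chosen.append(nm)
        remaining -= sizes[nm]
    return chosen


def make_complex(spec: SyntheticComplexSpec) -> SyntheticComplex:
    """Emit a synthetic complex and its exhaustive typed-pair ground truth.

    The ground-truth table has one row per (typed protein heavy atom, typed
    ligand heavy atom) pair: indices, both canonical types and the exact
    Euclidean distance recomputed from the emitted coordinates.
    """
    rng = np.random.RandomState(spec.seed)
    table = build_protein_type_table()

    if spec.placements is not None:
        placed = [(k, n, np.asarray(t, dtype=float), np.eye(3)) for k, n, t in spec.placements]
    else:
        placed = [
            ("residue", nm, rng.uniform(-spec.radius, spec.radius, size=3), _rotation_matrix(rng))
            for nm in _compose_exact(
                spec.n_protein_atoms,
                {"GLY": 4, "ALA": 5, "ASN": 8, "GLY+OXT": 5, "ALA+OXT": 6, "ASN+OXT": 9},
                rng,
            )
        ] + [
            ("ligand", nm, rng.uniform(-spec.radius / 2, spec.radius / 2, size=3), _rotation_matrix(rng))
            for nm in _compose_exact(
                spec.n_ligand_atoms,
                {"ethanol": 3, "acetone": 4, "benzene": 6},
                rng,
            )
        ]

    for attempt in range(200):
        records, lig_frags = _instantiate(placed)
        all_xyz = np.vstack(
            [r.coords for r in records]
            + [xyz for _, atoms in lig_frags for _, xyz in atoms]
        )
        if len(all_xyz) < 2:
            break
        d = np.linalg.norm(all_xyz[:, None, :] - all_xyz[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= spec.min_separation:
            break
        if spec.placements is not None:
            raise GenerationError(
                f"explicit placement has atoms {d.min():.2f} A apart "
                f"(< {spec.min_separation} A)"
            )
        # re-draw the random translations and try again
        placed = [
            (k, n, rng.uniform(-spec.radius, spec.radius, size=3), _rotation_matrix(rng))
            if k != "ligand"
            else (k, n, rng.uniform(-spec.radius / 2, spec.radius / 2, size=3), _rotation_matrix(rng))
            for k, n, _, _ in placed
        ]
    else:
        raise GenerationError("could not place fragments without clashes")

    pdb_text = write_protein(records)
    sdf_text = _ligand_sdf(lig_frags)
    ligand = _parse_sdf_text(sdf_text)

    # Ground truth: every typed heavy-atom pair with its exact distance.
    rows = []
    typed_protein = [
        (i, r, table.get(r.residue_name, r.atom_name)) for i, r in enumerate(records)
    ]
    lig_heavy = ligand.heavy_atom_indices
    for i, rec, ptype in typed_protein:
        if ptype is None:
            continue
        for j in lig_heavy:
            ltype = str(type_ligand_atom(ligand.mol, j))
            rows.append(
                {
                    "protein_index": i,
                    "ligand_index": j,
                    "protein_type": str(ptype),
                    "ligand_type": ltype,
                    "distance": float(np.linalg.norm(rec.coords - ligand.coords(j))),
                }
            )
    ground_truth = pd.DataFrame(
        rows, columns=["protein_index", "ligand_index", "protein_type", "ligand_type", "distance"]
    )
    return SyntheticComplex(pdb_text, sdf_text, ground_truth, records, ligand)


def _instantiate(placed):
    records, lig_frags = [], []
    for kind, name, translation, rotation in placed:
        if kind == "residue":
            res_name, _, oxt = name.partition("+")
            atoms = list(_RESIDUE_COORDS[res_name]) + ([_OXT_COORD] if oxt else [])
            for atom_name, local in atoms:
                xyz = rotation @ np.asarray(local) + translation
                records.append(
                    ProteinAtomRecord(
                        residue_name=res_name, atom_name=atom_name, chain_id="A", coords=xyz
                    )
                )
        elif kind == "atom":
            res_name, _, atom_name = name.partition(":")
            records.append(
                ProteinAtomRecord(
                    residue_name=res_name, atom_name=atom_name, chain_id="A",
                    coords=np.asarray(translation),
                )
            )
        elif kind == "ligand":
            atoms, bonds = _LIGAND_TEMPLATES[name]
            moved = [
                (elem, tuple(rotation @ np.asarray(xyz) + translation)) for elem, xyz in atoms
            ]
            lig_frags.append(((name, bonds), moved))
        else:
            raise ValueError(f"unknown placement kind {kind!r}")
    return records, lig_frags


def _ligand_sdf(lig_frags) -> str:
    all_atoms, all_bonds, offset, names = [], [], 0, []
    for (name, bonds), atoms in lig_frags:
        names.append(name)
        all_atoms.extend(atoms)
        all_bonds.extend((i + offset, j + offset, o) for i, j, o in bonds)
        offset += len(atoms)
    return _molblock("_".join(names), all_atoms, all_bonds) + "$$$$\n"


def _parse_sdf_text(sdf_text: str) -> LigandMol:
    mol = Chem.MolFromMolBlock(sdf_text.split("$$$$")[0], removeHs=False, sanitize=True)
    if mol is None:
        raise GenerationError("emitted SDF text failed to re-parse")
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else "synthetic"
    return LigandMol(mol=mol, name=name)


def template_ligand(name: str) -> LigandMol:
    """One ligand template (acetone, benzene or ethanol) as a parsed molecule."""
    atoms, bonds = _LIGAND_TEMPLATES[name]
    return _parse_sdf_text(_molblock(name, atoms, bonds) + "$$$$\n")


def expected_pair_counts(
    ground_truth: pd.DataFrame, distance: float, mode: str = "ecif"
) -> dict[str, int]:
    """Brute-force double-loop pair counts over a ground-truth table.

    Independent oracle for ``featurize_complex``: iterates rows of the
    table and tallies canonical names directly.
    """
    counts: dict[str, int] = {}
    for row in ground_truth.itertuples(index=False):
        base = f"{row.protein_type}-{row.ligand_type}"
        if mode.lower() == "ecif":
            if row.distance <= distance:
                counts[base] = counts.get(base, 0) + 1
        else:
            name = base + ("-l" if row.distance <= distance else "-h")
            counts[name] = counts.get(name, 0) + 1
    return counts


# --------------------------------------------------------------------------
# Synthetic regression data
# --------------------------------------------------------------------------


@dataclass
class SyntheticRegressionSpec:
    """Planted-signal linear regression dataset.

    ``y = X[:, :informative] @ effect_sizes + eps`` with standard-normal
    features and Gaussian noise.  When ``relative_noise`` is set, the noise
    standard deviation is ``noise_sigma`` times the standard deviation of
    the noiseless signal.
    """

    n_samples: int = 500
    n_informative: int = 5
    n_noise: int = 195
    effect_sizes: tuple[float, ...] | None = None
    noise_sigma: float = 0.3
    relative_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < self.n_informative + 1:
            raise ValueError("need n_samples >= n_informative + 1")
        if self.effect_sizes is None:
            self.effect_sizes = tuple(1.0 for _ in range(self.n_informative))
        if len(self.effect_sizes) != self.n_informative:
            raise ValueError("effect_sizes length must equal n_informative")


def make_regression(spec: SyntheticRegressionSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate (X, y); informative columns are named ``signal_*``."""
    rng = np.random.RandomState(spec.seed)
    p = spec.n_informative + spec.n_noise
    X = rng.normal(size=(spec.n_samples, p))
    beta = np.asarray(spec.effect_sizes, dtype=float)
    signal = X[:, : spec.n_informative] @ beta
    if spec.relative_noise and spec.n_informative > 0:
        sigma = spec.noise_sigma * signal.std()
    else:
        sigma = spec.noise_sigma
    y = signal + (rng.normal(scale=sigma, size=spec.n_samples) if sigma > 0 else 0.0)
    columns = [f"signal_{i}" for i in range(spec.n_informative)] + [
        f"noise_{i}" for i in range(spec.n_noise)
    ]
    return (
        pd.DataFrame(X, columns=columns),
        pd.Series(y, name="y"),
    )
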