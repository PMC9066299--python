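"""The 194 ligand-level 2-D physicochemical/topological descriptors.

These are whole-molecule RDKit descriptors (Crippen atomic-contribution
logP and molar refractivity, VSA-partitioned surface terms, Kier-Hall
valence connectivity indices Chi0v..Chi4v, Gasteiger partial-charge extrema,
E-state indices, ring/H-bond/rotor counts and the fragment counts) used to
augment the interaction pair features.  The manifest of 194 names is frozen
as a shipped data file; descriptors are functions of the 2-D molecular
graph only, so the vector is invariant to atom ordering and coordinates.

A descriptor that is undefined for a molecule (e.g. charge extrema when
Gasteiger charges fail) is imputed to 0 and logged, keeping matrices
rectangular.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .errors import EmptyStructureError, VocabularyError
from .io import LigandMol

logger = logging.getLogger(__name__)

N_DESCRIPTORS = 194


@lru_cache(maxsize=1)
def descriptor_names() -> list[str]:
    """The fixed, ordered 194-descriptor manifest."""
    text = resources.files("pdecif.data").joinpath("ligand_descriptors.txt").read_text()
    names = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(names) != N_DESCRIPTORS or len(set(names)) != N_DESCRIPTORS:
        raise VocabularyError(
            f"descriptor manifest must hold {N_DESCRIPTORS} unique names, got {len(names)}"
        )
    available = dict(Descriptors._descList)
    missing = [n for n in names if n not in available]
    if missing:
        raise VocabularyError(f"descriptors missing from RDKit: {missing}")
    return names


@dataclass
class LigandDescriptorVector:
    """Ordered, named 194-vector of ligand descriptors for one molecule."""

    values: np.ndarray
    names: list[str]
    imputed: list[str]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def compute_ligand_descriptors(mol: LigandMol | Chem.Mol) -> LigandDescriptorVector:
    """Compute all 194 descriptors; undefined values are imputed to 0."""
    rdmol = mol.mol if isinstance(mol, LigandMol) else mol
    if rdmol is None or not any(a.GetAtomicNum() > 1 for a in rdmol.GetAtoms()):
        raise EmptyStructureError("cannot compute descriptors of an empty molecule")
    try:
        # Descriptor definitions assume implicit hydrogens; explicit ones would
        # enter the graph as vertices and skew the topological indices.
        rdmol = Chem.RemoveHs(rdmol)
    except Exception:
        pass
    functions = dict(Descriptors._descList)
    names = descriptor_names()
    values = np.zeros(len(names), dtype=float)
    imputed: list[str] = []
    for i, name in enumerate(names):
        try:
            v = float(functions[name](rdmol))
        except Exception:
            v = math.nan
        if not math.isfinite(v):
            imputed.append(name)
            v = 0.0
        values[i] = v
    if imputed:
        logger.warning("imputed %d undefined descriptors to 0: %s", len(imputed), imputed)
    return LigandDescriptorVector(values=values, names=list(names), imputed=imputed)
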