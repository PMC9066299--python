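"""Protein-ligand atom-type pair counting: ECIF and PDECIF descriptors.

ECIF descriptors count occurrences of (protein type, ligand type) pairs whose
atoms lie within a distance threshold ``d``.  PDECIF splits every pair into a
short-range count (distance <= d, suffix ``-l``) and an uncapped long-range
count (distance > d, suffix ``-h``); the suffixes are purely delineating
symbols.  With 22 protein and 70 ligand types the ECIF vocabulary holds
22 x 70 = 1540 pairs and the PDECIF vocabulary twice that.

Canonical pair names put the protein type first: ``ptype-ltype`` and, for
PDECIF, ``ptype-ltype-l`` / ``ptype-ltype-h``.  A boundary tie (distance
exactly ``d``) counts as short/within, and distances are compared in double
precision straight from the file coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .atom_types import (
    ProteinTypeTable,
    build_protein_type_table,
    load_ligand_vocabulary,
    type_ligand_atom,
)
from .descriptors import compute_ligand_descriptors, descriptor_names
from .errors import DegenerateMatrixError, EmptyComplexError
from .io import ComplexEntry, LigandMol, ProteinAtomRecord, read_ligand, read_protein

logger = logging.getLogger(__name__)


class Bin(Enum):
    NONE = ""
    SHORT = "-l"
    LONG = "-h"


@dataclass(frozen=True)
class PairDescriptor:
    """A protein-type/ligand-type pair, optionally tagged with a distance bin."""

    protein_type: str
    ligand_type: str
    bin: Bin = Bin.NONE

    @property
    def name(self) -> str:
        return f"{self.protein_type}-{self.ligand_type}{self.bin.value}"

    @classmethod
    def from_name(cls, name: str) -> "PairDescriptor":
        tag = Bin.NONE
        core = name
        for b in (Bin.SHORT, Bin.LONG):
            if name.endswith(b.value):
                tag, core = b, name[: -len(b.value)]
                break
        parts = core.split("-")
        if len(parts) != 2:
            raise ValueError(f"not a canonical pair name: {name!r}")
        return cls(parts[0], parts[1], tag)


def enumerate_vocabulary(
    mode: str = "ecif",
    table: ProteinTypeTable | None = None,
    ligand_vocabulary: list[str] | None = None,
) -> list[str]:
    """Ordered descriptor names for a mode: 1540 for ECIF, 3080 for PDECIF.

    Order: protein types (shipped order) outer, ligand types (shipped order)
    inner; for PDECIF each pair appears as short (``-l``) then long (``-h``).
    """
    mode = _check_mode(mode)
    table = table if table is not None else build_protein_type_table()
    lig = ligand_vocabulary if ligand_vocabulary is not None else load_ligand_vocabulary()
    names = []
    for ptype in table.distinct_types():
        for ltype in lig:
            if mode == "ecif":
                names.append(f"{ptype}-{ltype}")
            else:
                names.append(f"{ptype}-{ltype}-l")
                names.append(f"{ptype}-{ltype}-h")
    return names


def _check_mode(mode: str) -> str:
    m = str(mode).lower()
    if m not in ("ecif", "pdecif"):
        raise ValueError(f"mode must be 'ecif' or 'pdecif', got {mode!r}")
    return m


@dataclass
class FeatureVector:
    """Counts for one complex, aligned to the mode's descriptor vocabulary."""

    counts: np.ndarray
    names: list[str]
    complex_id: str
    distance: float
    mode: str

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.names, name=self.complex_id)


@dataclass
class FeatureMatrix:
    """Complexes x named descriptor columns, with pK affinity labels."""

    X: pd.DataFrame
    y: pd.Series
    distance: float
    mode: str

    @property
    def column_names(self) -> list[str]:
        return list(self.X.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["affinity"] = self.y
        return out


def _typed_protein_atoms(
    protein_atoms: list[ProteinAtomRecord], table: ProteinTypeTable
) -> tuple[np.ndarray, list[str]]:
    coords, types = [], []
    skipped = 0
    for rec in protein_atoms:
        atype = table.get(rec.residue_name, rec.atom_name)
        if atype is None:
            skipped += 1
            continue
        coords.append(rec.coords)
        types.append(str(atype))
    if skipped:
        logger.warning("skipped %d untypeable protein atoms", skipped)
    return np.asarray(coords, dtype=float), types


def _typed_ligand_atoms(
    ligand: LigandMol, vocabulary: set[str]
) -> tuple[np.ndarray, list[str]]:
    coords, types = [], []
    skipped = 0
    for idx in ligand.heavy_atom_indices:
        t = str(type_ligand_atom(ligand.mol, idx))
        if t not in vocabulary:
            skipped += 1
            continue
        coords.append(ligand.coords(idx))
        types.append(t)
    if skipped:
        logger.warning(
            "ligand %s: skipped %d atoms outside the 70-type vocabulary",
            ligand.name,
            skipped,
        )
    return np.asarray(coords, dtype=float), types


def featurize_complex(
    protein_atoms: list[ProteinAtomRecord],
    ligand: LigandMol,
    distance: float,
    mode: str = "ecif",
    table: ProteinTypeTable | None = None,
    ligand_vocabulary: list[str] | None = None,
    complex_id: str = "",
) -> FeatureVector:
    """Count typed protein-ligand heavy-atom pairs for one complex.

    ECIF: a pair with Euclidean distance r contributes iff r <= d.
    PDECIF: r <= d increments the ``-l`` count, r > d the (uncapped) ``-h``
    count, so every typed pair is counted exactly once.
    """
    mode = _check_mode(mode)
    if not distance > 0:
        raise ValueError(f"distance threshold must be positive, got {distance}")
    table = table if table is not None else build_protein_type_table()
    lig_vocab = ligand_vocabulary if ligand_vocabulary is not None else load_ligand_vocabulary()
    names = enumerate_vocabulary(mode, table, lig_vocab)
    index = {n: i for i, n in enumerate(names)}

    p_coords, p_types = _typed_protein_atoms(protein_atoms, table)
    l_coords, l_types = _typed_ligand_atoms(ligand, set(lig_vocab))
    if len(p_types) == 0 or len(l_types) == 0:
        raise EmptyComplexError(
            f"complex {complex_id or ligand.name!r}: no typeable atoms on "
            f"{'protein' if len(p_types) == 0 else 'ligand'} side"
        )

    counts = np.zeros(len(names), dtype=np.int64)
    dist = cdist(p_coords, l_coords)
    within = dist <= distance
    for i, ptype in enumerate(p_types):
        for j, ltype in enumerate(l_types):
            if mode == "ecif":
                if within[i, j]:
                    counts[index[f"{ptype}-{ltype}"]] += 1
            else:
                suffix = "-l" if within[i, j] else "-h"
                counts[index[f"{ptype}-{ltype}{suffix}"]] += 1
    return FeatureVector(counts, names, complex_id, float(distance), mode)


def assemble_matrix(
    entries: list[ComplexEntry],
    distance: float,
    mode: str = "ecif",
    include_ligand_descriptors: bool = False,
) -> FeatureMatrix:
    """Featurize every indexed complex into one matrix with affinity labels.

    Ligand-descriptor columns, when requested, are appended after the pair
    columns.  Per-complex failures are collected and reported together; any
    failure aborts the assembly.
    """
    featurizer = EcifFeaturizer(
        mode=mode, distance=distance, include_ligand_descriptors=include_ligand_descriptors
    ).fit()
    X = featurizer.transform(entries)
    y = pd.Series(
        [e.affinity for e in entries], index=[e.complex_id for e in entries], name="affinity"
    )
    return FeatureMatrix(X=X, y=y, distance=float(distance), mode=_check_mode(mode))


def prune_zero_columns(matrix: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Drop columns that are zero in every complex; keep survivor order.

    Returns the pruned matrix and the kept-column names, so the identical
    projection can be applied to a held-out test matrix.
    """
    if matrix.X.shape[0] == 0:
        raise DegenerateMatrixError("empty feature matrix")
    pruner = ZeroColumnPruner().fit(matrix.X)
    kept = list(pruner.kept_names_)
    if not kept:
        raise DegenerateMatrixError("all feature columns are zero")
    pruned = FeatureMatrix(
        X=pruner.transform(matrix.X), y=matrix.y, distance=matrix.distance, mode=matrix.mode
    )
    return pruned, kept


class EcifFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer from complexes to pair counts.

    Parameters
    ----------
    mode : {"ecif", "pdecif"}
        Capped pair counts, or short/long distance-binned counts.
    distance : float
        Distance threshold d in Angstroms (boundary inclusive for short).
    include_ligand_descriptors : bool
        Append the 194 ligand 2-D descriptors after the pair columns.

    ``transform`` accepts a list of :class:`ComplexEntry` (files are read on
    the fly) or of ``(protein_atoms, LigandMol)`` tuples, and returns a
    DataFrame with canonical descriptor names as columns.
    """

    def __init__(
        self,
        mode: str = "ecif",
        distance: float = 6.0,
        include_ligand_descriptors: bool = False,
    ):
        self.mode = mode
        self.distance = distance
        self.include_ligand_descriptors = include_ligand_descriptors

    def fit(self, X=None, y=None) -> "EcifFeaturizer":
        self.table_ = build_protein_type_table()
        self.ligand_vocabulary_ = load_ligand_vocabulary()
        self.feature_names_ = enumerate_vocabulary(
            self.mode, self.table_, self.ligand_vocabulary_
        )
        if self.include_ligand_descriptors:
            self.feature_names_ = self.feature_names_ + descriptor_names()
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "feature_names_")
        rows, ids, failures = [], [], []
        for item in X:
            try:
                rows.append(self._one_row(item))
                ids.append(self._item_id(item, len(ids)))
            except Exception as exc:
                failures.append(f"{self._item_id(item, len(ids))}: {exc}")
        if failures:
            raise EmptyComplexError(
                "featurization failed for %d complex(es): %s"
                % (len(failures), "; ".join(failures))
            )
        return pd.DataFrame(rows, index=ids, columns=self.feature_names_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)

    @staticmethod
    def _item_id(item, fallback: int) -> str:
        if isinstance(item, ComplexEntry):
            return item.complex_id
        return f"complex_{fallback}"

    def _one_row(self, item) -> np.ndarray:
        if isinstance(item, ComplexEntry):
            protein_atoms = read_protein(item.protein_path)
            ligand = read_ligand(item.ligand_path)
            cid = item.complex_id
        else:
            protein_atoms, ligand = item
            cid = ligand.name
        vec = featurize_complex(
            protein_atoms,
            ligand,
            self.distance,
            self.mode,
            table=self.table_,
            ligand_vocabulary=self.ligand_vocabulary_,
            complex_id=cid,
        )
        if not self.include_ligand_descriptors:
            return vec.counts.astype(float)
        desc = compute_ligand_descriptors(ligand).values
        return np.concatenate([vec.counts.astype(float), desc])


class ZeroColumnPruner(BaseEstimator, TransformerMixin):
    """Drop all-zero columns, learned on training data only.

    The fitted mask is reapplied verbatim to held-out matrices so train and
    test stay aligned without information leaking from the test set.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "ZeroColumnPruner":
        frame = pd.DataFrame(X)
        self.support_mask_ = (frame != 0).any(axis=0).to_numpy()
        self.kept_names_ = list(frame.columns[self.support_mask_])
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "support_mask_")
        frame = pd.DataFrame(X)
        if frame.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {frame.shape[1]}"
            )
        return frame.loc[:, self.support_mask_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_mask_")
        return self.support_mask_.copy()
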