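"""Pair counting: vocabulary enumeration, oracle equivalence, invariants."""

import numpy as np
import pandas as pd
import pytest
from rdkit.Geometry import Point3D

from pdecif import (
    EcifFeaturizer,
    FeatureMatrix,
    PairDescriptor,
    ProteinAtomRecord,
    ZeroColumnPruner,
    enumerate_vocabulary,
    expected_pair_counts,
    featurize_complex,
    make_complex,
    prune_zero_columns,
    template_ligand,
    SyntheticComplexSpec,
)
from pdecif.errors import DegenerateMatrixError, EmptyComplexError
from pdecif.featurize import Bin


def nonzero(fv):
    return {n: int(c) for n, c in zip(fv.names, fv.counts) if c}


def single_pair_complex(r):
    """One ASN OXT protein atom and one acetone, carbonyl carbon at distance r."""
    return make_complex(
        SyntheticComplexSpec(
            placements=[("atom", "ASN:OXT", (0.0, 0.0, 0.0)), ("ligand", "acetone", (r, 0.0, 0.0))]
        )
    )


class TestVocabularyEnumeration:
    def test_ecif_vocabulary_has_1540_pairs(self):
        assert len(enumerate_vocabulary("ecif")) == 1540

    def test_pdecif_vocabulary_doubles_to_3080(self):
        names = enumerate_vocabulary("pdecif")
        assert len(names) == 3080
        assert all(n.endswith(("-l", "-h")) for n in names)

    def test_short_bin_precedes_long_for_every_pair(self):
        names = enumerate_vocabulary("pdecif")
        assert all(
            names[i].endswith("-l") and names[i + 1] == names[i][:-2] + "-h"
            for i in range(0, len(names), 2)
        )

    def test_pair_descriptor_name_round_trips(self):
        for name in ("C;4;3;0;0;0-O;2;1;0;0;0", "C;4;3;0;0;0-O;2;1;0;0;0-l",
                     "N;3;2;1;0;0-C;4;3;0;1;1-h"):
            assert PairDescriptor.from_name(name).name == name

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            enumerate_vocabulary("both")


class TestSinglePairExamples:
    def test_within_threshold_ecif_counts_one(self):
        cx = single_pair_complex(3.0)
        fv = featurize_complex(cx.protein_records, cx.ligand, 6.0, "ecif")
        counts = nonzero(fv)
        # OXT (O;2;1;0;0;0) is within 6 A of all four acetone heavy atoms
        assert counts["O;2;1;0;0;0-C;4;3;0;0;0"] == 1
        assert sum(counts.values()) == 4

    def test_within_threshold_pdecif_fills_short_bin(self):
        cx = single_pair_complex(3.0)
        fv = featurize_complex(cx.protein_records, cx.ligand, 6.0, "pdecif")
        counts = nonzero(fv)
        assert counts["O;2;1;0;0;0-C;4;3;0;0;0-l"] == 1
        assert "O;2;1;0;0;0-C;4;3;0;0;0-h" not in counts

    def test_beyond_threshold_uncapped_long_bin(self):
        cx = single_pair_complex(20.0)
        ecif = featurize_complex(cx.protein_records, cx.ligand, 6.0, "ecif")
        assert ecif.counts.sum() == 0
        pdecif = featurize_complex(cx.protein_records, cx.ligand, 6.0, "pdecif")
        counts = nonzero(pdecif)
        assert counts["O;2;1;0;0;0-C;4;3;0;0;0-h"] == 1
        assert sum(counts.values()) == 4  # every pair lands in a bin

    def test_boundary_distance_counts_as_short(self):
        cx = single_pair_complex(6.0)
        fv = featurize_complex(cx.protein_records, cx.ligand, 6.0, "pdecif")
        assert nonzero(fv)["O;2;1;0;0;0-C;4;3;0;0;0-l"] == 1


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("mode,d", [("ecif", 6.0), ("pdecif", 4.0), ("pdecif", 8.0)])
def test_counts_equal_brute_force_oracle(seed, mode, d):
    cx = make_complex(SyntheticComplexSpec(n_protein_atoms=20, n_ligand_atoms=8, seed=seed))
    fv = featurize_complex(cx.protein_records, cx.ligand, d, mode)
    assert nonzero(fv) == expected_pair_counts(cx.ground_truth, d, mode)


class TestStructuralIdentities:
    def test_short_subvector_equals_ecif_at_equal_distance(self, small_complex):
        for d in (2.0, 6.0, 10.0):
            ecif = featurize_complex(small_complex.protein_records, small_complex.ligand, d, "ecif")
            pdecif = featurize_complex(
                small_complex.protein_records, small_complex.ligand, d, "pdecif"
            )
            short = {n[:-2]: c for n, c in zip(pdecif.names, pdecif.counts) if n.endswith("-l")}
            full = dict(zip(ecif.names, ecif.counts))
            assert short == full

    def test_total_pdecif_counts_conserve_typed_pair_product(self, small_complex):
        n_pairs = len(small_complex.ground_truth)
        for d in (1.0, 5.0, 50.0):
            fv = featurize_complex(
                small_complex.protein_records, small_complex.ligand, d, "pdecif"
            )
            assert fv.counts.sum() == n_pairs

    def test_ecif_counts_monotone_in_distance(self, small_complex):
        previous = None
        for d in (2.0, 4.0, 6.0, 8.0, 10.0):
            fv = featurize_complex(small_complex.protein_records, small_complex.ligand, d, "ecif")
            if previous is not None:
                assert np.all(fv.counts >= previous)
            previous = fv.counts

    def test_counts_invariant_under_rigid_transformation(self, small_complex):
        rng = np.random.RandomState(11)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = rng.uniform(-30, 30, size=3)

        moved_protein = [
            ProteinAtomRecord(r.residue_name, r.atom_name, r.chain_id, R @ r.coords + t)
            for r in small_complex.protein_records
        ]
        from rdkit import Chem

        moved_mol = Chem.Mol(small_complex.ligand.mol)
        conf = moved_mol.GetConformer()
        for i in range(moved_mol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            moved = R @ np.array([p.x, p.y, p.z]) + t
            conf.SetAtomPosition(i, Point3D(*moved))
        moved_ligand = type(small_complex.ligand)(mol=moved_mol, name="moved")

        for mode in ("ecif", "pdecif"):
            before = featurize_complex(
                small_complex.protein_records, small_complex.ligand, 6.0, mode
            )
            after = featurize_complex(moved_protein, moved_ligand, 6.0, mode)
            assert np.array_equal(before.counts, after.counts)

    def test_no_typeable_atoms_raises_empty_complex(self):
        record = ProteinAtomRecord("XYZ", "QQ", "A", np.zeros(3))
        with pytest.raises(EmptyComplexError):
            featurize_complex([record], template_ligand("acetone"), 6.0, "ecif")

    def test_nonpositive_distance_rejected(self, small_complex):
        with pytest.raises(ValueError):
            featurize_complex(small_complex.protein_records, small_complex.ligand, 0.0)


class TestPruning:
    def _matrix(self, frame):
        y = pd.Series(np.linspace(4, 8, len(frame)), index=frame.index, name="affinity")
        return FeatureMatrix(X=frame, y=y, distance=6.0, mode="ecif")

    def test_zero_columns_removed_order_preserved(self):
        frame = pd.DataFrame(
            {"a": [0, 0], "b": [1, 0], "c": [0, 0], "d": [0, 2]}, index=["x", "y"]
        )
        pruned, kept = prune_zero_columns(self._matrix(frame))
        assert kept == ["b", "d"]
        assert list(pruned.X.columns) == ["b", "d"]

    def test_matrix_without_zero_columns_unchanged(self):
        frame = pd.DataFrame({"a": [1, 0], "b": [0, 2]}, index=["x", "y"])
        pruned, kept = prune_zero_columns(self._matrix(frame))
        assert kept == ["a", "b"]
        pd.testing.assert_frame_equal(pruned.X, frame)

    def test_all_zero_matrix_is_degenerate(self):
        frame = pd.DataFrame({"a": [0, 0], "b": [0, 0]}, index=["x", "y"])
        with pytest.raises(DegenerateMatrixError):
            prune_zero_columns(self._matrix(frame))

    def test_survivors_match_independent_column_scan(self):
        rng = np.random.RandomState(5)
        data = rng.poisson(0.05, size=(20, 300))
        frame = pd.DataFrame(data, columns=[f"c{i}" for i in range(300)])
        _, kept = prune_zero_columns(self._matrix(frame))
        brute = [c for c in frame.columns if any(v != 0 for v in frame[c])]
        assert kept == brute

    def test_pruner_applies_train_mask_to_test_matrix(self):
        train = pd.DataFrame({"a": [0, 0], "b": [1, 2], "c": [3, 0]})
        test = pd.DataFrame({"a": [9, 9], "b": [0, 0], "c": [1, 1]})
        pruner = ZeroColumnPruner().fit(train)
        projected = pruner.transform(test)
        # support comes from the training matrix only
        assert list(projected.columns) == ["b", "c"]

    def test_pruner_rejects_mismatched_width(self):
        pruner = ZeroColumnPruner().fit(pd.DataFrame({"a": [1], "b": [0]}))
        with pytest.raises(ValueError):
            pruner.transform(pd.DataFrame({"a": [1]}))


class TestFeaturizerTransformer:
    def test_matrix_shape_without_and_with_ligand_descriptors(self, small_complex):
        pairs = [(small_complex.protein_records, small_complex.ligand)] * 3
        plain = EcifFeaturizer(mode="ecif", distance=6.0).fit().transform(pairs)
        assert plain.shape == (3, 1540)
        augmented = (
            EcifFeaturizer(mode="ecif", distance=6.0, include_ligand_descriptors=True)
            .fit()
            .transform(pairs)
        )
        assert augmented.shape == (3, 1540 + 194)

    def test_pdecif_with_descriptors_width(self, small_complex):
        pairs = [(small_complex.protein_records, small_complex.ligand)]
        wide = (
            EcifFeaturizer(mode="pdecif", distance=8.0, include_ligand_descriptors=True)
            .fit()
            .transform(pairs)
        )
        assert wide.shape == (1, 3080 + 194)

    def test_feature_names_out_matches_columns(self, small_complex):
        featurizer = EcifFeaturizer(mode="pdecif", distance=6.0).fit()
        frame = featurizer.transform([(small_complex.protein_records, small_complex.ligand)])
        assert list(featurizer.get_feature_names_out()) == list(frame.columns)

    def test_sklearn_param_round_trip(self):
        featurizer = EcifFeaturizer(mode="pdecif", distance=4.5)
        params = featurizer.get_params()
        assert params["mode"] == "pdecif" and params["distance"] == 4.5
        clone = EcifFeaturizer(**params)
        assert clone.get_params() == params
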