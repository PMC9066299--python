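# pdecif

Protein–ligand interaction featurization and binding-affinity scoring with
**ECIF** (extended connectivity interaction features) and **PDECIF**
(pair-distance ECIF), for computational chemists building and auditing
machine-learned scoring functions.

## The representations

Every heavy atom is typed by six environment properties joined with
semicolons — element, explicit valence, attached heavy atoms, attached
hydrogens, aromaticity, ring membership — e.g. `C;4;3;0;0;0` (a carbonyl
carbon) or `O;2;1;0;0;0` (a carbonyl oxygen, also the type of a terminal
`ASN-OXT`). Protein atoms are typed by a (residue, atom-name) lookup table
built from amino-acid topology templates (22 distinct types); ligand atoms
are typed from the perceived RDKit molecular graph against a fixed 70-type
vocabulary. See `docs/methods.md` for the typing conventions and the
provenance of both vocabularies.

A complex is described by counts of protein–ligand type pairs:

- **ECIF** — for each of the 22 × 70 = 1540 ordered pairs
  `ptype-ltype`, the number of heavy-atom pairs with Euclidean distance
  *r* ≤ *d* (the threshold, e.g. 6 Å).
- **PDECIF** — each pair splits into a short-range count `ptype-ltype-l`
  (*r* ≤ *d*) and an *uncapped* long-range count `ptype-ltype-h`
  (*r* > *d*), 3080 columns in all. The suffixes are purely delineating
  symbols.

Matrices can be augmented with 194 whole-molecule 2-D RDKit descriptors
(Crippen logP, VSA partitions, Chi valence connectivity indices,
partial-charge extrema, …), and all-zero columns are pruned on training
data only.

Scoring functions are gradient boosted trees (XGBoost) tuned by exhaustive
grid search over boosting rounds ∈ {500, 1000, 1500, 2000}, max depth ∈
{2, 4, 6, 8} and learning rate ∈ {0.001, 0.01, 0.1, 0.2, 0.3}, with the
candidates scored on training data under one of three resampling schemes —
a 70–30 split, 5-fold CV or 10-fold CV, performed once — and reported as
Pearson *R* and RMSE (pK units) on an untouched test set. Boruta
all-relevant feature selection (shadow features, binomial hit tests,
random-forest backend) is included for feature auditing.

## Worked example

```python
from pdecif import (SyntheticComplexSpec, make_complex, featurize_complex)

cx = make_complex(SyntheticComplexSpec(
    placements=[("atom", "ASN:OXT", (0.0, 0.0, 0.0)),
                ("ligand", "acetone", (3.0, 0.0, 0.0))]))
fv = featurize_complex(cx.protein_records, cx.ligand, distance=6.0, mode="pdecif")
print({n: int(c) for n, c in zip(fv.names, fv.counts) if c})
```

prints

```
{'O;2;1;0;0;0-C;4;1;3;0;0-l': 2, 'O;2;1;0;0;0-C;4;3;0;0;0-l': 1, 'O;2;1;0;0;0-O;2;1;0;0;0-l': 1}
```

The protein side is a single terminal carboxylate oxygen (`O;2;1;0;0;0`);
the acetone carbonyl carbon placed 3 Å away contributes one short-range
`…-C;4;3;0;0;0-l` pair, its oxygen one `…-O;2;1;0;0;0-l` pair, and the two
methyl carbons (`C;4;1;3;0;0`) two more — all within the 6 Å threshold, so
every `-h` column stays zero.

The same pipeline runs from the shell:

```bash
pdecif fixtures --n-protein 20 --n-ligand 8 --n-complexes 15 --seed 3 --out toy/
pdecif dataset  --index toy/index.csv --mode pdecif --distance 6 --out toy/matrix.csv
pdecif train    --matrix toy/matrix.csv --resampling cv5 --seed 1 --out toy/model
pdecif evaluate --model toy/model --matrix toy/matrix.csv
pdecif select   --matrix toy/matrix.csv --max-runs 100 --seed 1 --out toy/selected.txt
```

## Layout

- `src/pdecif/atom_types.py` — six-property typing; protein table; vocabularies
- `src/pdecif/featurize.py` — pair counting (`EcifFeaturizer`), pruning
- `src/pdecif/descriptors.py` — the 194 ligand 2-D descriptors
- `src/pdecif/modeling.py` — resampling, grid search, `GradientBoostedScorer`
- `src/pdecif/boruta.py` — Boruta selection (`BorutaSelector`)
- `src/pdecif/io.py` — PDB / MOL / SDF / index reading
- `src/pdecif/fixtures.py` — synthetic complexes and regression data
- `src/pdecif/data/` — auditable vocabulary and descriptor manifests
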