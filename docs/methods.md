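# Methods

## Atom-environment typing

An atom type is the string `symbol;valence;heavy;h;aromatic;ring`:
element symbol; explicit valence (sum of bond orders, hydrogens included);
number of bonded heavy atoms; number of bonded hydrogens (explicit +
implicit); aromaticity and ring membership as 0/1. Only heavy atoms are
typed; hydrogens contribute solely to the valence and H-count properties.

**Ligand side.** Types are computed from the RDKit molecular graph after
sanitization: valence is `GetTotalValence()`, hydrogens via
`GetTotalNumHs(includeNeighbors=True)`, aromaticity is RDKit's default
model, and ring membership means membership in any SSSR ring. Explicit and
implicit hydrogens give identical types. The admissible ligand vocabulary
is fixed at 70 types (`data/ligand_atom_types.txt`, lexicographic order);
atoms whose computed type falls outside it are skipped from pair counting
with a logged warning, because the 1540-pair descriptor space is defined
only over the fixed vocabularies.

**Protein side.** Protein atoms are typed by exact (residue name, atom
name) lookup in a table built from hand-written topology templates of the
20 standard amino acids plus the terminal `OXT` (`atom_types.py`; also
shipped as `data/protein_atom_table.csv`). Aromatic side chains are
written in one Kekulé structure with the aromatic flag carried separately,
so valences are Kekulé bond-order sums — the same numbers RDKit perceives
on the ligand side (benzene CH: 2 + 1 + 1H = 4). Backbone atoms are typed
in mid-chain context (virtual `-C`/`+N` neighbours count toward degree and
valence); `OXT` is typed as a carbonyl-like oxygen, `O;2;1;0;0;0`.
Protonation conventions, chosen once for the dominant physiological state:

- carboxylates (Asp, Glu) anionic: one C=O, one C–O⁻ (`O;1;1;0;0;0`);
- Lys ammonium (`N;4;1;3;0;0`);
- Arg guanidinium in its symmetric delocalized form, all three C–N bonds
  at order 2 (`CZ` → `C;6;3;0;0;0`, `NE` → `N;4;2;1;0;0`, `NH1/NH2` →
  `N;4;1;2;0;0`);
- His neutral aromatic tautomer, proton on `ND1`;
- Cys thiol with one hydrogen (`S;2;1;1;0;0`).

Under these conventions the table realizes exactly 22 distinct protein
types; the builder raises if that cardinality is ever broken. Lookups
outside the table (non-standard residues, cofactors) return "absent" and
the atom is skipped — absence is a value, not an error.

**Vocabulary provenance.** The 22/70 cardinalities are the method's
defining constants, but the original reference tables are external data
and not re-derivable from their published description. Both shipped
vocabularies are therefore reconstructions: the protein table from the
templates above, and the 70-type ligand list curated to cover drug-like
chemistry (halogens, boron, carbon/nitrogen/oxygen environments in all
common valence/ring states, phosphate and sulfur groups). They are plain
text so they can be audited and swapped; all counting code reads them
through one loader.

## Pair counting

For a complex with typed protein atoms *P* and typed ligand heavy atoms
*L*, every pair (p, l) ∈ P × L contributes exactly once:

- **ECIF(d)**: increment `ptype-ltype` iff r ≤ d;
- **PDECIF(d)**: increment `ptype-ltype-l` iff r ≤ d, else
  `ptype-ltype-h` (no upper cap).

Conventions: canonical names are protein-type first; a boundary tie
(r exactly d) counts as short — "within a threshold" read inclusively;
distances are compared in double precision straight from the file
coordinates, no rounding. Column order is protein types (shipped order)
outer, ligand types inner, and `-l` immediately before `-h` per pair.
These choices give the identities the test suite enforces: the `-l`
sub-vector of PDECIF(d) equals ECIF(d) elementwise, total PDECIF counts
equal |P|·|L| independent of d, ECIF counts are monotone in d, and all
counts are invariant under rigid motion.

Zero-column pruning is fit on the training matrix only and the same
projection applied to test matrices; computing support on pooled data
would leak test-set information into the feature space.

## Ligand descriptors

194 whole-molecule 2-D descriptors are appended when requested
(`data/ligand_descriptors.txt`). The manifest is frozen from RDKit's 2-D
descriptor list minus sixteen entries that are either composite scores
(`qed`), fingerprint densities (`FpDensityMorgan1-3`), numerically fragile
(`Ipc`, `AvgIpc`, the eight `BCUT2D_*`), bookkeeping (`NumRadicalElectrons`)
or recent additions (`SPS`) — keeping every family the method's feature
analysis relies on (Crippen `MolLogP`, `SlogP_VSA*`, `Chi*v`,
partial-charge extrema). Descriptors are computed on the implicit-hydrogen
graph (explicit hydrogens are stripped first, since they would enter the
topological indices as vertices). Undefined values — e.g. Gasteiger-charge
extrema on a bare metal — are imputed to 0 and logged, keeping matrices
rectangular. The vector is invariant to atom order and 3-D coordinates.

## Scoring-function training

The learner is XGBoost regression (`reg:squarederror`, `hist` tree method;
every non-searched setting pinned in `FIXED_LEARNER_PARAMS`). The grid is
rounds × depth × learning-rate; candidates are scored on training data only
under one of three resampling schemes, each performed once without
repetition: a 70–30 split (training size ⌈0.7 n⌉), 5-fold or 10-fold CV
(shuffled, seed-driven). The winner is the lowest mean validation RMSE —
RMSE rather than R because squared error is the loss the learner
optimizes — with ties broken toward fewer rounds, then shallower trees,
then lower learning rate (the enumeration order, so "first minimum" is the
tie-break). The final model is refit on the full training set and reported
as Pearson R and RMSE on the untouched test set; constant predictions are
flagged (R undefined) rather than silently dropped, with RMSE still valid.
One seed drives split/fold shuffling and learner randomness. No early
stopping: rounds are taken literally from the grid.

## Boruta feature selection

Each run appends a freshly shuffled shadow copy of **all original
features**, fits a random forest (default 500 trees), and records a hit
for every still-undecided real feature whose importance exceeds the
maximum shadow importance. After each run a two-sided binomial test of the
cumulative hit count against p = 0.5, Bonferroni-corrected over the full
feature count, confirms (majority side) or rejects (minority side);
rejected features leave the model, confirmed ones remain but are no longer
tested. The loop stops when all features are decided or at `max_runs`
(default 500); leftovers are reported tentative, never force-resolved.
Drawing shadows from all original features (rather than only the shrinking
undecided pool) keeps the max-shadow bar at the original null spread;
without it, the last few chance-correlated survivors of a pure-noise
matrix face a collapsed shadow pool and get spuriously confirmed. At
α = 0.01 a planted signal confirms in ~14 runs; on 50-column pure-noise
matrices (n = 200) the expected number of confirmations is at the nominal
α-level per feature, i.e. usually zero, occasionally one.

## Synthetic data

`make_complex` assembles complexes from hand-audited fragments — GLY, ALA,
ASN residues (optionally with `OXT`) and acetone, benzene, ethanol with
explicit hydrogens — placed either at explicit coordinates or with seeded
random rotations/translations inside a sphere (default radius 8 Å),
re-drawing until no two atoms are closer than 0.5 Å. Atom counts are met
exactly by composing fragment sizes (a generation error names impossible
targets). Alongside the PDB/SDF text it emits a ground-truth table of every
typed pair with its exact distance; the brute-force double loop over that
table (`expected_pair_counts`) is the principal oracle of the test suite.
These fixtures exercise geometry, typing and counting exhaustively, but
they are not physically realistic binding poses: passing tests demonstrate
the correctness of the featurization machinery, not predictive performance
on real protein–ligand data, which requires external benchmark sets that
are deliberately outside this package's test surface.

`make_regression` plants a linear signal (`y = Xβ + ε`, standard-normal
features) with either absolute or signal-relative noise; column names mark
the ground truth for selection tests. Desk-scale study conditions used by
the acceptance checks: pair-count oracle on 100 random complexes (12–24
protein / 6–12 ligand heavy atoms); model recovery on n = 500 with 5
informative of 200 columns at noise σ = 0.3 × sd(signal) over a reduced
2×2×2 grid (rounds {100, 300}, depth {2, 4}, rate {0.1, 0.3}); Boruta with
`max_runs` = 100 on n = 200, 50 features. Full-scale grids and run counts
remain the defaults quoted above.

## Degenerate inputs and numerical choices

Empty structures, hydrogen-only molecules, zero-variance targets,
all-zero matrices, k > n folds, and sub-minimum sample counts raise typed
errors early. Metric computation requires length ≥ 3. Distances use exact
double-precision arithmetic (`scipy.spatial.distance.cdist`); counts are
64-bit integers. All randomness flows from explicit integer seeds through
`numpy.random.RandomState`, making every generator, resample, learner fit
and Boruta run reproducible bit-for-bit.

## Known limitations

- The reconstructed 22/70 vocabularies follow documented conventions but
  may differ from the original reference tables in individual entries
  (tautomer/protonation choices); feature *names* are therefore stable
  within this package but not guaranteed byte-compatible with externally
  produced ECIF feature files.
- Protein typing covers standard residues only; cofactors, metals, waters
  and non-standard residues are excluded by design.
- No protonation/charge assignment is performed on inputs; structures are
  typed as read.
- mmCIF input and automatic ligand-format conversion are out of scope; a
  readable PDB and MOL/SDF pair is required.
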