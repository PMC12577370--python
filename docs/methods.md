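# Methods

This note records the models, conventions and design choices behind the
package, and what the synthetic test battery does and does not
demonstrate.

## Fingerprint construction

A docking pose is represented by its receptor side only: for each protein
atom the eight ChemPLP interaction-term contributions, in the fixed order
ChemScore PLP.Hbond, ChemScore PLP.CHO, ChemScore PLP.Metal, PLP.S(bond),
PLP.S(metal), PLP.S(buried), PLP.S(nonpolar), PLP.S(repulsive). The raw
fingerprint inverts the sign of the first three terms, because the
docking engine reports the ChemScore-derived terms with the opposite
convention from the PLP surface terms; after inversion, "more favorable"
points the same way everywhere. The inversion is an involution — applying
it twice restores the input — which the tests assert.

Standardization projects the per-atom map onto the target-independent key
space *(residue type, interaction term, atom class)*. Each key's value is
the arithmetic mean over all protein atoms matching that triple,
**including** atoms whose contribution vector is all zero: an atom that
is present but non-interacting is information, and counting it makes the
mean independent of how a parser chooses to emit zero rows. A
`include_zero_atoms=False` flag provides the nonzero-only alternative.
A `positive_only` flag restricts the means to strictly favorable values,
for the variant of the fingerprint that tracks only positive
interactions; the default keeps all terms including PLP.S(repulsive),
since repulsion is exactly what distinguishes a wrong pose.

The dense layout enumerates residues (major), terms, atom classes
(minor). Defaults: the 20 standard amino acids and the five atom classes
DONOR, ACCEPTOR, DONACC, NONPOLAR, METAL — 800 keys. The atom-class
vocabulary is configurable because the scoring engine's own taxonomy
admits more than one 5-class reading (an ambivalent donor/acceptor class
versus a charged class); the layout carries a content hash so sparse maps
and dense vectors cannot be silently mixed. Nonstandard residues raise by
default; an opt-in OTHER bucket extends the layout instead. Missing keys
are zero-filled at vectorization — absence of an interaction is an
informative zero, not missing data.

## Docking I/O

The package defines a strict TSV fixture dialect (one pose header line
with molecule id / pose index / total fitness, one row per protein atom
with the atom descriptor plus eight term values, optional ligand
coordinate rows). Scores are written with 6 significant digits — typical
score-file precision — making write→read round trips value-identical.
The protein atom table is accumulated once per file; any per-pose
disagreement in atom descriptors is an error, because a docking run has
one rigid receptor. A best-effort reader for GOLD-style concatenated
mol2 with per-atom score comment blocks is included; since that on-disk
layout is not standardized, constructs outside the supported subset fail
loudly with the offending line rather than being guessed at.

Best-pose selection takes the maximal total fitness; ties break to the
lowest pose index for determinism.

## Dataset building

Curation keeps unique molecules with molecular weight in [180, 900] Da
(inclusive — the boundary tests pin this reading), activity type among
IC50/EC50/Ki/Kd, assay confidence class 8 or 9, and activity strictly
below 10 µM. Duplicates collapse by canonical SMILES to the most potent
record. TRUE non-binders are kept only when their maximal Morgan
(radius 2, 2048-bit) Tanimoto similarity to any active is below 0.40 — a
conventional dissimilarity cutoff, exposed as a parameter since the
protocol itself fixes only the filter, not the threshold. TRUE/ZNC/DCM
datasets hold exactly 4 decoys per active, sampled uniformly without
replacement under a seed; an undersized pool is a hard error naming the
shortfall.

DIV decoys are wrong-pose conformations of the actives: per molecule the
best pose is excluded, then remaining poses are retained greedily in
descending score order subject to a minimum RMSD of 1.5 Å from the best
pose and from every other retained pose. RMSD is computed without
superposition (all poses share the receptor frame) and without symmetry
correction. The greedy score-descending rule reproduces the effect of a
diversity-cluster option in the docking engine: one cluster of mutually
distant conformations per molecule.

The external validation set is carved *before* any decoy enrichment:
10% per label (round-half-up), drawn only from the TRUE actives and
inactives; the 4:1 ratio is then applied to the post-carve active count.
Train/test splitting (70/30) supports three strategies: stratified random
(per-label round-half-up, remainder reconciled from the majority label);
Murcko-scaffold grouping; and Butina clustering of Morgan-Tanimoto
distances (cutoff 0.35). The grouped splitters assign whole groups to the
training side, largest first, until the fraction is met, so no scaffold
or cluster ever straddles the split; for pose-level (DIV) datasets the
partition is made at the parent-molecule level. A clustering-based
reading of the "fingerprint splitter" was chosen over a hash partition
because only grouping delivers the leakage guarantee the splitter exists
for.

## Training

`PadifClassifier` fixes the protocol: z-score standardization fitted on
training rows only (re-fitted inside each CV fold during selection, then
on the full training set for the final model), optional ADASYN
oversampling applied after scaling to training folds only, stratified
k-fold cross-validation (default k = 10, capped at the minority count)
over a small fixed per-family hyperparameter grid, mean fold F1 as the
selection metric (ties to the earlier grid entry), and a final refit.
Scores are class probabilities in [0, 1]; rankings use them raw — EF/NEF
are rank-based, so probability calibration is unnecessary. The SVM
obtains probabilities through explicit Platt calibration
(`CalibratedClassifierCV`, sigmoid, 3 unshuffled folds). The MLP uses
early stopping on a 10% validation split. The grids are deliberately
small (two candidates per family): the protocol under study delegates
breadth to an auto-ML layer; here reproducibility was preferred, and the
grid is a constructor argument.

ADASYN is implemented in the package: for each minority sample, the
fraction of majority points among its k = 5 nearest neighbours weights a
largest-remainder allocation of synthetic points, which are uniform
interpolations toward random minority neighbours. Two edge policies:
a minority class of at most k members disables oversampling with a
warning, and perfectly separated classes (all weights zero) fall back to
uniform weights rather than generating nothing.

## Metrics

F1 and balanced accuracy follow the standard confusion-count definitions;
undefined denominators yield a missing value (`None`), never 0. The
enrichment factor at x% uses a top-fraction of `ceil(x/100 · N)` records
— ceiling guarantees a non-empty selection at 1% on small sets. Its
normalization divides by the saturation bound
`EF(max) = (min(n_top, n_act)/n_top)/(n_act/N)`, giving NEF in [0, 1].
Ties are resolved by policy: *pessimistic* (default) places tied actives
below tied decoys for conservative estimates, *optimistic* the reverse;
the null-calibration test uses the midpoint of the two, which is the
expected value under random tie resolution. The interaction profile
marginalizes residues by averaging the keys present per (term, atom
class) pair per molecule, then averages within groups — pairs a group
never touches are reported missing.

## Synthetic studies

The generator emulates the statistical structure the workflow assumes.
Receptor: one atom per (residue, atom-class) pair by default, so all 800
keys are reachable. Contributions: class-conditional normals with
baseline mean 1.0 and SD 0.5; the *best* pose of an active molecule adds
`effect_size` SD to a fixed, evenly spaced, logged subset of 40 keys.
Wrong poses of actives draw from the background distribution — exactly
the premise of the DIV strategy. Pose geometry is a base conformation
plus rigid per-pose translations of 0.3–3.0 Å, straddling the 1.5 Å
diversity cutoff so the filter is exercised in both directions. Compound
tables place rows on both sides of every curation boundary and carry
their own survivor bookkeeping, independent of the curation code.
Generated SMILES are parseable and scaffold-diverse; decoy pools draw
from a scaffold family disjoint from the active series (as real
screening libraries roughly do), which keeps the dissimilarity filter's
survival rate realistic.

What passing synthetic tests shows: the pipeline's bookkeeping,
leakage-freedom, determinism and metric arithmetic are correct, and the
training stack recovers a planted signal of known size. What it does not
show: performance on real docking output, where term correlations,
pose-quality artifacts and activity-cliff chemistry are far harsher than
class-conditional normals.

Problem sizes used by the protocol checks: parameter recovery runs
simulate→train→evaluate at a 3 SD separation with 400 molecules (20%
actives, 3 poses each, 3 CV folds, default grids) and requires balanced
accuracy ≥ 0.95 from every family; the null calibration repeats the
pipeline at zero separation over 20 seeds with 200 molecules each and a
single-candidate random forest, checking mean balanced accuracy against
chance and mean NEF_20% against the random-ranking expectation.

## Known limitations

* The GOLD mol2 reader covers the constructs seen in available examples;
  anything else raises a parse error by design.
* Decoy pools and actives are sampled SMILES strings, not property-matched
  molecules; DUD-E-style property matching is out of scope.
* No probability calibration across models; scores are comparable within
  a model, not between models.
* The t-test annotations seen in per-target comparison figures of
  screening studies are not part of the package's acceptance surface;
  `scipy.stats` serves that purpose directly.
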