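# padifwf

Target-specific virtual-screening workflow built on the **protein per-atom
score contributions derived interaction fingerprint (PADIF)**.

## The problem

Docking scoring functions estimate how well a ligand pose fits a binding
site, but their raw scores are weak at *screening power* — ranking true
binders above non-binders in a mixed library. A practical remedy is to
train a target-specific classifier on interaction fingerprints extracted
from docking poses. Its performance, however, hinges on where the negative
training examples (decoys) come from. This package implements the full
post-docking workflow needed to study and use that approach:

* parse per-atom score contributions from docking output,
* build and standardize the PADIF,
* curate actives and assemble decoy datasets under four strategies —
  **TRUE** (confirmed non-binders, dissimilarity-filtered), **ZNC**
  (random draws from a purchasable-compound pool), **DCM** (dark chemical
  matter: recurrent HTS non-binders) and **DIV** (diverse "wrong-pose"
  conformations of the actives themselves),
* split datasets by random, Murcko-scaffold or fingerprint-cluster
  strategies,
* train RF / SVM / XGBoost / MLP classifiers with z-score scaling, ADASYN
  oversampling and F1-guided hyperparameter selection,
* evaluate screening power with enrichment-based metrics.

It is aimed at computational chemists who already have docking output (or
want to study the protocol itself on synthetic data — no docking software
or database downloads are required for that).

## The fingerprint and the metrics

Each docking pose carries, for every protein atom, eight ChemPLP
interaction-term contributions (ChemScore PLP.Hbond, PLP.CHO, PLP.Metal
and the five PLP.S surface terms). The raw PADIF is this per-atom map
with the signs of the three ChemScore-derived terms inverted so all terms
share one sign convention. Because the raw key space depends on the
binding site, the standardized fingerprint PADIF_STD re-keys it by
*(residue type, interaction term, atom class)* and assigns each key the
mean contribution of all matching protein atoms — at most
20 × 8 × 5 = **800 keys** with the default vocabularies. Ligand atoms are
ignored entirely, which makes models independent of ligand chemotype.

Model quality uses, for confusion counts TP/FP/TN/FN with P = TP+FN and
N = TN+FP:

```
F1  = TP / (TP + (FP + FN)/2)
BA  = (TP/P + TN/N) / 2
EF_x%  = (N_active,x% / N_total,x%) / (N_actives / N_total)
NEF_x% = EF_x% / EF(max)_x%,   EF(max)_x% = (min(N_total,x%, N_actives)/N_total,x%) / (N_actives/N_total)
```

where the top fraction holds `ceil(x/100 · N_total)` records and ranking
ties are resolved by an explicit policy (default: pessimistic — tied
actives rank below tied decoys). NEF lies in [0, 1].

## Worked example

A fully synthetic study: 200 molecules (40 actives) docked with 5 poses
each, class signal injected at 3 SD on 40 fingerprint keys, random forest
trained on a 70/30 split.

```python
import numpy as np
from padifwf import synthgen, padif
from padifwf.learn import PadifClassifier
from padifwf.metrics import balanced_accuracy, confusion, ranking_metrics

spec = synthgen.SynthSpec(poses_per_molecule=5, effect_size=3.0, seed=42)
classes = {f"mol{i:03d}": int(i < 40) for i in range(200)}
poses, protein, _ = synthgen.gen_docking_output(spec, classes)
fp = padif.padif_matrix(poses, protein, best_pose_only=True)

y = np.array([classes[m] for m in fp.index])
idx = np.random.default_rng(0).permutation(len(y)); k = int(0.7 * len(y))
model = PadifClassifier("rf", n_folds=3, random_state=0).fit(fp.values[idx[:k]], y[idx[:k]])
scores = model.predict_scores(fp.values[idx[k:]])

ba = balanced_accuracy(confusion(y[idx[k:]], (scores >= 0.5).astype(int)))
print(f"test balanced accuracy: {ba:.3f}")
for rm in ranking_metrics(y[idx[k:]], scores, (1.0, 20.0)):
    print(f"EF_{rm.fraction:g}% = {rm.ef:.2f} (max {rm.ef_max:.2f}), NEF_{rm.fraction:g}% = {rm.nef:.3f}")
```

prints

```
test balanced accuracy: 1.000
EF_1% = 5.45 (max 5.45), NEF_1% = 1.000
EF_20% = 5.00 (max 5.00), NEF_20% = 1.000
```

At this class separation the classifier separates actives from decoys
perfectly: the balanced accuracy is 1.0 and both enrichment factors reach
their saturation bound, so the normalized enrichment is 1.0 — every top
slot that can hold an active does.

The same pipeline is scriptable from the shell; each stage reads the
previous stage's artifacts from a run directory:

```bash
padifwf simulate --run-dir run --seed 11
padifwf extract  --run-dir run
padifwf build    --run-dir run --seed 11
padifwf split    --run-dir run --strategy true --method scaffold
padifwf train    --run-dir run --strategy true --method scaffold --model xgb
padifwf evaluate --run-dir run --strategy true --method scaffold --model xgb
padifwf report   --run-dir run
```

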