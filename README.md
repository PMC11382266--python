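# surfclass

Interpretable classification of **secreted vs cytosolic proteins from
surface chemistry**: a pipeline that turns a 3D protein structure into
surface-composition descriptors, trains a balanced random-forest protocol
on them, and reduces the trained forest to quantitative class-boundary
thresholds on individual descriptors.

The scientific question is whether the *chemical make-up of a protein's
solvent-exposed surface* — not its sequence — carries enough signal to
tell where the protein lives (the oxidizing, dilute extracellular space vs
the reducing, crowded cytosol), and, more importantly, *which* surface
features draw the line and *where*.

## The method

1. **Surface residues by relative SASA.** Solvent-accessible surface area
   is computed per atom with a Shrake–Rupley quadrature (probe 1.4 Å,
   deterministic golden-spiral point set oriented in the molecule's
   principal-axes frame). Each residue's *maximum* SASA is its SASA in a
   reduced structure keeping only the residue and its two sequence
   neighbours at their original coordinates; relative SASA = SASA /
   max-SASA, and residues with relative SASA ≥ 0.3 are surface residues.
2. **Descriptors.** 34 per-protein descriptors in percent units: the 20
   surface amino-acid compositions, five residue-class compositions
   (hydrophilic / hydrophobic / + / − / polar-uncharged), surface and
   overall α-helix and β-sheet compositions (Kabsch–Sander H-bond
   assignment), the surface-to-total residue ratio, and four side-chain
   functional-group compositions.
3. **Feature pruning.** Pearson-correlated pairs (|r| > 0.85) lose the
   member with the larger cumulative |r|; after training, features whose
   mean Gini importance over the top-7 models is below 2% are dropped.
4. **Protocol.** Repeated class-balanced splits (70% training, equal
   per-class counts, the rest test) with recorded per-iteration seeds;
   random forests of fully grown trees with bootstrap resampling and √p
   features per split; metrics with secreted as the positive class
   (accuracy, precision, recall, f1 = 2PR/(P+R), ROC/AUC).
5. **Interpretation.** Each prediction is decomposed along decision paths:
   P(cytosol|x) = bias + Σ_f contribution_f(x), exactly. Plotting a
   feature's contribution against its value shows where the forest's vote
   flips; a sign-separating stump turns that into a boundary value, a
   direction ("secreted below/above") and a separation score.

Because the original protein dataset is a database snapshot, the shipped
inputs are synthetic: a structure generator (ideal helix/strand/coil
backbones with Cβ stubs) and a planted-rule table generator whose classes
differ by a known conjunction of thresholds — by default *secreted iff
surface Glu < 9.0% ∧ surface Cys > 1.8% ∧ surface Leu > 5.8%* with 5%
label noise, emulating the boundary structure this kind of analysis
reports. The pipeline's core claim is then testable: it must recover the
planted thresholds from data alone.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/02_surface_features.py
python analysis/03_train_classifier.py
python analysis/04_thresholds.py
```

The last two steps print (seeded, reproducible):

```
30 iterations: mean accuracy 0.951, best model accuracy 0.975 (precision 0.983,
recall 0.967, f1 0.975, AUC 0.971)
top-7-model mean importances (top 5):
  surf_GLU_pct: 0.314
  surf_LEU_pct: 0.289
  surf_CYS_pct: 0.126
  ...
  logistic_regression: accuracy 0.839 +- 0.020
  knn: accuracy 0.796 +- 0.012
  svm: accuracy 0.874 +- 0.022
  neural_network: accuracy 0.843 +- 0.015
  random_forest: accuracy 0.948 +- 0.016
secreted-class boundary report (value where the vote flips):
  surf_GLU_pct: secreted < 8.9% (separation 0.995)  [planted: <9.0, error 0.10]
  surf_LEU_pct: secreted > 5.8% (separation 0.998)  [planted: >5.8, error 0.00]
  surf_CYS_pct: secreted > 1.9% (separation 0.996)  [planted: >1.8, error 0.10]
```

Reading: the forest's held-out accuracy sits near the Bayes rate implied
by the 5% label noise; the three rule-carrying descriptors dominate the
Gini-importance ranking; the forest (axis-aligned splits) beats the four
scaled baselines on threshold-rule data; and the contribution decomposition
recovers each planted boundary to ~0.1 percentage points with the correct
direction.

The same stages run end to end from structures via the library:

```python
from surfclass import RunConfig, run_all
run_all(RunConfig(out_dir="results/run", structures=[...], labels="labels.tsv", seed=0))
```

which writes the feature table, pruning log, per-run metrics, averaged
importances, threshold report and a manifest (seeds + artifact hashes)
sufficient to reproduce the run bit-for-bit.

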