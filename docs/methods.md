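# Methods

This note records the models, parameter choices and numerical decisions
behind `surfclass`, and what the synthetic benchmarks do and do not show.

## Structure model

Structures (PDB or mmCIF, parsed with gemmi) are reduced to standard
amino-acid residues and heavy atoms: hydrogens are dropped, altlocs
resolved to highest occupancy, waters and heteroatoms excluded, and only
the first model of multi-model files is read. Nonstandard residues are
rejected unless explicitly mapped (e.g. MSE→MET); silent coercion hides
data problems more often than it helps. Van der Waals radii are assigned
at load time from a configurable table (C 1.70, N 1.55, O 1.52, S 1.80 Å —
a standard heavy-atom set; the choice shifts absolute SASA by a few
percent but barely moves *relative* SASA, which is a ratio of areas
computed with the same radii). Per-atom B-factors are kept as confidence
scores (pLDDT in AlphaFold-style files); an optional `min_confidence`
filter can drop low-confidence (likely disordered) residues, but the
default applies no filter — confidence-based exclusion changes the surface
definition and should be a deliberate, visible choice.

## SASA and surface residues

SASA uses the Shrake–Rupley construction: each atom's sphere is expanded
by the probe radius (1.4 Å, water) and sampled with a deterministic
golden-spiral point set; a point survives if it lies outside every other
atom's expanded sphere, and the surviving fraction times the sphere area
is the atom's accessible area.

Two properties one would like of the quadrature are mutually exclusive for
any fixed direction set: (a) exact invariance of areas under rigid motion
of the molecule, and (b) exact monotonicity (deleting an atom can never
decrease another atom's area). We default to orienting the point set in
the molecule's principal-axes frame with a covariant sign convention
(third central moment ≥ 0 per axis, handedness preserved): the directions
then co-rotate with the molecule and areas are rigid-motion invariant to
float precision. A `frame="fixed"` option keeps space-fixed directions,
under which monotonicity is exact instead. Frames from fewer than three
atoms are left space-fixed (no well-defined axes; the single-sphere area
is exact regardless).

Resolution: measured against a 40 000-point reference on a compact
poly-Ala helix, per-residue error is ~0.9% at 960 points and ~0.45% at
1920. The default is **1920 points**, the resolution at which doubling the
point count moves per-residue areas by under 0.5% even on compact
structures. Coincident atom coordinates make occlusion ill-defined and
raise a degenerate-geometry error.

The **maximum SASA** of a residue is its SASA in a reduced structure
containing only the residue and its sequence neighbours (index ± 1 in the
same chain — neighbours never cross chains), all atoms at their original
coordinates; terminal residues keep their single neighbour. This is an
in-place excision, not an idealized extended tripeptide: the reference
state preserves the local backbone conformation, so relative SASA measures
burial by *non-local* context only. Relative SASA = SASA / max-SASA;
residues with relative SASA **≥ 0.3** (inclusive) are surface residues.
For a structure that is exactly a tripeptide the reduced context is the
whole structure and the central residue's relative SASA is exactly 1.
Relative SASA can exceed 1 by up to the quadrature tolerance (~1%) since
the two computations may use different principal frames; a zero maximum
SASA is geometrically impossible with sane radii and raises an error.

## Secondary structure

Backbone hydrogen bonds use the Kabsch–Sander electrostatic model
(charges ±0.42 e on C/O, ±0.20 e on N/H; E = 0.084·332·(1/r_ON + 1/r_CH −
1/r_OH − 1/r_CN) kcal/mol; bond if E < −0.5). Amide H is placed 1 Å from N
along the previous C=O direction; chain-initial residues and prolines
cannot donate; missing carbonyl O atoms are rebuilt from N/CA/C geometry.
Helix (H) requires two consecutive i→i+4 turns (so minimum length 4);
strand (E) requires Kabsch–Sander parallel or antiparallel bridge patterns
with runs of at least 2; everything else is coil (C). Only the canonical
α pattern maps to H — 3₁₀/π helices fall to C. This is the simplest
defensible 3-state collapse given that only α-helix and β-sheet ratios are
consumed downstream; the assignment is swappable behind `assign_ss`.
Chains shorter than 3 residues are all coil. Labels are a pure function of
coordinates and are rigid-motion invariant.

## Descriptors

All descriptors are percentages. Surface compositions are over surface
residues only; overall quantities over all residues. Residue classes:
positive {Arg, His, Lys}, negative {Asp, Glu}, polar-uncharged {Ser, Thr,
Asn, Gln}, hydrophobic {Ala, Ile, Leu, Met, Phe, Trp, Tyr, Val};
hydrophilic is the union of the first three. Gly, Pro and Cys belong to
none of the four chemistry classes, so class percentages need not sum to
100 (hydrophilic = positive + negative + polar-uncharged holds exactly).
Functional-group compositions count side-chain bearers: amide {Asn, Gln},
hydroxyl {Ser, Thr, Tyr}, carboxyl {Asp, Glu}, thiol {Cys}.

The default registry (20 AA + 5 classes + 4 SS quantities + surface ratio
+ 4 functional groups = 34) is a documented reconstruction of a plausible
surface-descriptor set of that size, not a canonical list; it is
config-driven so variants can be expressed without code changes.

Correlation pruning removes, for every pair with |Pearson r| strictly
above 0.85 (processed in descending |r| order, ties broken by name), the
member with the larger cumulative |r| against all other features
(lexicographic tie-break); zero-variance columns are removed first with a
warning since their correlation is undefined. Pruning is idempotent and
survivors never contain a pair above the threshold.

Group comparisons use the Mann–Whitney U test (two-sided): distributions
of compositional descriptors are bounded and often skewed, so a rank test
is the safe default over a t-test; the test name is recorded in the
report. Constant-in-both-classes descriptors yield p = 1 with a warning.

## Training protocol

A split draws `round(0.7·n)` training rows divided equally between the
classes (floor), sampling each class without replacement from its own
seeded stream (`SeedSequence(seed).spawn`); all remaining rows are test.
This reproduces the balanced-training/unbalanced-test design (e.g. 708
rows → 248 + 248 training, 212 test). The full protocol repeats this over
`n_iterations` recorded seeds (default 150), fits a
`RandomForestClassifier` per split (defaults: 500 fully grown trees,
bootstrap, √p features per split — the four defining forest properties;
tree count and the rest exposed in config), and evaluates with secreted as
the positive class. The best model is the highest-test-accuracy run;
importances are Gini (mean impurity decrease, normalized to sum to 1),
averaged over the top-7 runs by accuracy. Features with mean importance
strictly below 2% are pruned, with a guard that at least two features
survive. The five-algorithm comparison (logistic regression, kNN, SVM,
one-hidden-layer MLP, forest) runs the identical split protocol, with
feature standardization for the four non-forest learners.

Tests and the shipped analysis scripts run scaled-down protocol instances
(8–30 iterations, 60–200 trees); recovery statistics on the planted tables
are already stable at that size, and the defaults remain the full
protocol.

## Contribution decomposition and thresholds

For each tree, walking a sample root→leaf and crediting each split's
change in the node's cytosol-class probability to the split's feature
yields an exact decomposition P(cytosol|x) = bias + Σ_f c_f(x), where the
bias is the root-node probability; averaging over trees preserves the
identity to float round-off (the "treeinterpreter" construction). Node
probabilities are renormalized from the stored class counts, which makes
the code robust to sklearn's count-vs-fraction storage conventions.
Positive contributions push toward cytosol; the two classes' contributions
are exact negatives in a binary problem.

A feature's threshold is extracted from its (value, contribution) profile
by a one-dimensional stump on the *sign* of the contribution: the boundary
maximizing the fraction of samples whose sign matches their side, reported
as the midpoint of the straddling values rounded to 0.1, together with the
secreted side (the side with negative cytosol-contribution) and the
separation score (matched fraction, in [0.5, 1]). Samples with exactly
zero contribution are excluded; fewer than 10 nonzero samples, or a
profile with one sign only, yields a no-boundary warning rather than a
number. An explicit estimator with a reported separation score replaces
drawing the vertical line by eye.

## Synthetic data

`make_structure` builds polypeptides from ideal internal coordinates
(N–CA 1.458, CA–C 1.525, C–N 1.329 Å; helix φ/ψ = −57°/−47°, strand
−139°/+135°, extended ±180°, coil-perturbed from a loose per-residue
dihedral distribution), places carbonyl O trans to the next amide, and
gives every non-Gly residue an Ala-like Cβ stub. Full rotamers are out of
scope: surface-composition logic depends on residue identity and backbone
burial, which stubs capture. Optional isotropic Gaussian coordinate noise
models structural imprecision. `make_antiparallel_sheet` pairs two ideal
strands by a 180° rotation plus a deterministic grid search over the rigid
offset maximizing inter-strand Kabsch–Sander bonds.

`make_planted_table` samples rule features uniformly in a ±5 band around
each boundary, accepts rows into the class matching the rule conjunction
(rejection sampling), flips labels with probability `noise_rate` (default
5%), and appends class-independent Uniform(0, 20) noise features (default
10) and optionally a Dirichlet compositional block scaled to 100. Defaults
(400 rows per class; rules surface-Glu < 9.0, surface-Cys > 1.8,
surface-Leu > 5.8) emulate the size and boundary structure of a realistic
two-class protein surface dataset. Every generator is a pure function of
its spec and seed.

**What passing the synthetic benchmarks shows — and does not.** Recovery
of the planted thresholds demonstrates that the protocol + decomposition
machinery extracts axis-aligned boundaries from noisy labeled data of this
size. It does not validate the biological claim on real proteins: real
descriptors are correlated, class boundaries need not be axis-aligned or
sharp, label noise is not independent of the features, and real structures
have side chains, cavities and disorder that Cβ-stub toys lack.

One measured caveat: with fully grown trees and 5% *label* noise, the
~5% unpredictable labels are memorized through the continuous noise
features, leaving each of them ~2–3% of the total Gini decrease — above
the 2% pruning floor. Dropping all pure-noise features at that floor is
only near-guaranteed for clean labels (measured ~1.6–2.2% per noise
feature at noise 0); under label noise the floor prunes nothing and the
ranking, not the floor, is what separates signal from noise features.

## Pipeline

`run_all` executes features → correlation-prune → protocol →
importance-prune (with retraining on the retained features when any were
dropped) → threshold report, writing each stage artifact and a manifest
with the config, per-stage seeds (derived from the global seed via
`SeedSequence.spawn` in a fixed stage order) and SHA-256 hashes of every
artifact. Reruns of the same config are hash-identical. Stage failures
raise an error naming the stage; artifacts already written are retained.

## Known limitations

- Quadrature SASA, not analytic: areas carry ~0.5% resolution-dependent
  error; relative SASA inherits up to ~1% near 1.0.
- The 3-state secondary-structure collapse ignores 3₁₀/π helices and
  β-bridges shorter than 2.
- The descriptor registry is a reconstruction; percent descriptors are
  compositional, so correlations between them are partly structural.
- Threshold extraction assumes a single sign change per feature; genuinely
  non-monotone features would need piecewise reporting.
- The synthetic generators make no attempt at realistic packing densities
  or AlphaFold-like confidence patterns.
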