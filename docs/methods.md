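# Methods

## Problem setting

Given a protein chain with known 3-D structure, label each residue as
DNA-binding (positive) or not. Binding residues make up only 4–9 % of the
published protein–DNA benchmarks, so the task is an imbalanced binary node
classification problem on residue graphs. This package implements the full
pipeline — structure parsing, contact-graph construction, feature
embedding, graph-aware minority oversampling, a SAGE+MLP classifier with
focal loss, and an imbalance-aware evaluation suite — and validates it on
synthetic data with known ground truth.

## Contact graphs

Nodes are the residues of one chain that carry a Cα atom, in chain order.
An undirected edge joins residues i and j iff ‖Cα_i − Cα_j‖ < t with
t = 8 Å by default. The comparison is strict `<`; at exactly 8.0 Å no edge
is created. No backbone edges are forced: consecutive Cα atoms sit ~3.8 Å
apart and satisfy the distance rule anyway. Residues without a Cα are
dropped (they cannot participate in a Cα-distance graph); alternate
conformations resolve to the highest-occupancy Cα; waters and hetero
groups are excluded. Construction uses a KD-tree with an exact strict-`<`
filter at the boundary and is tested against an O(n²) all-pairs scan.
Multiple chains are batched as a disjoint union (no cross-chain edges),
with offsets recorded for inversion.

## Feature providers

Per-residue features are an L×D matrix. Two providers share the contract
(L rows, finite entries, deterministic given their inputs):

* **plm-adapter** — final-layer per-residue representations of a
  3-billion-parameter protein language model, D = 2560. The adapter
  imports its backend lazily and raises an actionable error when it is not
  installed; computed embeddings are cached to disk keyed by a hash of
  (provider, dim, seed, sequence). Nothing in the test suite requires it.
* **synthetic** — row i is standard Gaussian noise; when a label vector is
  supplied, positive rows are shifted by `class_shift`·μ along a fixed
  seeded unit direction μ. The two classes are then unit-variance
  Gaussians separated by d = `class_shift` along μ, so the Bayes error of
  the oracle projection is Φ(−d/2) and the projection AUC is Φ(d/√2) —
  closed forms the tests check against.

The real provider's layer choice (final layer) and the absence of any
pre-normalization are package decisions; nothing downstream depends on
them beyond the feature dimension.

## Graph-aware SMOTE

Training nodes of the rarer class (computed, never assumed; an exact tie
is a warning no-op and a single-class training set is an error) are
oversampled until the minority count reaches ⌈`target_ratio` × majority⌉.
Each synthetic node interpolates a source minority node toward one of its
`k_neighbors` nearest minority training nodes in Euclidean feature space
(ties broken toward the lower node id), x' = x_src + λ(x_nn − x_src) with
λ ~ U[0, 1]. Sources are cycled round-robin so the synthetic mass spreads
over the whole minority set. A minority node with no same-class peer is
duplicated with small Gaussian jitter (σ = 0.01 × feature std) instead,
since interpolation is undefined with one sample.

Synthetic nodes are wired into the graph by one of three deterministic
strategies — `inherit-source` (source plus all its neighbors; default),
`inherit-union` (both endpoints plus the union of their neighborhoods),
`knn-feature` (k nearest base nodes in feature space) — every one of which
guarantees at least one incident edge. A learned edge generator was
deliberately avoided: it would embed a second trained model inside the
oversampler, and the deterministic strategies keep augmentation exactly
reproducible from the seed. Guarantees (tested): the base graph is
bit-identical inside the augmentation; every synthetic feature vector lies
coordinate-wise on the segment between its endpoints; post-augmentation
balance is within one node of the target; synthetic nodes enter only the
training mask; full provenance (source, neighbor, λ) is recorded and
exportable. Oversampling runs on the batched training graph, so neighbors
may come from other chains.

The unstated knobs of the original procedure — target ratio, k, the λ
distribution — are exposed as configuration with defaults 1.0, 5 and
U[0, 1] (the standard SMOTE convention).

## Classifier

Two SAGE layers followed by a two-hidden-layer MLP:

* SAGE layer: n_i = Σ_{j∈N(i)} h_j (sum by default, mean selectable;
  isolated nodes aggregate to zero), h'_i = [h_i, n_i],
  h_i ← ReLU(W h'_i + b).
* MLP: two LeakyReLU (slope 0.01) hidden layers, then a softmax head over
  K = 2 classes.
* Focal loss L = −α(1−p_t)^γ log p_t with p_t the probability assigned to
  the true class, clamped at 10⁻¹² before the log; batch loss is the mean
  over training nodes (real plus synthetic). α scales the loss uniformly;
  γ down-weights easy examples. Defaults α = 0.25, γ = 2.

Everything is NumPy: the backward pass is hand-derived (checked against
central finite differences at a generic point, away from ReLU kinks where
the derivative is set-valued) and optimization is full-batch Adam
(lr 10⁻³, β = 0.9/0.999). Default widths are 256/256 (SAGE) and 128/64
(MLP); the experiments below use 32/32 and 32/16, ample for
16-dimensional synthetic features. Weight init is He-scaled from the run
seed, so training is bit-reproducible. The decision rule is
p_pos ≥ threshold (default 0.5); the ≥ convention at the boundary and the
pooled (not per-chain-averaged) metrics are fixed for reproducibility.
`GraphSAGEClassifier` follows the scikit-learn estimator protocol and
serializes to a single `.npz` weights file plus a JSON manifest of all
hyperparameters.

## Evaluation

From the confusion counts at the stated threshold:
Spe = TN/(TN+FP), Pre = TP/(TP+FP), Rec = TP/(TP+FN),
F1 = 2·Pre·Rec/(Pre+Rec),
MCC = (TP·TN − FN·FP)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Zero-denominator ratios are reported as 0 with an explicit flag so report
tables stay finite under degenerate predictors. AUC is rank-based
(Mann–Whitney, ties counted half), cross-checked in the tests against both
exhaustive pair counting and scikit-learn. Synthetic nodes never
contribute to any metric; evaluation uses only nodes outside the training
mask.

The benchmark dataset statistics operation recomputes percent binding as
100·b/(b+n) from the published residue counts. Note: for the TE46 test
set the published counts (956 binding, 9911 non-binding) imply 8.80 %,
which is what this package computes and asserts; the source table prints
8.87 % for that row, inconsistent with its own counts.

## Synthetic data

The generator emulates the properties the pipeline is sensitive to, and
only those: Cα chains as self-avoiding random walks (3.8 Å steps, 3 Å
excluded-volume rejection, giving realistic contact degrees under the 8 Å
rule), exact imbalanced label counts (round(n × fraction)), positives
placed as one or two spatially contiguous patches (or uniformly), and
Gaussian features with the planted class signal above. It does not emulate
real folds, DNA-binding geometry, sequence composition biases, or the
correlated structure of language-model embeddings — so passing tests
demonstrate that the machinery is correct and that the imbalance mechanism
operates, not that benchmark-level accuracy transfers to real proteins.
Reproducing the published benchmark results would additionally require the
external datasets, 3B-parameter embeddings and released trained weights,
and is out of scope.

## Mechanism-recovery experiment

Ten seeds; per seed, datasets of 20 chains × 100 residues (2000 nodes),
5 % positives, 70/30 chain-level train/test split, 16-dim features with
effect size `class_shift`:

* **Null calibration** (class_shift = 0): held-out AUC should be at
  chance, 0.5 ± 0.08 averaged over seeds.
* **Signal detection** (class_shift = 2): median held-out AUC > 0.8.
* **Oversampling benefit**: paired per seed, median held-out minority
  recall with SMOTE ≥ without, both arms at threshold 0.5.

Two experiment-design choices matter and were made once:

* **Mean aggregation.** With sum aggregation, oversampling inflates the
  degree of minority-region training nodes far beyond anything seen in
  test chains, and the resulting magnitude shift miscalibrates held-out
  predictions. Mean aggregation makes neighborhood summaries
  degree-invariant and removes the artifact; the sum form remains the
  package default for single-graph use, per the printed update rule.
* **A fixed modest training budget** (60 epochs full-batch Adam at 10⁻³,
  identical in both arms). The synthetic minority is cleanly separable, so
  with an unbounded budget even the unbalanced baseline eventually fits
  it and imbalance costs nothing — unlike real noisy data. Under a matched
  finite budget the baseline exhibits the classic imbalance failure
  (recall collapse toward the majority class) and what oversampling
  recovers becomes measurable.

Recall at an exactly matched 0.95-specificity operating point is also
computed and reported for both arms. At that threshold-free comparison the
two arms are statistically indistinguishable on this fixture — the
oversampler's benefit here is operational (it moves the default-threshold
operating point to a far higher recall at slightly lower specificity),
which is exactly the failure mode that matters when a fixed threshold is
deployed.

## Numerical and degenerate-input choices

* log clamp 10⁻¹² in the focal loss; the γ < 1 singularity of its gradient
  at p_t = 1 is guarded the same way.
* Feature-distance ties in nearest-neighbor search and knn edge wiring
  break toward the lower node id.
* Edge lists are canonicalized (i < j, deduplicated) at graph
  construction; self-edges are rejected.
* Degenerate inputs raise typed errors rather than returning silently:
  empty chains, unlabeled residues, single-class training sets, all-zero
  confusion tables, single-class AUC.

## Limitations

* The NumPy trainer is full-batch only; graphs beyond ~10⁵ nodes would
  need mini-batching or sparse-aware layers.
* Synthetic-node edge strategies are heuristic; none is learned from the
  data.
* The plm-adapter path is exercised only through its error contract unless
  the optional backend and weights are installed.
* Hyperparameters reproducing the published benchmark tables are not known
  (the source does not report them); none are claimed here.
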