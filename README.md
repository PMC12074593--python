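# graphbind

Prediction of DNA-binding residues from protein structure and per-residue
sequence embeddings, built around three ideas:

1. **Residue contact graphs.** Each protein chain becomes a graph whose
   nodes are residues and whose edges join residue pairs with Cα–Cα
   distance strictly below 8 Å, so spatially close residues exchange
   information even when they are far apart in sequence.
2. **Graph-aware SMOTE.** Binding residues are rare (4–9 % in the published
   protein–DNA benchmarks), so the training graph is rebalanced by
   synthesizing minority nodes: each new node interpolates a minority
   node's features toward one of its k nearest minority neighbors
   (x' = x_src + λ·(x_nn − x_src), λ ~ U[0,1]) and is wired into the graph
   rather than left isolated.
3. **SAGE + MLP classifier with focal loss.** Each SAGE layer updates node
   i via n_i = Σ_{j∈N(i)} h_j, h'_i = [h_i, n_i], h_i ← ReLU(W h'_i + b);
   a two-hidden-layer LeakyReLU MLP with softmax output yields per-residue
   binding probabilities; training minimizes the focal loss
   L = −α(1−p_t)^γ log p_t, which down-weights easy (mostly non-binding)
   residues.

The model is plain NumPy with hand-written backpropagation and full-batch
Adam — residue graphs are small enough that no GPU framework is needed.
Evaluation reports Spe, Pre, Rec, F1, MCC and rank-based AUC, pooled over
all evaluated residues.

Feature matrices come from a provider contract: a protein-language-model
adapter (L×2560 per-residue embeddings, requires the optional `fair-esm`
backend) or a deterministic synthetic Gaussian provider with a controllable
planted class signal, used by all tests and experiments.

## Worked example

The `graphbind` command wires the pipeline together on synthetic fixtures:

```bash
graphbind make-fixtures demo/fx --n-chains 6 --chain-len 80 \
    --binding-fraction 0.08 --class-shift 2.5 --seed 7
graphbind build-graph demo/fx/chain*.pdb --out demo/graphs.npz --test-fraction 0.34
graphbind train demo/graphs.npz --out demo/model --epochs 150 --aggregate mean --seed 7
graphbind predict demo/model demo/graphs.npz --out demo/preds.tsv
graphbind evaluate demo/preds.tsv demo/graphs.npz --threshold 0.5
```

which prints (held-out residues of the 2 test chains, decision threshold 0.5):

```
Spe     Rec     Pre     F1      MCC     AUC
0.993   0.750   0.900   0.818   0.809   0.949
```

Specificity 0.993 and recall 0.750 mean almost no non-binding residue is
flagged while three quarters of true binding residues are found; MCC 0.809
summarizes the full confusion matrix, and AUC 0.949 is the probability a
random binding residue outranks a random non-binding one. `graphbind stats`
prints the published benchmark dataset summary (binding counts,
non-binding counts, percent binding).

As a library, the same pipeline is three calls:

```python
from graphbind import make_toy_dataset, train, TrainConfig
from graphbind.train_eval import evaluate_on_graph

graph = make_toy_dataset(n_chains=20, chain_len=100, binding_fraction=0.05,
                         class_shift=2.0, seed=1)
clf, history = train(graph, TrainConfig(epochs=60, aggregate="mean", seed=1))
report = evaluate_on_graph(clf, graph)   # held-out chains only
```

`GraphSAGEClassifier` and `GraphSMOTE` follow the scikit-learn estimator
protocol (`get_params`/`set_params`, `fit`/`predict_proba`,
`fit_resample`) and operate on `ProteinGraph` objects.

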