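import numpy as np
import pytest

from graphbind.contact_graph import ProteinGraph
from graphbind.structure_io import Residue, ResidueChain


def make_chain(n, seed=0, labels=None, spread=6.0):
    """A chain with random coordinates (3-decimal precision, PDB-writable)."""
    rng = np.random.default_rng(seed)
    coords = np.round(rng.uniform(-spread, spread, size=(n, 3)), 3)
    if labels is None:
        labels = [None] * n
    return ResidueChain(
        chain_id="A",
        residues=tuple(
            Residue(residue_index=i + 1, aa_code="AGRKDEW"[i % 7],
                    ca_xyz=tuple(coords[i]), label=labels[i])
            for i in range(n)),
    )


def make_graph(n=30, d=4, pos_frac=0.2, edge_p=0.15, seed=0, train_frac=1.0):
    """A random labeled graph for oversampler/model tests."""
    rng = np.random.default_rng(seed)
    feats = rng.standard_normal((n, d))
    labels = (rng.uniform(size=n) < pos_frac).astype(int)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.uniform() < edge_p]
    train = np.zeros(n, dtype=bool)
    train[: int(round(train_frac * n))] = True
    return ProteinGraph(
        node_features=feats,
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        labels=labels,
        node_ids=np.arange(1, n + 1),
        train_mask=train,
    )


@pytest.fixture
def random_graph():
    return make_graph(n=30, seed=42)
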