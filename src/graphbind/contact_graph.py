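"""Residue contact graphs.

Nodes are the retained residues of a chain, in chain order (0-based).
An undirected edge joins residues i and j whenever their C-alpha distance is
strictly below the threshold (default 8 A). Sequence-adjacent residues get no
special treatment: consecutive C-alphas sit ~3.8 A apart and therefore
satisfy the distance rule anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from graphbind.errors import ShapeError
from graphbind.structure_io import ResidueChain


@dataclass(frozen=True)
class GraphConfig:
    """Contact-graph construction parameters.

    ``distance_threshold`` is in Angstroms; the comparison is strict ``<``.
    """

    distance_threshold: float = 8.0

    def __post_init__(self) -> None:
        if not self.distance_threshold > 0:
            raise ValueError("distance_threshold must be positive")


@dataclass
class ProteinGraph:
    """A residue graph: features, undirected edges, labels, masks.

    ``edges`` is an (E, 2) int array with i < j per row and no duplicates.
    ``train_mask`` marks nodes whose labels drive the loss; its complement is
    the evaluation set. ``node_ids`` holds the 1-based residue indices and
    ``chain_ids`` the source chain of each node (useful after batching).
    """

    node_features: np.ndarray
    edges: np.ndarray
    labels: np.ndarray
    node_ids: np.ndarray
    train_mask: np.ndarray
    chain_ids: np.ndarray | None = None
    offsets: np.ndarray | None = None  # set by batch_graphs for inversion

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int)
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.train_mask = np.asarray(self.train_mask, dtype=bool)
        n = self.n_nodes
        if not (len(self.labels) == len(self.node_ids) == len(self.train_mask) == n):
            raise ShapeError("labels, node_ids and train_mask must all have one entry per node")
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ShapeError("edge endpoint out of range")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ShapeError("self-edges are not allowed")
        # canonical order (i < j), no duplicates
        e = np.sort(self.edges, axis=1)
        self.edges = np.unique(e, axis=0) if e.size else e.reshape(0, 2)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.node_features.shape[1]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def write_edge_list(self, path: str | Path) -> None:
        """Export edges as text, one 0-based ``i j`` pair per line."""
        Path(path).write_text("".join(f"{i} {j}\n" for i, j in self.edges))


def save_graph(path: str | Path, graph: ProteinGraph) -> None:
    """Serialize a (possibly batched) graph to a single .npz file."""
    arrays = dict(node_features=graph.node_features, edges=graph.edges,
                  labels=graph.labels, node_ids=graph.node_ids,
                  train_mask=graph.train_mask)
    if graph.chain_ids is not None:
        arrays["chain_ids"] = graph.chain_ids.astype(str)
    if graph.offsets is not None:
        arrays["offsets"] = graph.offsets
    np.savez(path, **arrays)


def load_graph(path: str | Path) -> ProteinGraph:
    data = np.load(path, allow_pickle=False)
    return ProteinGraph(
        node_features=data["node_features"], edges=data["edges"],
        labels=data["labels"], node_ids=data["node_ids"],
        train_mask=data["train_mask"],
        chain_ids=data["chain_ids"] if "chain_ids" in data else None,
        offsets=data["offsets"] if "offsets" in data else None,
    )


def build_contact_graph(
    chain: ResidueChain,
    features: np.ndarray,
    cfg: GraphConfig | None = None,
    train_mask: np.ndarray | None = None,
) -> ProteinGraph:
    """Build the C-alpha contact graph of one labeled chain.

    Edge (i, j) is present iff ||ca_i - ca_j|| < ``cfg.distance_threshold``
    with i != j. Node order equals chain order; feature rows must match the
    retained residues one-to-one.
    """
    cfg = cfg or GraphConfig()
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] != len(chain):
        raise ShapeError(f"feature matrix has {features.shape[0] if features.ndim == 2 else '?'} "
                         f"rows for a chain of {len(chain)} residues")
    coords = chain.coords
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite C-alpha coordinate")
    labels = chain.labels
    if labels is None:
        raise ValueError("chain must be fully labeled before graph construction")
    # KD-tree pair query returns pairs with distance <= r; drop the boundary
    # to honor the strict less-than rule.
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cfg.distance_threshold, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < cfg.distance_threshold]
    if train_mask is None:
        train_mask = np.ones(len(chain), dtype=bool)
    return ProteinGraph(
        node_features=features,
        edges=pairs.reshape(-1, 2),
        labels=labels,
        node_ids=np.array([r.residue_index for r in chain.residues]),
        train_mask=train_mask,
        chain_ids=np.array([chain.chain_id] * len(chain)),
    )


def batch_graphs(graphs: list[ProteinGraph]) -> ProteinGraph:
    """Disjoint union of several chain graphs; no edges cross chains.

    Node-id offsets are recorded on the result so :func:`split_batched`
    can invert the operation.
    """
    if not graphs:
        raise ValueError("no graphs to batch")
    dims = {g.feature_dim for g in graphs}
    if len(dims) > 1:
        raise ShapeError(f"mixed feature dimensions: {sorted(dims)}")
    offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
    edges = [g.edges + off for g, off in zip(graphs, offsets)]
    chain_ids = [g.chain_ids if g.chain_ids is not None
                 else np.array([str(k)] * g.n_nodes) for k, g in enumerate(graphs)]
    return ProteinGraph(
        node_features=np.vstack([g.node_features for g in graphs]),
        edges=np.vstack(edges) if edges else np.empty((0, 2), dtype=int),
        labels=np.concatenate([g.labels for g in graphs]),
        node_ids=np.concatenate([g.node_ids for g in graphs]),
        train_mask=np.concatenate([g.train_mask for g in graphs]),
        chain_ids=np.concatenate(chain_ids),
        offsets=offsets,
    )


def split_batched(batched: ProteinGraph) -> list[ProteinGraph]:
    """Invert :func:`batch_graphs` using the recorded offsets."""
    if batched.offsets is None:
        raise ValueError("graph carries no batch offsets")
    out = []
    for lo, hi in zip(batched.offsets[:-1], batched.offsets[1:]):
        mask = (batched.edges[:, 0] >= lo) & (batched.edges[:, 0] < hi)
        out.append(ProteinGraph(
            node_features=batched.node_features[lo:hi],
            edges=batched.edges[mask] - lo,
            labels=batched.labels[lo:hi],
            node_ids=batched.node_ids[lo:hi],
            train_mask=batched.train_mask[lo:hi],
            chain_ids=None if batched.chain_ids is None else batched.chain_ids[lo:hi],
        ))
    return out
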