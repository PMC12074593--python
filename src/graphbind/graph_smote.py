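"""Graph-aware SMOTE: rebalance a node-classification training set.

Minority-class training nodes are oversampled by interpolating each source
node's features toward one of its k nearest minority neighbors in feature
space (Euclidean), then wiring the synthetic node into the graph so that it
is not an isolated addition. Synthetic nodes enter only the training mask;
base nodes, features and edges are never modified.

The oversampler is exposed both as an imblearn-style estimator
(:class:`GraphSMOTE` with ``fit_resample``) and as the plain function
:func:`oversample`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from graphbind.contact_graph import ProteinGraph
from graphbind.errors import DegenerateInputError, ShapeError

logger = logging.getLogger(__name__)

EDGE_STRATEGIES = ("inherit-source", "inherit-union", "knn-feature")


@dataclass(frozen=True)
class OversampleConfig:
    """Oversampling parameters.

    ``target_ratio`` is the desired minority/majority count ratio among
    training nodes after augmentation (1.0 = fully balanced).
    Interpolation coefficients are uniform on [0, 1].
    """

    target_ratio: float = 1.0
    k_neighbors: int = 5
    edge_strategy: str = "inherit-source"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.edge_strategy not in EDGE_STRATEGIES:
            raise ValueError(f"edge_strategy must be one of {EDGE_STRATEGIES}")


@dataclass(frozen=True)
class SyntheticNode:
    """Provenance of one synthetic node: who it interpolates and by how much."""

    new_id: int
    source_id: int
    neighbor_id: int
    lam: float


@dataclass
class AugmentedGraph:
    """A base graph plus synthetic minority nodes and their edges.

    The base graph is embedded unmodified: nodes [0, base.n_nodes) of
    :meth:`as_graph` are the base nodes with their original features, labels
    and edges, and synthetic nodes appear only in the training mask.
    """

    base: ProteinGraph
    synthetic_features: np.ndarray
    synthetic_nodes: list[SyntheticNode] = field(default_factory=list)
    synthetic_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    minority_label: int = 1

    @property
    def n_synthetic(self) -> int:
        return len(self.synthetic_nodes)

    def as_graph(self) -> ProteinGraph:
        """Materialize the augmented graph as a plain :class:`ProteinGraph`."""
        n_syn = self.n_synthetic
        feats = (np.vstack([self.base.node_features, self.synthetic_features])
                 if n_syn else self.base.node_features)
        edges = (np.vstack([self.base.edges, self.synthetic_edges])
                 if len(self.synthetic_edges) else self.base.edges)
        return ProteinGraph(
            node_features=feats,
            edges=edges,
            labels=np.concatenate([self.base.labels,
                                   np.full(n_syn, self.minority_label, dtype=int)]),
            node_ids=np.concatenate([self.base.node_ids, -np.ones(n_syn, dtype=int)]),
            train_mask=np.concatenate([self.base.train_mask, np.ones(n_syn, dtype=bool)]),
        )

    def provenance_table(self) -> str:
        """Tab-separated provenance: new_id, source_id, neighbor_id, lambda."""
        lines = ["new_id\tsource_id\tneighbor_id\tlambda"]
        lines += [f"{s.new_id}\t{s.source_id}\t{s.neighbor_id}\t{s.lam:.6f}"
                  for s in self.synthetic_nodes]
        return "\n".join(lines) + "\n"


def identify_minority_nodes(graph: ProteinGraph) -> np.ndarray:
    """Training nodes of the rarer class (computed, never assumed).

    An exact tie returns an empty array: there is nothing to oversample.
    A single-class training set is degenerate and raises.
    """
    train = np.flatnonzero(graph.train_mask)
    if train.size == 0:
        raise DegenerateInputError("empty training mask")
    y = graph.labels[train]
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("training set contains a single class")
    if n_pos == n_neg:
        logger.warning("classes exactly balanced; nothing to oversample")
        return np.empty(0, dtype=int)
    minority = 1 if n_pos < n_neg else 0
    return train[y == minority]


def nearest_minority_neighbors(node: int, graph: ProteinGraph, k: int,
                               minority_nodes: np.ndarray | None = None) -> np.ndarray:
    """The k same-class training nodes closest to ``node`` in feature space.

    Euclidean distance; ties broken toward the lower node id; the node itself
    is excluded.
    """
    if minority_nodes is None:
        minority_nodes = identify_minority_nodes(graph)
    candidates = minority_nodes[minority_nodes != node]
    if candidates.size == 0:
        raise DegenerateInputError(f"node {node} has no same-class peer to interpolate with")
    d = np.linalg.norm(graph.node_features[candidates] - graph.node_features[node], axis=1)
    order = np.lexsort((candidates, d))  # distance first, lower id on ties
    return candidates[order[:k]]


def synthesize_node(x_src: np.ndarray, x_nn: np.ndarray, lam: float) -> np.ndarray:
    """Linear interpolation x_src + lam * (x_nn - x_src), lam in [0, 1]."""
    x_src, x_nn = np.asarray(x_src, dtype=float), np.asarray(x_nn, dtype=float)
    if x_src.shape != x_nn.shape:
        raise ShapeError(f"dimension mismatch: {x_src.shape} vs {x_nn.shape}")
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    return x_src + lam * (x_nn - x_src)


def _neighbors_of(graph: ProteinGraph, node: int,
                  extra_edges: list[tuple[int, int]]) -> set[int]:
    nbrs = set()
    for i, j in graph.edges:
        if i == node:
            nbrs.add(int(j))
        elif j == node:
            nbrs.add(int(i))
    for i, j in extra_edges:
        if i == node:
            nbrs.add(j)
        elif j == node:
            nbrs.add(i)
    return nbrs


def attach_synthetic_edges(
    aug: AugmentedGraph,
    new_id: int,
    source_id: int,
    neighbor_id: int,
    strategy: str = "inherit-source",
    k: int = 5,
) -> AugmentedGraph:
    """Wire one synthetic node into the graph.

    * ``inherit-source``: edges to the source node and all its neighbors.
    * ``inherit-union``: edges to both endpoints and the union of their
      neighborhoods.
    * ``knn-feature``: edges to the k nearest base nodes in feature space.

    Every strategy yields at least one edge (the source itself at minimum).
    """
    existing = [(int(i), int(j)) for i, j in aug.synthetic_edges]
    if strategy == "inherit-source":
        targets = {source_id} | _neighbors_of(aug.base, source_id, [])
    elif strategy == "inherit-union":
        targets = ({source_id, neighbor_id}
                   | _neighbors_of(aug.base, source_id, [])
                   | _neighbors_of(aug.base, neighbor_id, []))
    elif strategy == "knn-feature":
        all_feats = (np.vstack([aug.base.node_features, aug.synthetic_features])
                     if len(aug.synthetic_features) else aug.base.node_features)
        x_new = all_feats[new_id]
        d = np.linalg.norm(aug.base.node_features - x_new, axis=1)
        order = np.lexsort((np.arange(aug.base.n_nodes), d))
        targets = set(order[:k].tolist()) | {source_id}
    else:
        raise ValueError(f"unknown edge strategy {strategy!r}")
    targets.discard(new_id)
    new_edges = sorted((min(t, new_id), max(t, new_id)) for t in targets)
    edges = np.array(existing + new_edges, dtype=int).reshape(-1, 2)
    return replace(aug, synthetic_edges=edges)


def oversample(graph: ProteinGraph, cfg: OversampleConfig | None = None) -> AugmentedGraph:
    """Augment ``graph`` until minority training count reaches
    ``ceil(target_ratio * majority count)``.

    Each synthetic node records its (source, neighbor, lambda) provenance;
    the result is reproducible from ``cfg.seed``; the base graph is returned
    untouched inside the augmentation.
    """
    cfg = cfg or OversampleConfig()
    minority = identify_minority_nodes(graph)
    aug = AugmentedGraph(
        base=graph,
        synthetic_features=np.empty((0, graph.feature_dim)),
        minority_label=(int(graph.labels[minority[0]]) if minority.size else 1),
    )
    if minority.size == 0:
        return aug
    n_min = minority.size
    n_maj = int(graph.train_mask.sum()) - n_min
    n_new = int(np.ceil(cfg.target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return aug
    rng = np.random.default_rng(cfg.seed)

    # Precompute each minority node's k-NN list once (features are static).
    knn: dict[int, np.ndarray] = {}
    single_peer = minority.size < 2
    if not single_peer:
        for node in minority:
            knn[int(node)] = nearest_minority_neighbors(node, graph, cfg.k_neighbors,
                                                        minority_nodes=minority)

    feats = [aug.synthetic_features]
    nodes: list[SyntheticNode] = []
    feat_std = float(graph.node_features.std()) or 1.0
    for t in range(n_new):
        src = int(minority[t % minority.size])
        new_id = graph.n_nodes + t
        if single_peer:
            # lone minority sample: duplicate with small jitter, interpolation undefined
            lam = 0.0
            nbr = src
            x_new = graph.node_features[src] + rng.normal(
                0.0, 0.01 * feat_std, size=graph.feature_dim)
            logger.warning("minority node %d has no peer; duplicated with jitter", src)
        else:
            nbr = int(rng.choice(knn[src]))
            lam = float(rng.uniform())
            x_new = synthesize_node(graph.node_features[src], graph.node_features[nbr], lam)
        feats.append(x_new[None, :])
        nodes.append(SyntheticNode(new_id=new_id, source_id=src, neighbor_id=nbr, lam=lam))
    aug = replace(aug, synthetic_features=np.vstack(feats), synthetic_nodes=nodes)
    for s in nodes:
        aug = attach_synthetic_edges(aug, s.new_id, s.source_id, s.neighbor_id,
                                     strategy=cfg.edge_strategy, k=cfg.k_neighbors)
    return aug


class GraphSMOTE(BaseEstimator):
    """Graph-aware SMOTE oversampler with an imblearn-style interface.

    Parameters mirror :class:`OversampleConfig`. ``fit_resample(graph)``
    returns the augmented graph; provenance is stored on the fitted estimator.

    Attributes
    ----------
    minority_nodes_ : ndarray
        Training node ids of the minority class found during resampling.
    augmented_ : AugmentedGraph
        Full augmentation record of the last ``fit_resample`` call.
    """

    def __init__(self, target_ratio: float = 1.0, k_neighbors: int = 5,
                 edge_strategy: str = "inherit-source", seed: int = 0):
        self.target_ratio = target_ratio
        self.k_neighbors = k_neighbors
        self.edge_strategy = edge_strategy
        self.seed = seed

    def _config(self) -> OversampleConfig:
        return OversampleConfig(target_ratio=self.target_ratio,
                                k_neighbors=self.k_neighbors,
                                edge_strategy=self.edge_strategy, seed=self.seed)

    def fit_resample(self, graph: ProteinGraph) -> ProteinGraph:
        self.minority_nodes_ = identify_minority_nodes(graph)
        self.augmented_ = oversample(graph, self._config())
        return self.augmented_.as_graph()
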