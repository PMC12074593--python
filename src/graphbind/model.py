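"""SAGE-aggregation + MLP node classifier trained with focal loss.

The forward pass per SAGE layer: each node sums its neighbors' feature rows,
concatenates the sum with its own row, applies a learned linear map and a
ReLU. The resulting representations feed a two-hidden-layer MLP (LeakyReLU)
whose softmax output is the per-node class distribution. Training minimizes
the focal loss L = -alpha * (1 - p_t)^gamma * log(p_t) averaged over
training nodes, where p_t is the probability the model assigns to the true
class — the (1 - p_t)^gamma factor down-weights easy examples so the scarce
binding residues dominate the gradient.

Everything is plain NumPy with hand-written backpropagation and an Adam
optimizer; graphs are small enough (thousands of residues) that full-batch
CPU training is fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin

from graphbind.contact_graph import ProteinGraph
from graphbind.errors import DegenerateInputError, ShapeError

_P_FLOOR = 1e-12  # clamp for log(p_t); the loss is undefined at p_t = 0


@dataclass
class SageLayerParams:
    """One SAGE layer: W maps the concatenated [h_i, n_i] (2*D_in) to D_out."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if self.W.shape[0] != self.b.shape[0] or self.W.shape[1] % 2:
            raise ShapeError("W must be (D_out, 2*D_in) with b of length D_out")


@dataclass
class MlpParams:
    """Two LeakyReLU hidden layers and a K-class linear output head."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray

    def __post_init__(self) -> None:
        ok = (self.w1.shape[0] == self.b1.shape[0] == self.w2.shape[1]
              and self.w2.shape[0] == self.b2.shape[0] == self.w_out.shape[1]
              and self.w_out.shape[0] == self.b_out.shape[0] >= 2)
        if not ok:
            raise ShapeError("inconsistent MLP shapes")


@dataclass(frozen=True)
class FocalLossConfig:
    """alpha in (0, 1] balances the classes; gamma >= 0 focuses on hard samples."""

    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def adjacency(edges: np.ndarray, n_nodes: int) -> sp.csr_matrix:
    """Symmetric 0/1 adjacency matrix from canonical (i < j) edge rows."""
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    if edges.size:
        i = np.concatenate([edges[:, 0], edges[:, 1]])
        j = np.concatenate([edges[:, 1], edges[:, 0]])
        data = np.ones(len(i))
    else:
        i = j = data = np.empty(0)
    return sp.csr_matrix((data, (i, j)), shape=(n_nodes, n_nodes))


def sage_forward(H: np.ndarray, edges: np.ndarray, params: SageLayerParams,
                 aggregate: str = "sum") -> np.ndarray:
    """One SAGE layer: out_i = ReLU(W [h_i, n_i] + b), n_i = sum of neighbors.

    Isolated nodes aggregate to the zero vector. ``aggregate='mean'`` divides
    each sum by the node degree instead.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or 2 * H.shape[1] != params.W.shape[1]:
        raise ShapeError(f"features of width {H.shape[-1]} do not match W {params.W.shape}")
    A = adjacency(edges, H.shape[0])
    N = A @ H
    if aggregate == "mean":
        deg = np.asarray(A.sum(axis=1)).ravel()
        N = N / np.maximum(deg, 1.0)[:, None]
    elif aggregate != "sum":
        raise ValueError("aggregate must be 'sum' or 'mean'")
    Z = np.hstack([H, N]) @ params.W.T + params.b
    return np.maximum(Z, 0.0)


def leaky_relu(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mlp_forward(x: np.ndarray, params: MlpParams, slope: float = 0.01) -> np.ndarray:
    """Two LeakyReLU hidden layers then a softmax head; rows sum to 1."""
    x = np.asarray(x, dtype=float)
    a1 = leaky_relu(x @ params.w1.T + params.b1, slope)
    a2 = leaky_relu(a1 @ params.w2.T + params.b2, slope)
    return softmax(a2 @ params.w_out.T + params.b_out)


def focal_loss(p_pos: np.ndarray | float, y: np.ndarray | int,
               cfg: FocalLossConfig | None = None) -> float:
    """Mean focal loss of positive-class probabilities against 0/1 labels.

    p_t is p_pos for positives and 1 - p_pos for negatives; p_t is clamped
    at 1e-12 before the log. Reduces to plain cross-entropy at
    gamma = 0, alpha = 1.
    """
    cfg = cfg or FocalLossConfig()
    p_pos = np.atleast_1d(np.asarray(p_pos, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=int))
    if p_pos.shape != y.shape:
        raise ShapeError("p_pos and y must have matching shapes")
    if np.any((p_pos < 0) | (p_pos > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    p_t = np.where(y == 1, p_pos, 1.0 - p_pos)
    p_t = np.clip(p_t, _P_FLOOR, 1.0)
    return float(np.mean(-cfg.alpha * (1.0 - p_t) ** cfg.gamma * np.log(p_t)))


# ---------------------------------------------------------------------------
# full model: stacked SAGE layers + MLP head, with backprop


@dataclass
class ModelParams:
    sage: list[SageLayerParams]
    mlp: MlpParams

    def arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.sage:
            out += [layer.W, layer.b]
        out += [self.mlp.w1, self.mlp.b1, self.mlp.w2, self.mlp.b2,
                self.mlp.w_out, self.mlp.b_out]
        return out


def init_params(in_dim: int, sage_hidden: tuple[int, ...], mlp_hidden: tuple[int, int],
                n_classes: int, rng: np.random.Generator) -> ModelParams:
    """He-style initialization scaled by fan-in."""
    def he(shape):
        return rng.standard_normal(shape) * np.sqrt(2.0 / shape[-1])

    sage = []
    d = in_dim
    for h in sage_hidden:
        sage.append(SageLayerParams(W=he((h, 2 * d)), b=np.zeros(h)))
        d = h
    h1, h2 = mlp_hidden
    mlp = MlpParams(w1=he((h1, d)), b1=np.zeros(h1),
                    w2=he((h2, h1)), b2=np.zeros(h2),
                    w_out=he((n_classes, h2)), b_out=np.zeros(n_classes))
    return ModelParams(sage=sage, mlp=mlp)


def model_forward(graph: ProteinGraph, params: ModelParams, aggregate: str = "sum",
                  slope: float = 0.01) -> np.ndarray:
    """Per-node probability matrix (one row per node, rows sum to 1)."""
    H = graph.node_features
    for layer in params.sage:
        H = sage_forward(H, graph.edges, layer, aggregate=aggregate)
    return mlp_forward(H, params.mlp, slope=slope)


def _forward_cached(graph: ProteinGraph, params: ModelParams, aggregate: str,
                    slope: float) -> tuple[np.ndarray, dict]:
    A = adjacency(graph.edges, graph.n_nodes)
    deg = np.maximum(np.asarray(A.sum(axis=1)).ravel(), 1.0)
    cache: dict = {"A": A, "deg": deg, "sage": []}
    H = graph.node_features
    for layer in params.sage:
        N = A @ H
        if aggregate == "mean":
            N = N / deg[:, None]
        Hp = np.hstack([H, N])
        Zpre = Hp @ layer.W.T + layer.b
        out = np.maximum(Zpre, 0.0)
        cache["sage"].append((H, Hp, Zpre))
        H = out
    mlp = params.mlp
    z1 = H @ mlp.w1.T + mlp.b1
    a1 = leaky_relu(z1, slope)
    z2 = a1 @ mlp.w2.T + mlp.b2
    a2 = leaky_relu(z2, slope)
    P = softmax(a2 @ mlp.w_out.T + mlp.b_out)
    cache["mlp"] = (H, z1, a1, z2, a2)
    return P, cache


def _loss_and_grads(graph: ProteinGraph, params: ModelParams, train_idx: np.ndarray,
                    loss_cfg: FocalLossConfig, aggregate: str, slope: float
                    ) -> tuple[float, list[np.ndarray]]:
    """Focal loss over training nodes and its gradient in every parameter."""
    P, cache = _forward_cached(graph, params, aggregate, slope)
    y = graph.labels[train_idx]
    p_t = np.clip(P[train_idx, y], _P_FLOOR, 1.0)
    one_m = 1.0 - p_t
    loss = float(np.mean(-loss_cfg.alpha * one_m ** loss_cfg.gamma * np.log(p_t)))

    # dL/dp_t, guarding the gamma < 1 singularity at p_t = 1
    g = loss_cfg.gamma
    if g == 0:
        dl_dpt = -loss_cfg.alpha / p_t
    else:
        dl_dpt = loss_cfg.alpha * (g * np.maximum(one_m, _P_FLOOR) ** (g - 1) * np.log(p_t)
                                   - one_m ** g / p_t)
    dl_dpt /= len(train_idx)  # mean reduction

    # softmax jacobian: dp_t/dz_k = p_t (1[k = y] - p_k)
    dZout = np.zeros_like(P)
    Pt = P[train_idx]
    dZout[train_idx] = dl_dpt[:, None] * p_t[:, None] * (np.eye(P.shape[1])[y] - Pt)

    mlp = params.mlp
    H_mlp, z1, a1, z2, a2 = cache["mlp"]
    grads_rev: list[np.ndarray] = []
    # output head
    grads_rev += [dZout.sum(axis=0), dZout.T @ a2]          # b_out, w_out
    dA2 = dZout @ mlp.w_out
    dZ2 = dA2 * np.where(z2 > 0, 1.0, slope)
    grads_rev += [dZ2.sum(axis=0), dZ2.T @ a1]              # b2, w2
    dA1 = dZ2 @ mlp.w2
    dZ1 = dA1 * np.where(z1 > 0, 1.0, slope)
    grads_rev += [dZ1.sum(axis=0), dZ1.T @ H_mlp]           # b1, w1
    dH = dZ1 @ mlp.w1

    A, deg = cache["A"], cache["deg"]
    for layer, (H_in, Hp, Zpre) in zip(reversed(params.sage), reversed(cache["sage"])):
        dZpre = dH * (Zpre > 0)
        grads_rev += [dZpre.sum(axis=0), dZpre.T @ Hp]      # b, W
        dHp = dZpre @ layer.W
        d_in = H_in.shape[1]
        dN = dHp[:, d_in:]
        if aggregate == "mean":
            dN = dN / deg[:, None]
        dH = dHp[:, :d_in] + A.T @ dN
    grads = list(reversed(grads_rev))
    # arrays() order is [W, b] per sage layer then w1,b1,w2,b2,w_out,b_out;
    # grads_rev collected (b, W) pairs in reverse, so reversal restores order.
    return loss, grads


class _Adam:
    def __init__(self, arrays: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray],
             b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8) -> None:
        self.t += 1
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + eps)


class GraphSAGEClassifier(BaseEstimator, ClassifierMixin):
    """Residue-level node classifier: stacked SAGE layers + MLP, focal loss.

    Follows the scikit-learn estimator protocol but operates on
    :class:`~graphbind.contact_graph.ProteinGraph` objects instead of flat
    design matrices: ``fit(graph)`` trains full-batch on the nodes selected
    by ``graph.train_mask`` (synthetic oversampled nodes included when the
    graph came from the oversampler), and ``predict_proba(graph)`` returns
    one probability row per node.

    Parameters
    ----------
    sage_hidden : tuple of int
        Output width of each SAGE layer (two layers of 256 by default).
    mlp_hidden : (int, int)
        Widths of the two LeakyReLU hidden layers.
    aggregate : {'sum', 'mean'}
        Neighbor aggregation; the sum form is the default.
    alpha, gamma : float
        Focal-loss weight and focusing exponent.
    threshold : float
        Decision threshold on the positive-class probability
        (``predict`` labels a node 1 iff p >= threshold).

    Attributes
    ----------
    params_ : ModelParams
        Trained weights.
    loss_history_ : ndarray
        Training focal loss per epoch.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(self, sage_hidden: tuple[int, ...] = (256, 256),
                 mlp_hidden: tuple[int, int] = (128, 64), aggregate: str = "sum",
                 alpha: float = 0.25, gamma: float = 2.0, leaky_slope: float = 0.01,
                 learning_rate: float = 1e-3, epochs: int = 200, seed: int = 0,
                 threshold: float = 0.5):
        self.sage_hidden = sage_hidden
        self.mlp_hidden = mlp_hidden
        self.aggregate = aggregate
        self.alpha = alpha
        self.gamma = gamma
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.seed = seed
        self.threshold = threshold

    def fit(self, graph: ProteinGraph, y: None = None) -> "GraphSAGEClassifier":
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        train_idx = np.flatnonzero(graph.train_mask)
        if train_idx.size == 0:
            raise DegenerateInputError("empty training mask")
        y_train = graph.labels[train_idx]
        if len(np.unique(y_train)) < 2:
            raise DegenerateInputError("training nodes contain a single class")
        rng = np.random.default_rng(self.seed)
        params = init_params(graph.feature_dim, tuple(self.sage_hidden),
                             tuple(self.mlp_hidden), 2, rng)
        loss_cfg = FocalLossConfig(alpha=self.alpha, gamma=self.gamma)
        arrays = params.arrays()
        opt = _Adam(arrays, self.learning_rate)
        history = []
        for _ in range(self.epochs):
            loss, grads = _loss_and_grads(graph, params, train_idx, loss_cfg,
                                          self.aggregate, self.leaky_slope)
            opt.step(arrays, grads)
            history.append(loss)
        self.params_ = params
        self.loss_history_ = np.array(history)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = graph.feature_dim
        return self

    def predict_proba(self, graph: ProteinGraph) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted")
        if graph.feature_dim != self.n_features_in_:
            raise ShapeError(f"graph features have width {graph.feature_dim}, "
                             f"model expects {self.n_features_in_}")
        return model_forward(graph, self.params_, aggregate=self.aggregate,
                             slope=self.leaky_slope)

    def predict(self, graph: ProteinGraph) -> np.ndarray:
        return (self.predict_proba(graph)[:, 1] >= self.threshold).astype(int)

    def save(self, path: str | Path) -> None:
        """Single weights file (.npz) plus a JSON manifest of hyperparameters."""
        path = Path(path)
        arrays = {f"arr_{i}": a for i, a in enumerate(self.params_.arrays())}
        np.savez(path.with_suffix(".npz"), **arrays)
        manifest = dict(self.get_params(), n_features_in=int(self.n_features_in_),
                        format_version=1)
        manifest["sage_hidden"] = list(manifest["sage_hidden"])
        manifest["mlp_hidden"] = list(manifest["mlp_hidden"])
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GraphSAGEClassifier":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        manifest.pop("format_version")
        n_in = manifest.pop("n_features_in")
        manifest["sage_hidden"] = tuple(manifest["sage_hidden"])
        manifest["mlp_hidden"] = tuple(manifest["mlp_hidden"])
        clf = cls(**manifest)
        data = np.load(path.with_suffix(".npz"))
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
        rng = np.random.default_rng(0)
        params = init_params(n_in, clf.sage_hidden, clf.mlp_hidden, 2, rng)
        for slot, stored in zip(params.arrays(), arrays):
            slot[...] = stored
        clf.params_ = params
        clf.loss_history_ = np.empty(0)
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = n_in
        return clf
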