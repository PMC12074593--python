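"""Training orchestration and the imbalance-aware evaluation suite.

Metrics follow the standard confusion-matrix definitions:

    Spe = TN / (TN + FP)            Pre = TP / (TP + FP)
    Rec = TP / (TP + FN)            F1  = 2 Pre Rec / (Pre + Rec)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus a rank-based AUC (the probability a random positive outranks a random
negative, ties counted half — the Mann-Whitney U normalization). Zero
denominators are reported as 0 and flagged, so reports stay finite under
degenerate predictors. Metrics are pooled over all evaluated residues of all
chains, matching how benchmark tables report one value per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from graphbind.contact_graph import ProteinGraph, batch_graphs
from graphbind.errors import ShapeError
from graphbind.graph_smote import GraphSMOTE, OversampleConfig
from graphbind.model import FocalLossConfig, GraphSAGEClassifier

#: Residue counts of the published protein-DNA binding benchmark datasets
#: (binding, non-binding); inputs for dataset-level statistics.
BENCHMARK_DATASETS: dict[str, tuple[int, int]] = {
    "TR646": (15636, 298503),
    "TR573": (14479, 145404),
    "TE46": (956, 9911),
    "TE129": (2240, 35275),
    "TE181": (3208, 72050),
}


@dataclass(frozen=True)
class TrainConfig:
    """End-to-end training parameters."""

    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    oversample: OversampleConfig | None = field(default_factory=OversampleConfig)
    loss: FocalLossConfig = field(default_factory=FocalLossConfig)
    threshold: float = 0.5
    sage_hidden: tuple[int, ...] = (32, 32)
    mlp_hidden: tuple[int, int] = (32, 16)
    aggregate: str = "sum"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and derived scores at a stated decision threshold.

    ``flagged`` lists metrics whose denominator was zero and were reported
    as 0.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    Spe: float
    Pre: float
    Rec: float
    F1: float
    MCC: float
    AUC: float | None
    threshold: float
    flagged: tuple[str, ...] = ()

    def to_row(self) -> dict:
        return {"Spe": self.Spe, "Rec": self.Rec, "Pre": self.Pre,
                "F1": self.F1, "MCC": self.MCC, "AUC": self.AUC}


def confusion_counts(prob_pos: np.ndarray, labels: np.ndarray,
                     threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with prediction = 1 iff probability >= threshold."""
    prob_pos = np.asarray(prob_pos, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if prob_pos.shape != labels.shape:
        raise ShapeError("probabilities and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = prob_pos >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return tp, fp, tn, fn


def compute_metrics(tp: int, fp: int, tn: int, fn: int,
                    threshold: float = 0.5) -> MetricsReport:
    """Specificity, precision, recall, F1 and MCC from confusion counts.

    Ratios with a zero denominator are reported as 0 and named in
    ``flagged``; AUC is not computable from counts and is left as None.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("all confusion counts are zero")
    flagged: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flagged.append(name)
            return 0.0
        return num / den

    spe = ratio(tn, tn + fp, "Spe")
    pre = ratio(tp, tp + fp, "Pre")
    rec = ratio(tp, tp + fn, "Rec")
    f1 = ratio(2 * pre * rec, pre + rec, "F1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio(tp * tn - fn * fp, mcc_den, "MCC")
    return MetricsReport(TP=tp, FP=fp, TN=tn, FN=fn, Spe=spe, Pre=pre, Rec=rec,
                         F1=f1, MCC=mcc, AUC=None, threshold=threshold,
                         flagged=tuple(flagged))


def auc_score(prob_pos: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties half.

    Computed via midranks, i.e. the Mann-Whitney U statistic normalized by
    n_pos * n_neg.
    """
    prob_pos = np.asarray(prob_pos, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if prob_pos.shape != labels.shape:
        raise ShapeError("probabilities and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(prob_pos)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate(prob_pos: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> MetricsReport:
    """Full report (confusion counts, threshold metrics, AUC) on one vector."""
    tp, fp, tn, fn = confusion_counts(prob_pos, labels, threshold)
    report = compute_metrics(tp, fp, tn, fn, threshold)
    labels = np.asarray(labels, dtype=int)
    auc = auc_score(prob_pos, labels) if 0 < labels.sum() < len(labels) else None
    return MetricsReport(**{**report.__dict__, "AUC": auc})


def train(graphs: list[ProteinGraph] | ProteinGraph,
          cfg: TrainConfig | None = None) -> tuple[GraphSAGEClassifier, np.ndarray]:
    """Train the classifier on one or more chain graphs.

    Chains are batched into one disjoint-union graph; when
    ``cfg.oversample`` is set, the training portion is rebalanced with
    graph-aware SMOTE before fitting, and the loss runs over real plus
    synthetic training nodes. Returns the fitted classifier and the
    per-epoch loss history.
    """
    cfg = cfg or TrainConfig()
    if isinstance(graphs, ProteinGraph):
        graphs = [graphs]
    if not graphs:
        raise ValueError("no training graphs")
    batched = batch_graphs(graphs) if len(graphs) > 1 else graphs[0]
    if cfg.oversample is not None:
        smote = GraphSMOTE(target_ratio=cfg.oversample.target_ratio,
                           k_neighbors=cfg.oversample.k_neighbors,
                           edge_strategy=cfg.oversample.edge_strategy,
                           seed=cfg.oversample.seed)
        fit_graph = smote.fit_resample(batched)
    else:
        fit_graph = batched
    clf = GraphSAGEClassifier(sage_hidden=cfg.sage_hidden, mlp_hidden=cfg.mlp_hidden,
                              aggregate=cfg.aggregate, alpha=cfg.loss.alpha,
                              gamma=cfg.loss.gamma, learning_rate=cfg.learning_rate,
                              epochs=cfg.epochs, seed=cfg.seed, threshold=cfg.threshold)
    clf.fit(fit_graph)
    return clf, clf.loss_history_


def evaluate_on_graph(clf: GraphSAGEClassifier, graph: ProteinGraph,
                      threshold: float | None = None) -> MetricsReport:
    """Evaluate on the nodes outside ``graph.train_mask`` (never synthetic)."""
    mask = ~graph.train_mask
    if not mask.any():
        raise ValueError("graph has no evaluation nodes")
    prob = clf.predict_proba(graph)[mask, 1]
    return evaluate(prob, graph.labels[mask],
                    threshold if threshold is not None else clf.threshold)


def dataset_stats(datasets: dict[str, tuple[int, int]] | list[ProteinGraph] | None = None
                  ) -> pd.DataFrame:
    """Per-dataset binding/non-binding counts and percent binding residues.

    Accepts either a mapping ``name -> (binding, non_binding)`` or a list of
    labeled graphs (counted per chain, pooled). Defaults to the published
    benchmark counts. Percent = 100 * binding / (binding + non_binding),
    rounded to 2 decimals.
    """
    if datasets is None:
        datasets = BENCHMARK_DATASETS
    if isinstance(datasets, list):
        counts: dict[str, tuple[int, int]] = {}
        for k, g in enumerate(datasets):
            name = (str(g.chain_ids[0]) if g.chain_ids is not None and len(g.chain_ids)
                    else f"graph{k}")
            pos = int((g.labels == 1).sum())
            counts[name] = (pos, int(g.n_nodes - pos))
        datasets = counts
    rows = []
    for name, (binding, non_binding) in datasets.items():
        total = binding + non_binding
        pct = round(100.0 * binding / total, 2) if total else 0.0
        rows.append({"dataset": name, "binding": binding, "non_binding": non_binding,
                     "pct_binding": pct})
    return pd.DataFrame(rows).set_index("dataset")
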