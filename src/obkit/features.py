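"""Node connectivity features, distribution tests, rewiring and classification.

Per-node features are computed on the unweighted topology: degree
centrality (degree / (n - 1)) and PageRank (stationary probability of a
damped random walk, damping 0.85).  Conserved and non-conserved feature
distributions are compared with the two-sample Kolmogorov-Smirnov test.
Random rewiring (uniform endpoint resampling of a fraction of edges)
serves as a robustness control that progressively dilutes any
connectivity difference.  Cross-validated classifiers (random forest and
linear SVM) quantify how well conservation can be predicted from the
network features alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .backbone import to_distance
from .netbuild import Layer

__all__ = [
    "node_features",
    "ks_compare",
    "rewire",
    "classify_conservation",
    "ClassifierReport",
]

FEATURE_COLUMNS = ["degree_centrality", "page_rank"]
EXTRA_FEATURE_COLUMNS = ["clustering", "core_number"]


def node_features(
    layer: Layer, damping: float = 0.85, extended: bool = False
) -> pd.DataFrame:
    """Per-node feature table: degree centrality, PageRank, conserved label.

    ``extended=True`` adds the clustering coefficient and k-core number.
    PageRank uses the unweighted topology and sums to 1 over nodes.
    """
    G = layer.graph
    if G.number_of_nodes() == 0:
        raise ValueError("node_features: empty graph")
    dc = nx.degree_centrality(G)
    pr = nx.pagerank(G, alpha=damping, weight=None)
    genes = sorted(G.nodes)
    data = {
        "degree_centrality": [dc[g] for g in genes],
        "page_rank": [pr[g] for g in genes],
    }
    if extended:
        cl = nx.clustering(G)
        core = nx.core_number(nx.Graph(G))  # core_number rejects self-loops
        data["clustering"] = [cl[g] for g in genes]
        data["core_number"] = [float(core[g]) for g in genes]
    data["conserved"] = [bool(G.nodes[g].get("conserved", False)) for g in genes]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sample, two-sided Kolmogorov-Smirnov test (asymptotic p value)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_compare: empty sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def rewire(layer: Layer, fraction: float, seed: int) -> Layer:
    """Randomly replace a fraction of edges with uniform random node pairs.

    ``ceil(fraction * |E|)`` edges are removed; each is replaced by an
    edge between two uniformly drawn distinct nodes that is not already
    present, carrying over the removed edge's score.  The node set, edge
    count and simple-graph property are preserved; the result is
    deterministic for a given seed.  Endpoint resampling is deliberately
    not degree-preserving: the point of the control is to dilute degree
    differences themselves.
    """
    if not (0 <= fraction <= 1):
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    out = layer.copy()
    G = out.graph
    edges = sorted((u, v) if u <= v else (v, u) for u, v in G.edges())
    m = len(edges)
    k = math.ceil(fraction * m)
    if k == 0 or m == 0:
        return out
    rng = np.random.default_rng(seed)
    nodes = sorted(G.nodes)
    n = len(nodes)
    chosen = rng.choice(m, size=k, replace=False)
    removed = [edges[i] for i in sorted(chosen)]
    scores = [G.edges[e]["score"] for e in removed]
    G.remove_edges_from(removed)
    existing = {(u, v) if u <= v else (v, u) for u, v in G.edges()}
    for score in scores:
        while True:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            u, v = nodes[i], nodes[j]
            key = (u, v) if u <= v else (v, u)
            if key in existing:
                continue
            existing.add(key)
            G.add_edge(u, v, score=score, distance=to_distance(score))
            break
    return out


@dataclass
class ClassifierReport:
    """Cross-validated conservation-classification result."""

    model: str
    folds: int
    seed: int
    fold_aucs: list[float]
    precision: list[float]
    recall: list[float]
    fold_assignment: list[int]
    hyperparameters: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def to_json(self, path) -> None:
        payload = {
            "model": self.model,
            "folds": self.folds,
            "seed": self.seed,
            "fold_aucs": self.fold_aucs,
            "mean_auc": self.mean_auc,
            "precision": self.precision,
            "recall": self.recall,
            "fold_assignment": self.fold_assignment,
            "hyperparameters": self.hyperparameters,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _make_model(model: str, seed: int):
    if model == "random-forest":
        return (
            RandomForestClassifier(n_estimators=100, random_state=seed),
            {"n_estimators": 100},
            "proba",
        )
    if model == "linear-svm":
        clf = make_pipeline(
            StandardScaler(),
            LinearSVC(C=1.0, loss="hinge", dual=True, max_iter=20000,
                      random_state=seed),
        )
        return clf, {"C": 1.0, "loss": "hinge", "standardized": True}, "decision"
    raise ValueError(f"unknown model {model!r}")


def classify_conservation(
    ft: pd.DataFrame,
    model: str = "random-forest",
    folds: int = 4,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified k-fold CV of conserved-vs-not from network features.

    Features are every numeric column of ``ft`` except the boolean
    ``conserved`` label.  AUC is computed per fold from out-of-fold
    scores; the precision-recall curve pools all out-of-fold scores.
    """
    if "conserved" not in ft.columns:
        raise ValueError("feature table lacks a 'conserved' column")
    y = ft["conserved"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("classify_conservation: only one class present")
    feat_cols = [c for c in ft.columns if c != "conserved"]
    X = ft[feat_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    fold_assignment = np.full(len(y), -1, dtype=int)
    oof_scores = np.zeros(len(y), dtype=float)
    for f, (train, test) in enumerate(skf.split(X, y)):
        clf, hyper, kind = _make_model(model, seed)
        clf.fit(X[train], y[train])
        if kind == "proba":
            scores = clf.predict_proba(X[test])[:, 1]
        else:
            scores = clf.decision_function(X[test])
        oof_scores[test] = scores
        fold_assignment[test] = f
        fold_aucs.append(float(roc_auc_score(y[test], scores)))
    precision, recall, _ = precision_recall_curve(y, oof_scores)
    _, hyper, _ = _make_model(model, seed)
    return ClassifierReport(
        model=model,
        folds=folds,
        seed=seed,
        fold_aucs=fold_aucs,
        precision=[float(p) for p in precision],
        recall=[float(r) for r in recall],
        fold_assignment=fold_assignment.tolist(),
        hyperparameters=hyper,
    )
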