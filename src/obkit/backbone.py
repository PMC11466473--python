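"""Metric backbone extraction for weighted graphs.

Confidence scores ``s`` in (0, 1] are mapped to distances with the
isomorphism ``d = 1/s - 1`` (strictly decreasing, d(1) = 0), so strong
associations are short.  An edge (u, v) is *metric* when its direct
distance equals the shortest-path distance between u and v; it is
*semi-metric* (and redundant for all shortest paths) when some indirect
path is strictly shorter.  The metric backbone — the subgraph of all
metric edges over all original nodes — is exactly the minimal subgraph
sufficient to compute every shortest path of the original network.

Ties (an indirect path exactly as long as the direct edge, within a
relative tolerance) count the edge as metric, which keeps the operator
idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .netbuild import Layer

__all__ = [
    "to_distance",
    "metric_backbone",
    "verify_distance_preservation",
    "BackboneResult",
]

_CHUNK = 512  # sources per Dijkstra batch; bounds the dense row block


def to_distance(score: float, kind: str = "reciprocal") -> float:
    """Map a confidence score in (0, 1] to a distance >= 0.

    Kinds: ``reciprocal`` (default) d = 1/s - 1; ``neglog`` d = -ln s;
    ``one_minus`` d = 1 - s.  All are strictly decreasing with d(1) = 0.
    """
    if not (0 < score <= 1):
        raise ValueError(f"score {score} outside (0, 1]")
    if kind == "reciprocal":
        return 1.0 / score - 1.0
    if kind == "neglog":
        return -math.log(score)
    if kind == "one_minus":
        return 1.0 - score
    raise ValueError(f"unknown distance kind {kind!r}")


@dataclass
class BackboneResult:
    """Partition of a layer's edges into metric and semi-metric sets."""

    layer: Layer
    metric_edges: frozenset[tuple[str, str]]
    semi_metric_edges: frozenset[tuple[str, str]]
    rel_tol: float = 1e-9
    _backbone: Layer | None = field(default=None, repr=False, compare=False)

    @property
    def backbone(self) -> Layer:
        """The metric-edge subgraph, keeping all original nodes."""
        if self._backbone is None:
            G = self.layer.graph.edge_subgraph(self.metric_edges).copy()
            G.add_nodes_from(self.layer.graph.nodes(data=True))
            self._backbone = Layer(self.layer.species_id, G)
        return self._backbone

    @property
    def n_metric(self) -> int:
        return len(self.metric_edges)

    @property
    def n_semi_metric(self) -> int:
        return len(self.semi_metric_edges)


def _distance_matrix_parts(layer: Layer):
    nodes = sorted(layer.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, d in layer.graph.edges(data="distance"):
        if d is None or d < 0 or not np.isfinite(d):
            raise ValueError(f"edge {u!r}-{v!r} has invalid distance {d}")
        rows.append(idx[u])
        cols.append(idx[v])
        vals.append(float(d))
    n = len(nodes)
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return nodes, idx, mat


def metric_backbone(layer: Layer, rel_tol: float = 1e-9) -> BackboneResult:
    """Classify every edge as metric or semi-metric.

    Edge (u, v) with direct distance ``d_uv`` is metric iff
    ``d_uv <= D(u, v) * (1 + rel_tol)`` where D is the all-pairs
    shortest-path distance (computed by single-source Dijkstra from every
    node, batched through scipy's C implementation).  Since D <= d_uv
    always, this counts exact ties as metric.
    """
    nodes, idx, mat = _distance_matrix_parts(layer)
    n = len(nodes)
    metric: set[tuple[str, str]] = set()
    semi: set[tuple[str, str]] = set()
    if layer.graph.number_of_edges() == 0:
        return BackboneResult(layer, frozenset(), frozenset(), rel_tol)
    # incident edges keyed by the lower-index endpoint so each edge is
    # classified exactly once
    incident: dict[int, list[tuple[int, float, tuple[str, str]]]] = {}
    for u, v, d in layer.graph.edges(data="distance"):
        iu, iv = idx[u], idx[v]
        key = (u, v) if u <= v else (v, u)
        if iu > iv:
            iu, iv = iv, iu
        incident.setdefault(iu, []).append((iv, float(d), key))
    sources = sorted(incident)
    for start in range(0, len(sources), _CHUNK):
        batch = sources[start : start + _CHUNK]
        D = dijkstra(mat, directed=False, indices=batch)
        for row, iu in enumerate(batch):
            for iv, d, key in incident[iu]:
                if d <= D[row, iv] * (1.0 + rel_tol):
                    metric.add(key)
                else:
                    semi.add(key)
    return BackboneResult(layer, frozenset(metric), frozenset(semi), rel_tol)


def verify_distance_preservation(
    bb: BackboneResult, rel_tol: float | None = None
) -> tuple[bool, float]:
    """Check that the backbone preserves all shortest-path distances.

    Returns ``(ok, max_relative_deviation)`` over all node pairs of the
    original layer; pairs disconnected in the original must stay
    disconnected, and a pair disconnected only in the backbone yields an
    infinite deviation.
    """
    if rel_tol is None:
        rel_tol = bb.rel_tol
    layer = bb.layer
    if layer.graph.number_of_nodes() == 0:
        return True, 0.0
    nodes, _, mat_full = _distance_matrix_parts(layer)
    _, _, mat_bb = _distance_matrix_parts(bb.backbone)
    if mat_bb.shape != mat_full.shape:
        # node sets differ (tampered input); rebuild on the full node order
        idx = {n: i for i, n in enumerate(nodes)}
        rows, cols, vals = [], [], []
        for u, v, d in bb.backbone.graph.edges(data="distance"):
            rows.append(idx[u])
            cols.append(idx[v])
            vals.append(float(d))
        mat_bb = sp.csr_matrix((vals, (rows, cols)), shape=mat_full.shape)
    n = len(nodes)
    max_dev = 0.0
    for start in range(0, n, _CHUNK):
        batch = list(range(start, min(start + _CHUNK, n)))
        D_full = dijkstra(mat_full, directed=False, indices=batch)
        D_bb = dijkstra(mat_bb, directed=False, indices=batch)
        full_inf = np.isinf(D_full)
        bb_inf = np.isinf(D_bb)
        if np.any(bb_inf & ~full_inf):
            return False, float("inf")
        both = ~full_inf
        diff = np.abs(D_bb[both] - D_full[both])
        denom = np.maximum(D_full[both], np.finfo(float).tiny)
        if diff.size:
            max_dev = max(max_dev, float(np.max(diff / denom)))
    return max_dev <= rel_tol, max_dev
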