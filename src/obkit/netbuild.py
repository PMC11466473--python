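"""Build expression-filtered, single-species weighted interaction layers.

A :class:`Layer` is one species' undirected simple graph: each edge
carries a confidence score ``s`` in (0, 1] and a derived distance
``d >= 0``; nodes optionally carry a boolean ``conserved`` flag.  The
default pipeline keeps an interaction iff both endpoints are expressed
(group-mean TPM strictly above the cutoff) and the score passes the
confidence threshold (default >= 0.5), then reduces to the largest
connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .io import EdgeRecord, ExpressionMatrix, GeneSet, _data_rows, _open_out

logger = logging.getLogger(__name__)

__all__ = [
    "Layer",
    "expressed_genes",
    "build_layer",
    "largest_connected_component",
    "write_layer",
    "read_layer",
]


@dataclass
class Layer:
    """One species' undirected weighted interaction graph.

    Edge attributes: ``score`` in (0, 1] and ``distance`` >= 0.
    Optional node attribute: ``conserved`` (bool).
    """

    species_id: str
    graph: nx.Graph

    def validate(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            s = data.get("score")
            d = data.get("distance")
            if s is None or not (0 < s <= 1):
                raise ValueError(f"edge {u!r}-{v!r} score {s} outside (0, 1]")
            if d is None or d < 0 or d != d or d == float("inf"):
                raise ValueError(f"edge {u!r}-{v!r} distance {d} invalid")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as canonically ordered (min, max) tuples."""
        return {(u, v) if u <= v else (v, u) for u, v in self.graph.edges()}

    def conserved_nodes(self) -> set[str]:
        return {
            n
            for n, flag in self.graph.nodes(data="conserved", default=False)
            if flag
        }

    def copy(self) -> "Layer":
        return Layer(self.species_id, self.graph.copy())


def expressed_genes(
    expr: ExpressionMatrix, group: str, cutoff: float = 1.0
) -> GeneSet:
    """Genes whose arithmetic-mean TPM across the group's samples is > cutoff.

    The inequality is strict: a gene at exactly the cutoff is excluded.
    """
    samples = expr.samples_of_group(group)  # raises on unknown group
    mean_tpm = expr.values[samples].mean(axis=1)
    members = frozenset(mean_tpm.index[mean_tpm > cutoff].astype(str))
    return GeneSet(label=group, members=members)


def build_layer(
    edges: Iterable[EdgeRecord],
    genes: GeneSet,
    species_id: str = "",
    min_score: float = 0.5,
    distance_kind: str = "reciprocal",
) -> Layer:
    """Induce a layer on the expressed genes, keeping edges with score >= min_score.

    Nodes are the expressed genes that appear as an endpoint of any input
    edge; an edge is retained iff both endpoints are expressed and its
    score passes the (inclusive) threshold.  Distances are populated via
    :func:`obkit.backbone.to_distance`.
    """
    from .backbone import to_distance  # local import to avoid a module cycle

    G = nx.Graph()
    for rec in edges:
        a_in = rec.gene_a in genes.members
        b_in = rec.gene_b in genes.members
        if a_in:
            G.add_node(rec.gene_a)
        if b_in:
            G.add_node(rec.gene_b)
        if a_in and b_in and rec.score >= min_score and rec.gene_a != rec.gene_b:
            G.add_edge(
                rec.gene_a,
                rec.gene_b,
                score=rec.score,
                distance=to_distance(rec.score, kind=distance_kind),
            )
    return Layer(species_id, G)


def largest_connected_component(layer: Layer) -> Layer:
    """The induced subgraph on the largest component.

    Ties are broken deterministically: among equally large components
    the one whose sorted node-id list is lexicographically smallest wins.
    """
    if layer.graph.number_of_nodes() == 0:
        logger.warning("largest_connected_component: empty graph")
        return layer.copy()
    comps = [sorted(c) for c in nx.connected_components(layer.graph)]
    best = min(comps, key=lambda c: (-len(c), c))
    return Layer(layer.species_id, layer.graph.subgraph(best).copy())


# ---------------------------------------------------------------------------
# serialization: edge TSV (gene_a, gene_b, score, distance[, metric]) plus an
# optional node-attribute TSV (gene, conserved)


def write_layer(
    layer: Layer,
    edges_path,
    nodes_path=None,
    metric_edges: set[tuple[str, str]] | None = None,
) -> None:
    with _open_out(edges_path) as fh:
        cols = "gene_a\tgene_b\tscore\tdistance"
        if metric_edges is not None:
            cols += "\tmetric"
        fh.write(cols + "\n")
        for u, v in sorted(layer.edge_set()):
            data = layer.graph.edges[u, v]
            row = f"{u}\t{v}\t{data['score']:.17g}\t{data['distance']:.17g}"
            if metric_edges is not None:
                row += f"\t{int((u, v) in metric_edges)}"
            fh.write(row + "\n")
    if nodes_path is not None:
        with _open_out(nodes_path) as fh:
            fh.write("gene_id\tconserved\n")
            for n in sorted(layer.graph.nodes):
                flag = int(bool(layer.graph.nodes[n].get("conserved", False)))
                fh.write(f"{n}\t{flag}\n")


def read_layer(
    edges_path, nodes_path=None, species_id: str = ""
) -> tuple[Layer, set[tuple[str, str]] | None]:
    """Read a serialized layer; returns (layer, metric-edge set or None)."""
    G = nx.Graph()
    metric: set[tuple[str, str]] | None = None
    first = True
    for parts in _data_rows(edges_path, min_cols=4):
        if first:
            first = False
            try:
                float(parts[2])
            except ValueError:
                if len(parts) >= 5 and parts[4] == "metric":
                    metric = set()
                continue
        u, v = (parts[0], parts[1]) if parts[0] <= parts[1] else (parts[1], parts[0])
        G.add_edge(u, v, score=float(parts[2]), distance=float(parts[3]))
        if len(parts) >= 5 and metric is not None and parts[4] == "1":
            metric.add((u, v))
    if nodes_path is not None:
        first = True
        for parts in _data_rows(nodes_path, min_cols=2):
            if first:
                first = False
                if parts[1] not in ("0", "1"):
                    continue
            G.add_node(parts[0], conserved=bool(int(parts[1])))
    return Layer(species_id, G), metric
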