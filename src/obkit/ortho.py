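"""Multilayer orthology and the orthoBackbone.

Each species contributes one layer (its interaction graph and metric
backbone).  Genes in different layers are linked when they share an
orthogroup; the relation is one-to-many, so a gene may link to several
paralogs in another layer.  The *orthoBackbone* keeps a backbone edge
(a, b) of layer L iff for **every** other layer L' there is at least one
analogous backbone edge (a', b') with a' orthologous to a, b'
orthologous to b and a' != b'.  Nodes left without retained edges are
dropped, so each layer's orthoBackbone is a (usually much smaller)
subgraph of its metric backbone and not necessarily itself a backbone.

Downstream statistics: Jaccard overlap of edge sets, annotation-based
core selection, and the DEG edge-disruption fraction (edges with at
least one differentially expressed endpoint).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from scipy import stats

from .backbone import BackboneResult, metric_backbone
from .io import GeneSet, OrthogroupTable
from .netbuild import Layer

logger = logging.getLogger(__name__)

__all__ = [
    "MultilayerNetwork",
    "OrthoBackbone",
    "DisruptionReport",
    "link_layers",
    "compute_backbones",
    "extract_orthobackbone",
    "edge_jaccard",
    "select_core",
    "edge_disruption",
    "compare_disruption",
]

Edge = tuple[str, str]


def _canon(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass
class MultilayerNetwork:
    """Species layers plus interlayer ortholog links.

    ``links[species][gene][other_species]`` is the set of genes of
    ``other_species``'s layer sharing ``gene``'s orthogroup.  Links are
    symmetric, connect only genes of different layers, and every linked
    pair shares an orthogroup.  A node is flagged conserved iff its
    orthogroup has members present in *all* layers.
    """

    layers: dict[str, Layer]
    orthogroups: OrthogroupTable
    links: dict[str, dict[str, dict[str, frozenset[str]]]]
    backbones: dict[str, BackboneResult] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted(self.layers)

    def orthologs(self, species: str, gene: str, other: str) -> frozenset[str]:
        return self.links.get(species, {}).get(gene, {}).get(other, frozenset())


def link_layers(
    og: OrthogroupTable, layers: dict[str, Layer]
) -> MultilayerNetwork:
    """Build interlayer links and conserved flags from orthogroup membership.

    Every layer's species must appear in the orthogroup table; layer
    nodes absent from the table get zero links and a False flag.
    """
    missing = set(layers) - og.species()
    if missing:
        raise ValueError(
            f"layer species absent from the orthogroup table: {sorted(missing)}"
        )
    node_sets = {sp: set(layer.graph.nodes) for sp, layer in layers.items()}
    # per species: orthogroup -> genes of that orthogroup present in the layer
    present: dict[str, dict[str, frozenset[str]]] = {}
    gene_og: dict[str, dict[str, str]] = {}
    for sp in layers:
        g2o = og.gene_to_group(sp)
        gene_og[sp] = g2o
        by_og: dict[str, set[str]] = {}
        for g in node_sets[sp]:
            o = g2o.get(g)
            if o is not None:
                by_og.setdefault(o, set()).add(g)
        present[sp] = {o: frozenset(gs) for o, gs in by_og.items()}
    links: dict[str, dict[str, dict[str, frozenset[str]]]] = {}
    for sp, layer in layers.items():
        sp_links: dict[str, dict[str, frozenset[str]]] = {}
        for g in node_sets[sp]:
            o = gene_og[sp].get(g)
            per_other: dict[str, frozenset[str]] = {}
            conserved = o is not None
            for other in layers:
                if other == sp:
                    continue
                partners = (
                    present[other].get(o, frozenset()) if o is not None else frozenset()
                )
                per_other[other] = partners
                if not partners:
                    conserved = False
            sp_links[g] = per_other
            layer.graph.nodes[g]["conserved"] = conserved
        links[sp] = sp_links
    return MultilayerNetwork(dict(layers), og, links)


def compute_backbones(ml: MultilayerNetwork, rel_tol: float = 1e-9) -> None:
    """Fill in the metric backbone of every layer (in place)."""
    for sp, layer in ml.layers.items():
        ml.backbones[sp] = metric_backbone(layer, rel_tol=rel_tol)


@dataclass
class OrthoBackbone:
    """Per layer: the retained (cross-species conserved) backbone edges."""

    edges: dict[str, frozenset[Edge]]
    nodes: dict[str, frozenset[str]]

    def layer_subgraph(self, ml: MultilayerNetwork, species: str) -> Layer:
        G = ml.layers[species].graph.edge_subgraph(self.edges[species]).copy()
        return Layer(species, G)


def extract_orthobackbone(ml: MultilayerNetwork) -> OrthoBackbone:
    """Collapse the per-layer metric backbones through the ortholog links.

    A backbone edge (a, b) of layer L is retained iff every other layer
    L' contains a backbone edge (a', b') with a' in links(a, L'), b' in
    links(b, L') and a' != b' (the one-to-many rule: one analogous
    backbone edge suffices).  The per-layer rule is independent of layer
    processing order.  Nodes with no retained edge are removed.
    """
    missing = [sp for sp in ml.layers if sp not in ml.backbones]
    if missing:
        raise ValueError(f"missing backbone for layer(s): {sorted(missing)}")
    bb_edges = {sp: bb.metric_edges for sp, bb in ml.backbones.items()}
    # index backbone edges by endpoint for fast analog lookup
    by_node: dict[str, dict[str, set[str]]] = {}
    for sp, edges in bb_edges.items():
        nbrs: dict[str, set[str]] = {}
        for u, v in edges:
            nbrs.setdefault(u, set()).add(v)
            nbrs.setdefault(v, set()).add(u)
        by_node[sp] = nbrs
    out_edges: dict[str, frozenset[Edge]] = {}
    out_nodes: dict[str, frozenset[str]] = {}
    others = {sp: [o for o in ml.layers if o != sp] for sp in ml.layers}
    for sp in ml.layers:
        kept: set[Edge] = set()
        for a, b in bb_edges[sp]:
            ok = True
            for other in others[sp]:
                cand_a = ml.orthologs(sp, a, other)
                cand_b = ml.orthologs(sp, b, other)
                if not cand_a or not cand_b:
                    ok = False
                    break
                nbrs = by_node[other]
                found = False
                for a2 in cand_a:
                    hits = nbrs.get(a2)
                    if hits and any(b2 in hits for b2 in cand_b if b2 != a2):
                        found = True
                        break
                if not found:
                    ok = False
                    break
            if ok:
                kept.add(_canon(a, b))
        out_edges[sp] = frozenset(kept)
        out_nodes[sp] = frozenset(n for e in kept for n in e)
    return OrthoBackbone(out_edges, out_nodes)


def edge_jaccard(edges_a: set[Edge], edges_b: set[Edge]) -> float:
    """Jaccard similarity |A & B| / |A | B| of two undirected edge sets."""
    a = {_canon(*e) for e in edges_a}
    b = {_canon(*e) for e in edges_b}
    union = a | b
    if not union:
        logger.warning("edge_jaccard: both edge sets empty; returning 0")
        return 0.0
    return len(a & b) / len(union)


def select_core(
    ob_layer: set[Edge],
    set_x: GeneSet,
    set_y: GeneSet,
    mode: str = "intersection",
) -> set[Edge]:
    """Edges with an endpoint in both annotation sets.

    ``mode="intersection"`` (default): at least one endpoint lies in
    X & Y — e.g. a gene that is both spermatogenesis-related and a gene
    expression regulator.  ``mode="one_each"``: one endpoint in X and
    the other in Y.
    """
    if mode == "intersection":
        both = set_x.members & set_y.members
        return {_canon(*e) for e in ob_layer if e[0] in both or e[1] in both}
    if mode == "one_each":
        return {
            _canon(*e)
            for e in ob_layer
            if (e[0] in set_x.members and e[1] in set_y.members)
            or (e[0] in set_y.members and e[1] in set_x.members)
        }
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class DisruptionReport:
    total: int
    disrupted: int

    @property
    def fraction(self) -> float:
        return self.disrupted / self.total


def edge_disruption(edges: set[Edge], deg: GeneSet) -> DisruptionReport:
    """Count edges with at least one differentially expressed endpoint."""
    edges = set(edges)
    if not edges:
        raise ValueError("edge_disruption: empty edge set")
    hit = sum(1 for u, v in edges if u in deg.members or v in deg.members)
    return DisruptionReport(total=len(edges), disrupted=hit)


def compare_disruption(
    edges_a: set[Edge], edges_b: set[Edge], deg: GeneSet
) -> tuple[float, float]:
    """Two-sided Fisher exact test comparing the disruption of two edge sets.

    Returns (odds ratio, p value) for the 2x2 table of disrupted vs
    intact counts.
    """
    ra = edge_disruption(edges_a, deg)
    rb = edge_disruption(edges_b, deg)
    table = [
        [ra.disrupted, ra.total - ra.disrupted],
        [rb.disrupted, rb.total - rb.disrupted],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def pairwise_orthobackbone_sizes(
    ml: MultilayerNetwork,
) -> dict[tuple[str, str], dict[str, int]]:
    """orthoBackbone edge counts for every species pair, per layer.

    Two-species orthoBackbones are never smaller than the all-species
    one: every extra layer tightens the retention condition.
    """
    out: dict[tuple[str, str], dict[str, int]] = {}
    for pair in combinations(sorted(ml.layers), 2):
        # copies: link_layers re-flags conservation with pair-only semantics
        sub_layers = {sp: ml.layers[sp].copy() for sp in pair}
        sub = link_layers(ml.orthogroups, sub_layers)
        sub.backbones = {sp: ml.backbones[sp] for sp in pair}
        ob = extract_orthobackbone(sub)
        out[pair] = {sp: len(ob.edges[sp]) for sp in pair}
    return out
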