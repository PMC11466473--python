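"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here deliberately take a different route
than the package code (dense Floyd-Warshall min-plus iteration instead
of sparse Dijkstra; edge-scan enumeration instead of ortholog-indexed
lookup; a hand-rolled Newick builder for tree oracles), so that
agreement between the two is informative.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import networkx as nx

from obkit.backbone import to_distance
from obkit.netbuild import Layer

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
settings.load_profile("ci")


def make_layer(edges, species_id="sp", nodes=()):
    """Build a Layer from (u, v, score) triples."""
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for u, v, s in edges:
        G.add_edge(u, v, score=s, distance=to_distance(s))
    return Layer(species_id, G)


def random_score_layer(rng, n_max=50, p=None, species_id="sp"):
    """A random weighted graph with Beta-distributed confidence scores."""
    n = int(rng.integers(4, n_max + 1))
    if p is None:
        p = float(rng.uniform(0.1, 0.5))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((f"n{i}", f"n{j}", float(np.clip(rng.beta(2, 2), 1e-6, 1.0))))
    return make_layer(edges, species_id=species_id, nodes=[f"n{i}" for i in range(n)])


def floyd_warshall_classify(layer, rel_tol=1e-9):
    """Brute-force metric/semi-metric edge labels via dense min-plus iteration."""
    nodes = sorted(layer.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for u, v, d in layer.graph.edges(data="distance"):
        i, j = idx[u], idx[v]
        D[i, j] = D[j, i] = min(D[i, j], d)
    for k in range(n):
        D = np.minimum(D, D[:, k, None] + D[None, k, :])
    metric, semi = set(), set()
    for u, v, d in layer.graph.edges(data="distance"):
        key = (u, v) if u <= v else (v, u)
        if d <= D[idx[u], idx[v]] * (1 + rel_tol):
            metric.add(key)
        else:
            semi.add(key)
    return metric, semi


def orthobackbone_enumeration_oracle(ml):
    """Brute-force orthoBackbone: scan every other layer's backbone edges.

    Retains backbone edge (a, b) of layer L iff each other layer has a
    backbone edge (x, y), x != y, with x sharing a's orthogroup and y
    sharing b's (or swapped).
    """
    og_of = {sp: ml.orthogroups.gene_to_group(sp) for sp in ml.layers}
    result = {}
    for sp in ml.layers:
        kept = set()
        for a, b in ml.backbones[sp].metric_edges:
            oa, ob_ = og_of[sp].get(a), og_of[sp].get(b)
            if oa is None or ob_ is None:
                continue
            ok = True
            for other in ml.layers:
                if other == sp:
                    continue
                found = False
                for x, y in ml.backbones[other].metric_edges:
                    ox, oy = og_of[other].get(x), og_of[other].get(y)
                    if (ox == oa and oy == ob_) or (ox == ob_ and oy == oa):
                        found = True
                        break
                if not found:
                    ok = False
                    break
            if ok:
                kept.add((a, b) if a <= b else (b, a))
        result[sp] = kept
    return result


def random_binary_tree_newick(rng, leaves):
    """Rooted binary tree over the given leaf labels, plus an oracle path.

    Returns (newick, path_leaf_sets for leaves[0] as focal), computed
    from the nested-list structure directly, independent of any Newick
    parser.
    """
    items = [(lbl, frozenset({lbl})) for lbl in leaves]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append((f"({a[0]},{b[0]})", a[1] | b[1]))

    focal = leaves[0]

    # recompute the root->focal path by re-merging with the same seed-free
    # structure: track, for every internal merge, the leaf set; the path is
    # every merge set containing the focal leaf, ordered by size descending.
    def collect(newick):
        # parse the newick we just built (pure bracket matching)
        sets = []

        def parse(s):
            if not s.startswith("("):
                return frozenset({s})
            depth = 0
            for k, ch in enumerate(s[1:-1], start=1):
                if ch == "(":
                    depth += 1
                elif ch == ")":
                    depth -= 1
                elif ch == "," and depth == 0:
                    left = parse(s[1:k])
                    right = parse(s[k + 1 : -1])
                    merged = left | right
                    sets.append(merged)
                    return merged
            raise AssertionError("unbalanced newick")

        parse(newick)
        return sets

    newick = items[0][0]
    internal_sets = collect(newick)
    path = [s for s in internal_sets if focal in s]
    path.sort(key=len, reverse=True)
    path.append(frozenset({focal}))
    return newick + ";", path


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
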