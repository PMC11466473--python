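import numpy as np
import pytest

from conftest import make_layer, orthobackbone_enumeration_oracle
from obkit.backbone import metric_backbone
from obkit.io import GeneSet, OrthogroupTable
from obkit.ortho import (
    compare_disruption,
    compute_backbones,
    edge_disruption,
    edge_jaccard,
    extract_orthobackbone,
    link_layers,
    pairwise_orthobackbone_sizes,
    select_core,
)
from obkit.synthetic import SimulationConfig, simulate_multilayer


def _og(groups):
    return OrthogroupTable(
        {
            og_id: {sp: frozenset(genes) for sp, genes in by_sp.items()}
            for og_id, by_sp in groups.items()
        }
    )


def _ml(og, layers):
    ml = link_layers(og, layers)
    compute_backbones(ml)
    return ml


# --- linking ----------------------------------------------------------------


def test_link_layers_paralogs_one_to_many():
    og = _og({"OG1": {"s1": ["B"], "s2": ["Bp", "Bpp"]}})
    layers = {
        "s1": make_layer([("A", "B", 0.9)], species_id="s1"),
        "s2": make_layer([("Bp", "Bpp", 0.9)], species_id="s2"),
    }
    ml = link_layers(og, layers)
    assert ml.orthologs("s1", "B", "s2") == {"Bp", "Bpp"}
    assert ml.orthologs("s2", "Bp", "s1") == {"B"}
    assert layers["s1"].graph.nodes["B"]["conserved"] is True
    assert layers["s1"].graph.nodes["A"]["conserved"] is False


def test_link_layers_gene_without_orthogroup():
    og = _og({"OG1": {"s1": ["X"], "s2": ["Y"]}})
    layers = {
        "s1": make_layer([("A", "B", 0.9)], species_id="s1"),
        "s2": make_layer([("Y", "Z", 0.9)], species_id="s2"),
    }
    ml = link_layers(og, layers)
    assert ml.orthologs("s1", "A", "s2") == frozenset()
    assert layers["s1"].graph.nodes["A"]["conserved"] is False


def test_link_layers_missing_species_errors():
    og = _og({"OG1": {"s1": ["A"]}})
    layers = {
        "s1": make_layer([("A", "B", 0.9)], species_id="s1"),
        "s2": make_layer([("C", "D", 0.9)], species_id="s2"),
    }
    with pytest.raises(ValueError, match="s2"):
        link_layers(og, layers)


# --- orthoBackbone ----------------------------------------------------------


def _mirror_path_setup(drop_bc_in_s2=False):
    og = _og({
        "OGA": {"s1": ["A"], "s2": ["A2"]},
        "OGB": {"s1": ["B"], "s2": ["B2"]},
        "OGC": {"s1": ["C"], "s2": ["C2"]},
    })
    l2_edges = [("A2", "B2", 0.9)]
    if not drop_bc_in_s2:
        l2_edges.append(("B2", "C2", 0.9))
    layers = {
        "s1": make_layer([("A", "B", 0.9), ("B", "C", 0.9)], species_id="s1"),
        "s2": make_layer(l2_edges, species_id="s2", nodes=["C2"]),
    }
    return _ml(og, layers)


def test_orthobackbone_perfect_mirror_retains_all():
    ob = extract_orthobackbone(_mirror_path_setup())
    assert ob.edges["s1"] == {("A", "B"), ("B", "C")}
    assert ob.edges["s2"] == {("A2", "B2"), ("B2", "C2")}


def test_orthobackbone_missing_analog_drops_edge_and_node():
    ob = extract_orthobackbone(_mirror_path_setup(drop_bc_in_s2=True))
    assert ob.edges["s1"] == {("A", "B")}
    assert ob.edges["s2"] == {("A2", "B2")}
    assert "C" not in ob.nodes["s1"]
    assert "C2" not in ob.nodes["s2"]


def test_orthobackbone_one_to_many_at_least_one_rule():
    # in layer 2 the analog A2-B2 is absent but the paralog analog
    # A2-B2p is a backbone edge, which suffices
    og = _og({
        "OGA": {"s1": ["A"], "s2": ["A2"]},
        "OGB": {"s1": ["B"], "s2": ["B2", "B2p"]},
    })
    layers = {
        "s1": make_layer([("A", "B", 0.9)], species_id="s1"),
        "s2": make_layer([("A2", "B2p", 0.9)], species_id="s2", nodes=["B2"]),
    }
    ob = extract_orthobackbone(_ml(og, layers))
    assert ob.edges["s1"] == {("A", "B")}


def test_orthobackbone_requires_distinct_analog_endpoints():
    # A and B share one orthogroup whose only layer-2 member is the
    # single gene AB2: no analog edge between two distinct genes exists
    og = _og({"OGAB": {"s1": ["A", "B"], "s2": ["AB2"]}})
    layers = {
        "s1": make_layer([("A", "B", 0.9)], species_id="s1"),
        "s2": make_layer([("AB2", "X", 0.9)], species_id="s2"),
    }
    ob = extract_orthobackbone(_ml(og, layers))
    assert ob.edges["s1"] == frozenset()


def test_orthobackbone_missing_backbone_errors():
    og = _og({"OG1": {"s1": ["A"], "s2": ["A2"]}})
    layers = {
        "s1": make_layer([("A", "B", 0.9)], species_id="s1"),
        "s2": make_layer([("A2", "B2", 0.9)], species_id="s2"),
    }
    ml = link_layers(og, layers)
    with pytest.raises(ValueError, match="missing backbone"):
        extract_orthobackbone(ml)


def _random_toy_ml(seed, n_layers):
    cfg = SimulationConfig(
        n_layers=n_layers,
        genes_per_layer=int(np.random.default_rng(seed).integers(12, 31)),
        conserved_fraction=0.6,
        paralog_rate=0.3,
        mean_degree=3.0,
        degree_multiplier=2.0,
        n_ranks=max(6, n_layers + 1),
        seed=seed,
    )
    layers, og, _ = simulate_multilayer(cfg)
    return _ml(og, layers)


def test_orthobackbone_subset_chain_and_order_invariance():
    for seed in range(5):
        ml = _random_toy_ml(seed, n_layers=3)
        ob = extract_orthobackbone(ml)
        for sp in ml.layers:
            assert ob.edges[sp] <= ml.backbones[sp].metric_edges
            assert ml.backbones[sp].metric_edges <= ml.layers[sp].edge_set()
        # permuted layer order gives identical results
        order = list(reversed(ml.species))
        ml2 = link_layers(ml.orthogroups, {sp: ml.layers[sp] for sp in order})
        ml2.backbones = {sp: ml.backbones[sp] for sp in order}
        ob2 = extract_orthobackbone(ml2)
        assert ob2.edges == ob.edges
        # pairwise orthoBackbones contain the three-way one
        for (sa, sb), sizes in pairwise_orthobackbone_sizes(ml).items():
            assert sizes[sa] >= len(ob.edges[sa])
            assert sizes[sb] >= len(ob.edges[sb])


def test_orthobackbone_matches_enumeration_oracle_on_toys():
    for seed in range(8):
        ml = _random_toy_ml(seed, n_layers=2 + seed % 2)
        ob = extract_orthobackbone(ml)
        oracle = orthobackbone_enumeration_oracle(ml)
        assert {sp: set(e) for sp, e in ob.edges.items()} == oracle


# --- edge statistics --------------------------------------------------------


def test_edge_jaccard_cases(caplog):
    assert edge_jaccard({("A", "B")}, {("B", "A")}) == 1.0
    assert edge_jaccard({("A", "B")}, {("C", "D")}) == 0.0
    assert edge_jaccard(
        {("A", "B"), ("B", "C")}, {("A", "B"), ("C", "D")}
    ) == pytest.approx(1 / 3)
    with caplog.at_level("WARNING"):
        assert edge_jaccard(set(), set()) == 0.0
    assert "empty" in caplog.text


def test_select_core_intersection_rule():
    edges = {("A", "B"), ("B", "C"), ("C", "D")}
    x = GeneSet("x", frozenset({"A", "B"}))
    y = GeneSet("y", frozenset({"A", "D"}))
    assert select_core(edges, x, y) == {("A", "B")}
    assert select_core(edges, x, GeneSet("y")) == set()


def test_select_core_one_each_mode():
    edges = {("A", "B"), ("B", "C")}
    x = GeneSet("x", frozenset({"A"}))
    y = GeneSet("y", frozenset({"B"}))
    assert select_core(edges, x, y, mode="one_each") == {("A", "B")}


def test_edge_disruption_enumerated():
    path = {("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")}
    assert edge_disruption(path, GeneSet("deg")).fraction == 0.0
    assert edge_disruption(
        path, GeneSet("deg", frozenset("ABCDE"))
    ).fraction == 1.0
    rep = edge_disruption(path, GeneSet("deg", frozenset({"B"})))
    assert rep.disrupted == 2 and rep.total == 4
    assert rep.fraction == pytest.approx(0.5)


def test_edge_disruption_empty_edges_errors():
    with pytest.raises(ValueError, match="empty"):
        edge_disruption(set(), GeneSet("deg"))


def test_edge_disruption_monotone_under_deg_inclusion(rng):
    nodes = [f"n{i}" for i in range(20)]
    edges = {
        (a, b)
        for a, b in (
            tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(40)
        )
    }
    prev = -1.0
    picked: set[str] = set()
    for n in nodes:
        picked.add(n)
        frac = edge_disruption(edges, GeneSet("deg", frozenset(picked))).fraction
        assert frac >= prev
        prev = frac


def test_compare_disruption_fisher():
    a = {("A", "B"), ("B", "C"), ("C", "D")}
    b = {("X", "Y"), ("Y", "Z")}
    odds, p = compare_disruption(a, b, GeneSet("deg", frozenset({"B"})))
    assert 0 < p <= 1
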