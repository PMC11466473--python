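import numpy as np
import pandas as pd
import pytest

from conftest import random_binary_tree_newick
from obkit.io import ExpressionMatrix, OrthogroupTable
from obkit.phylostrat import (
    assign_phylostrata,
    compare_conserved_fraction,
    conserved_fraction,
    rank_tree,
    read_phylostrata,
    tai,
    write_phylostrata,
)


def _expr(values: dict, groups: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values), groups)


# --- tree ranking -----------------------------------------------------------


def test_rank_tree_three_leaves():
    t = rank_tree("((A,B),C);", "A")
    assert t.n_ranks == 3
    assert t.path_leaf_sets == [
        frozenset({"A", "B", "C"}),
        frozenset({"A", "B"}),
        frozenset({"A"}),
    ]


def test_rank_tree_sixteen_strata_on_25_species_tree():
    # caterpillar backbone of 15 attachments below the root->focal path,
    # some of them two-leaf clades, for 25 leaves and a 16-rank path
    nest = "H"
    others = []
    for j in range(15):
        clade = f"(x{j},y{j})" if j < 9 else f"z{j}"
        others += [f"x{j}", f"y{j}"] if j < 9 else [f"z{j}"]
        nest = f"({nest},{clade})"
    t = rank_tree(nest + ";", "H")
    assert len(t.leaves) == 25
    assert t.n_ranks == 16


def test_rank_tree_missing_focal():
    with pytest.raises(ValueError, match="Z"):
        rank_tree("((A,B),C);", "Z")


def test_rank_tree_rejects_multifurcating_root():
    with pytest.raises(ValueError, match="root"):
        rank_tree("(A,B,C);", "A")


# --- phylostratum assignment ------------------------------------------------


def _og(**groups):
    return OrthogroupTable(
        {
            og_id: {sp: frozenset(genes) for sp, genes in by_sp.items()}
            for og_id, by_sp in groups.items()
        }
    )


def test_assign_basic_ranks():
    tree = rank_tree("((A,B),C);", "A")
    og = _og(
        OG1={"A": ["a1"], "C": ["c1"]},  # MRCA is the root
        OG2={"A": ["a2"]},  # species-specific
        OG3={"A": ["a3"], "B": ["b1"]},  # MRCA is (A,B)
    )
    ranks = assign_phylostrata(og, tree)
    assert ranks == {"a1": 1, "a2": 3, "a3": 2}


def test_assign_orphans_get_species_specific_rank():
    tree = rank_tree("((A,B),C);", "A")
    ranks = assign_phylostrata(_og(OG1={"A": ["a1"], "B": ["b1"]}), tree,
                               extra_focal_genes=["a1", "orphan"])
    assert ranks == {"a1": 2, "orphan": 3}


def test_assign_unknown_species_errors():
    tree = rank_tree("((A,B),C);", "A")
    with pytest.raises(ValueError, match="not in the tree"):
        assign_phylostrata(_og(OG1={"A": ["a1"], "Q": ["q1"]}), tree)


def test_assign_matches_exhaustive_mrca_oracle():
    """On random trees <= 12 leaves, the assigned rank equals the deepest
    ranked node whose leaf set contains all member species."""
    rng = np.random.default_rng(7)
    for _ in range(40):
        n_leaves = int(rng.integers(3, 13))
        leaves = [f"L{i}" for i in range(n_leaves)]
        newick, path = random_binary_tree_newick(rng, leaves)
        tree = rank_tree(newick, leaves[0])
        assert tree.path_leaf_sets == path
        groups = {}
        expected = {}
        for og_i in range(10):
            others = [
                lv for lv in leaves[1:] if rng.random() < 0.4
            ]
            members = {leaves[0]} | set(others)
            groups[f"OG{og_i}"] = {sp: frozenset({f"{sp}_g{og_i}"}) for sp in members}
            deepest = max(
                r for r, ls in enumerate(path, start=1) if members <= ls
            )
            expected[f"{leaves[0]}_g{og_i}"] = deepest
        ranks = assign_phylostrata(OrthogroupTable(groups), tree)
        assert ranks == expected


# --- TAI --------------------------------------------------------------------


def test_tai_all_rank_one_is_one():
    em = _expr({"s1": [5.0, 2.0]}, {"s1": "g"})
    em.values.index = ["a", "b"]
    res = tai(em, {"a": 1, "b": 1})
    assert res.per_sample["s1"] == pytest.approx(1.0)


def test_tai_hand_computed():
    em = _expr({"s1": [3.0, 1.0]}, {"s1": "g"})
    em.values.index = ["old", "young"]
    res = tai(em, {"old": 1, "young": 4}, cutoff=0.0)
    assert res.per_sample["s1"] == pytest.approx(1.75, abs=1e-12)
    assert res.contributions["g"].sum() == pytest.approx(1.0, abs=1e-9)


def test_tai_scale_invariant():
    genes = [f"g{i}" for i in range(6)]
    ranks = {g: i + 1 for i, g in enumerate(genes)}
    vals = pd.DataFrame({"s1": [3.0, 7, 2, 9, 4, 5]}, index=genes)
    a = tai(ExpressionMatrix(vals, {"s1": "g"}), ranks)
    b = tai(ExpressionMatrix(vals * 10, {"s1": "g"}), ranks)
    assert a.per_sample["s1"] == pytest.approx(b.per_sample["s1"], abs=1e-12)


def test_tai_monotone_in_rank():
    em = _expr({"s1": [3.0, 5.0]}, {"s1": "g"})
    em.values.index = ["a", "b"]
    lo = tai(em, {"a": 2, "b": 3}).per_sample["s1"]
    hi = tai(em, {"a": 5, "b": 3}).per_sample["s1"]
    assert hi > lo


def test_tai_empty_transcriptome_errors():
    em = _expr({"s1": [0.5, 0.2]}, {"s1": "g"})
    em.values.index = ["a", "b"]
    with pytest.raises(ValueError, match="empty transcriptome"):
        tai(em, {"a": 1, "b": 2})


def test_phylostrata_tsv_round_trip(tmp_path):
    ranks = {"a": 1, "b": 16}
    p = tmp_path / "ps.tsv"
    write_phylostrata(ranks, p)
    assert read_phylostrata(p) == ranks


# --- conserved fraction -----------------------------------------------------


def test_conserved_fraction_cases():
    genes = ["a", "b", "c", "d"]
    em = ExpressionMatrix(
        pd.DataFrame({"s1": [5.0, 5, 5, 5]}, index=genes), {"s1": "g"}
    )
    ranks = {"a": 1, "b": 3, "c": 9, "d": 12}
    assert conserved_fraction(em, ranks)["g"] == pytest.approx(0.5)
    assert conserved_fraction(em, {g: 3 for g in genes})["g"] == pytest.approx(1.0)
    assert conserved_fraction(em, ranks, old_ranks=frozenset())["g"] == 0.0


def test_conserved_fraction_monotone_in_old_ranks():
    genes = [f"g{i}" for i in range(10)]
    em = ExpressionMatrix(
        pd.DataFrame({"s1": [5.0] * 10}, index=genes), {"s1": "g"}
    )
    ranks = {g: i + 1 for i, g in enumerate(genes)}
    prev = 0.0
    for top in range(0, 11):
        f = conserved_fraction(em, ranks, old_ranks=frozenset(range(1, top + 1)))["g"]
        assert 0.0 <= f <= 1.0
        assert f >= prev
        prev = f


def test_compare_conserved_fraction_mann_whitney():
    genes = ["a", "b", "c", "d"]
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.uniform(2, 10, size=(4, 6)), index=genes,
        columns=[f"s{i}" for i in range(6)],
    )
    groups = {f"s{i}": ("x" if i < 3 else "y") for i in range(6)}
    ranks = {"a": 1, "b": 2, "c": 9, "d": 12}
    u, p = compare_conserved_fraction(
        ExpressionMatrix(vals, groups), ranks, "x", "y"
    )
    assert 0 <= u <= 9
    assert 0 < p <= 1
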