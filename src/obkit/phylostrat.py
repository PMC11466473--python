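"""Phylostratigraphy: ranked species trees, gene ages and transcriptome age.

A *phylostratum* is a node on the root-to-focal-species path of a rooted
species tree, ranked 1 (root, oldest) .. K (focal leaf, species-specific).
Each orthogroup is dated by the oldest clade it maps to: the most recent
common ancestor of all species with members.  Because the focal species
is always among them, that ancestor lies on the ranked path, and every
focal-species gene of the orthogroup inherits its rank.

The transcriptome age index (TAI) of a sample is the expression-weighted
mean rank of its expressed genes,

    TAI = sum_i rank_i * TPM_i / sum_i TPM_i ,

so higher values mean younger transcriptomes.  Genes are considered
expressed above a mean-TPM cutoff (default: mean TPM > 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, OrthogroupTable

__all__ = [
    "RankedSpeciesTree",
    "TaiResult",
    "rank_tree",
    "assign_phylostrata",
    "tai",
    "conserved_fraction",
    "compare_conserved_fraction",
    "write_phylostrata",
    "read_phylostrata",
]


@dataclass
class RankedSpeciesTree:
    """A rooted species tree with the root->focal path ranked 1..K.

    ``path_leaf_sets[r-1]`` is the leaf set of the rank-r node; rank 1 is
    the root (all leaves) and rank K the focal leaf itself.
    """

    newick: str
    focal_species: str
    path_leaf_sets: list[frozenset[str]]

    @property
    def n_ranks(self) -> int:
        return len(self.path_leaf_sets)

    @property
    def leaves(self) -> frozenset[str]:
        return self.path_leaf_sets[0]


@dataclass
class TaiResult:
    """Per-sample and per-group TAI plus per-rank contribution shares.

    ``contributions`` holds, per group, the share of the TAI numerator
    contributed by each rank; shares sum to 1 within a group.
    """

    per_sample: pd.Series
    per_group: pd.Series
    contributions: pd.DataFrame


def rank_tree(newick: str, focal_species: str) -> RankedSpeciesTree:
    """Rank the root->focal-leaf path of a rooted Newick tree 1..K.

    The root must be bifurcating (a basal multifurcation is taken as the
    signature of an unrooted tree and rejected).
    """
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    root = tree.seed_node
    n_children = len(root.child_nodes())
    if n_children != 2:
        raise ValueError(
            f"tree root has {n_children} children; a rooted, bifurcating "
            "root is required (unrooted/multifurcating-at-root input)"
        )
    focal_node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == focal_species:
            focal_node = leaf
            break
    if focal_node is None:
        raise ValueError(f"focal species {focal_species!r} is not a leaf of the tree")
    path = []
    node = focal_node
    while node is not None:
        path.append(node)
        node = node.parent_node
    path.reverse()  # root first
    leaf_sets = [
        frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
        )
        for node in path
    ]
    return RankedSpeciesTree(newick, focal_species, leaf_sets)


def assign_phylostrata(
    og: OrthogroupTable,
    tree: RankedSpeciesTree,
    extra_focal_genes: Iterable[str] | None = None,
) -> dict[str, int]:
    """Assign each focal-species gene the rank of its orthogroup's oldest clade.

    The rank is that of the deepest ranked node whose leaf set contains
    every species with members in the orthogroup (the MRCA restricted to
    the ranked path).  Genes passed via ``extra_focal_genes`` that belong
    to no orthogroup are treated as species-specific (rank K), matching
    the phylostratigraphic convention for orphan genes.
    """
    unknown = og.species() - set(tree.leaves)
    if unknown:
        raise ValueError(
            f"orthogroup table references species not in the tree: {sorted(unknown)}"
        )
    focal = tree.focal_species
    K = tree.n_ranks
    ranks: dict[str, int] = {}
    for og_id, by_species in og.groups.items():
        focal_genes = by_species.get(focal, frozenset())
        if not focal_genes:
            continue
        members = og.species_with_members(og_id)
        rank = 1
        for r in range(K, 0, -1):
            if members <= tree.path_leaf_sets[r - 1]:
                rank = r
                break
        for g in focal_genes:
            ranks[g] = rank
    if extra_focal_genes is not None:
        for g in extra_focal_genes:
            ranks.setdefault(g, K)
    return ranks


def _included_genes(
    expr: ExpressionMatrix, samples: Sequence[str], cutoff: float
) -> pd.Index:
    mean_tpm = expr.values[list(samples)].mean(axis=1)
    return expr.values.index[mean_tpm > cutoff]


def _require_ranks(genes: Iterable[str], ps: Mapping[str, int]) -> None:
    missing = [g for g in genes if g not in ps]
    if missing:
        raise ValueError(
            f"{len(missing)} expressed gene(s) have no phylostratum rank, "
            f"e.g. {missing[:5]}"
        )


def tai(
    expr: ExpressionMatrix,
    ps: Mapping[str, int],
    cutoff: float = 1.0,
) -> TaiResult:
    """Transcriptome age index per sample and per group.

    Genes are included per group when their arithmetic-mean TPM across
    the group's samples is strictly above ``cutoff``; every included
    gene must have a rank.  The group TAI is the mean of its samples'
    TAIs, and contribution shares split the group-mean TAI numerator by
    rank.
    """
    per_sample: dict[str, float] = {}
    per_group: dict[str, float] = {}
    contrib: dict[str, pd.Series] = {}
    for group in expr.group_labels():
        samples = expr.samples_of_group(group)
        genes = _included_genes(expr, samples, cutoff)
        if len(genes) == 0:
            raise ValueError(f"empty transcriptome for group {group!r}")
        _require_ranks(genes, ps)
        ranks = np.array([ps[g] for g in genes], dtype=float)
        for s in samples:
            tpm = expr.values.loc[genes, s].to_numpy(dtype=float)
            total = tpm.sum()
            if total <= 0:
                raise ValueError(f"empty transcriptome in sample {s!r}")
            per_sample[s] = float((ranks * tpm).sum() / total)
        mean_tpm = expr.values.loc[genes, samples].mean(axis=1).to_numpy(dtype=float)
        numerator = ranks * mean_tpm
        shares = (
            pd.Series(numerator, index=ranks.astype(int))
            .groupby(level=0)
            .sum()
        )
        contrib[group] = shares / numerator.sum()
        per_group[group] = float(np.mean([per_sample[s] for s in samples]))
    contributions = pd.DataFrame(contrib).fillna(0.0).sort_index()
    return TaiResult(
        per_sample=pd.Series(per_sample),
        per_group=pd.Series(per_group),
        contributions=contributions,
    )


def conserved_fraction(
    expr: ExpressionMatrix,
    ps: Mapping[str, int],
    old_ranks: frozenset[int] | set[int] = frozenset(range(1, 6)),
    cutoff: float = 1.0,
) -> pd.Series:
    """Per-group fraction of expressed genes mapping to the old phylostrata.

    A gene counts as expressed when its group-mean TPM is strictly above
    ``cutoff``; it counts as old when its rank lies in ``old_ranks``
    (default 1-5, the strata shared by all Metazoa in a 16-rank tree).
    """
    out: dict[str, float] = {}
    for group in expr.group_labels():
        samples = expr.samples_of_group(group)
        genes = _included_genes(expr, samples, cutoff)
        if len(genes) == 0:
            raise ValueError(f"empty transcriptome for group {group!r}")
        _require_ranks(genes, ps)
        n_old = sum(1 for g in genes if ps[g] in old_ranks)
        out[group] = n_old / len(genes)
    return pd.Series(out)


def per_sample_conserved_fraction(
    expr: ExpressionMatrix,
    ps: Mapping[str, int],
    old_ranks: frozenset[int] | set[int] = frozenset(range(1, 6)),
    cutoff: float = 1.0,
) -> pd.Series:
    """Fraction of per-sample-expressed genes (TPM > cutoff) with old ranks."""
    out: dict[str, float] = {}
    for s in expr.sample_ids:
        tpm = expr.values[s]
        genes = tpm.index[tpm > cutoff]
        if len(genes) == 0:
            raise ValueError(f"empty transcriptome in sample {s!r}")
        _require_ranks(genes, ps)
        out[s] = sum(1 for g in genes if ps[g] in old_ranks) / len(genes)
    return pd.Series(out)


def compare_conserved_fraction(
    expr: ExpressionMatrix,
    ps: Mapping[str, int],
    group_a: str,
    group_b: str,
    old_ranks: frozenset[int] | set[int] = frozenset(range(1, 6)),
    cutoff: float = 1.0,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-sample old-gene fractions of two groups."""
    frac = per_sample_conserved_fraction(expr, ps, old_ranks, cutoff)
    a = [frac[s] for s in expr.samples_of_group(group_a)]
    b = [frac[s] for s in expr.samples_of_group(group_b)]
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def write_phylostrata(ps: Mapping[str, int], path) -> None:
    from .io import _open_out

    with _open_out(path) as fh:
        fh.write("gene_id\trank\n")
        for g in sorted(ps):
            fh.write(f"{g}\t{ps[g]}\n")


def read_phylostrata(path) -> dict[str, int]:
    from .io import _data_rows

    out: dict[str, int] = {}
    first = True
    for parts in _data_rows(path, min_cols=2):
        if first:
            first = False
            if not parts[1].lstrip("-").isdigit():
                continue  # header
        out[parts[0]] = int(parts[1])
    return out
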