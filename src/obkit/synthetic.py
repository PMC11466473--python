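"""Synthetic multilayer networks with a planted conserved core.

The generator emulates the statistical structure the pipeline assumes:

* several species layers with one-to-many orthology (a conserved gene
  may have two paralogous copies in a layer);
* a planted conserved core whose genes are present in every layer, whose
  expected degree is ``degree_multiplier`` times the background mean
  degree, and whose core-core interactions are *shared* across layers
  (interologs), so a non-trivial orthoBackbone exists;
* edge confidence scores drawn from a Beta distribution on (0, 1];
* a ranked species tree (caterpillar topology) with the focal species
  innermost, old planted ranks for conserved genes and species-specific
  or intermediate ranks for the rest;
* expression matrices with a planted age-stage trend (the expression
  share of young genes grows across stages), and DEG sets with an
  optional bias towards the conserved core.

Each layer is a Chung-Lu-style expected-degree random graph: pair
(i, j) is an edge with probability ``w_i * w_j / sum(w)`` (capped at 1),
where ``w`` is the target expected degree.  Conserved-conserved pairs
are drawn once from a shared ancestral adjacency and replicated in every
layer through the ortholog map; all remaining pairs are drawn
independently per layer.  With ``degree_multiplier == 1`` conserved and
background nodes are therefore statistically indistinguishable.

One global seed drives per-component child generators (seeded as
``(seed, component-tag)``), so any stage is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .backbone import to_distance
from .io import GeneSet, OrthogroupTable
from .netbuild import Layer

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_multilayer",
    "simulate_expression",
    "simulate_deg",
]

# component tags for child RNGs
_TAG_CORE, _TAG_LAYER, _TAG_EXPR, _TAG_DEG, _TAG_RANKS = 1, 2, 3, 4, 5


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic multilayer generator.

    Defaults emulate, at desk scale, a three-species spermatocyte
    network: three layers of 2000 genes, about half of them deeply
    conserved, a conserved core three times as connected as background,
    occasional paralogs, Beta(4, 2) confidence scores (most mass above
    the 0.5 confidence threshold), a 16-rank species tree with conserved
    genes planted in the oldest five strata, a positive age-stage
    expression trend and a 20% DEG fraction.
    """

    n_layers: int = 3
    genes_per_layer: int = 2000
    conserved_fraction: float = 0.5
    degree_multiplier: float = 3.0
    paralog_rate: float = 0.2
    score_beta: tuple[float, float] = (4.0, 2.0)
    mean_degree: float = 20.0
    n_ranks: int = 16
    old_rank_max: int = 5
    stages: tuple[str, ...] = ("spermatogonia", "spermatocytes", "spermatids")
    samples_per_stage: int = 3
    stage_age_slope: float = 0.5
    deg_fraction: float = 0.2
    deg_bias_to_core: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.genes_per_layer < 2:
            raise ValueError("need at least 1 layer and 2 genes per layer")
        if not (0 < self.conserved_fraction <= 1):
            raise ValueError("conserved_fraction must lie in (0, 1]")
        if self.degree_multiplier < 1:
            raise ValueError("degree_multiplier must be >= 1")
        if not (0 <= self.paralog_rate <= 1):
            raise ValueError("paralog_rate must lie in [0, 1]")
        if not (0 <= self.deg_fraction <= 1):
            raise ValueError("deg_fraction must lie in [0, 1]")
        if self.mean_degree * self.degree_multiplier >= self.genes_per_layer - 1:
            raise ValueError(
                "infeasible degree demand: mean_degree * degree_multiplier "
                "must be below genes_per_layer - 1"
            )
        if self.n_ranks < self.n_layers + 1 or self.old_rank_max >= self.n_ranks:
            raise ValueError("n_ranks must exceed both n_layers and old_rank_max")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_layers)]

    @property
    def focal_species(self) -> str:
        return "sp1"


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the synthetic data."""

    config: SimulationConfig
    tree_newick: str
    conserved: dict[str, dict[str, bool]]  # species -> gene -> flag
    orthogroup_of: dict[str, dict[str, str]]  # species -> gene -> og id
    ranks: dict[str, int]  # focal gene -> planted phylostratum rank
    planted_edges: dict[str, list[tuple[str, str, float]]]

    @property
    def focal_species(self) -> str:
        return self.config.focal_species

    def focal_genes(self) -> list[str]:
        return sorted(self.conserved[self.focal_species])

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "tree_newick": self.tree_newick,
            "conserved": {
                sp: dict(sorted(d.items())) for sp, d in sorted(self.conserved.items())
            },
            "orthogroup_of": {
                sp: dict(sorted(d.items()))
                for sp, d in sorted(self.orthogroup_of.items())
            },
            "ranks": dict(sorted(self.ranks.items())),
            "planted_edges": {
                sp: sorted(edges) for sp, edges in sorted(self.planted_edges.items())
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _species_tree(cfg: SimulationConfig) -> tuple[str, list[str]]:
    """Caterpillar tree whose root->focal path has exactly n_ranks nodes.

    ``taxa[j]`` (j >= 2) joins the path at rank ``n_ranks - j + 1``; the
    first ``n_layers`` taxa are the species layers, the rest outgroups.
    """
    taxa = [None, cfg.focal_species]  # 1-based addressing
    for j in range(2, cfg.n_ranks + 1):
        if j <= cfg.n_layers:
            taxa.append(f"sp{j}")
        else:
            taxa.append(f"out{j}")
    nest = cfg.focal_species
    for j in range(2, cfg.n_ranks + 1):
        nest = f"({nest},{taxa[j]})"
    return nest + ";", taxa  # type: ignore[return-value]


def _rank_to_taxon(cfg: SimulationConfig, taxa: list[str], rank: int) -> str:
    """The taxon whose MRCA with the focal leaf sits at the given rank (< K)."""
    return taxa[cfg.n_ranks - rank + 1]


def _sample_scores(rng: np.random.Generator, size: int, ab: tuple[float, float]):
    s = rng.beta(ab[0], ab[1], size=size)
    return np.clip(s, 1e-9, 1.0)


def simulate_multilayer(
    cfg: SimulationConfig,
) -> tuple[dict[str, Layer], OrthogroupTable, GroundTruth]:
    """Generate species layers, an orthogroup table and the ground truth."""
    species = cfg.species
    n = cfg.genes_per_layer
    n_cons = int(round(cfg.conserved_fraction * n))
    w_c = cfg.mean_degree * cfg.degree_multiplier
    w_b = cfg.mean_degree
    S = n_cons * w_c + (n - n_cons) * w_b

    tree_newick, taxa = _species_tree(cfg)
    rng_core = np.random.default_rng([cfg.seed, _TAG_CORE])
    rng_ranks = np.random.default_rng([cfg.seed, _TAG_RANKS])

    # --- orthogroups and planted ranks -----------------------------------
    og_groups: dict[str, dict[str, frozenset[str]]] = {}
    copies: dict[str, dict[int, list[str]]] = {sp: {} for sp in species}
    conserved: dict[str, dict[str, bool]] = {sp: {} for sp in species}
    og_of: dict[str, dict[str, str]] = {sp: {} for sp in species}
    ranks: dict[str, int] = {}

    for i in range(n_cons):
        og_id = f"OG{i:05d}"
        rank = int(rng_ranks.integers(1, cfg.old_rank_max + 1))
        by_species: dict[str, frozenset[str]] = {}
        for sp in species:
            n_copies = 2 if rng_core.random() < cfg.paralog_rate else 1
            genes = [
                f"{sp}_C{i:05d}" + ("" if c == 0 else f"p{c}")
                for c in range(n_copies)
            ]
            copies[sp][i] = genes
            by_species[sp] = frozenset(genes)
            for g in genes:
                conserved[sp][g] = True
                og_of[sp][g] = og_id
        # pin the planted age with a dummy member in the matching outgroup
        if rank < cfg.n_ranks - cfg.n_layers + 1:
            anchor = _rank_to_taxon(cfg, taxa, rank)
            by_species[anchor] = frozenset({f"{anchor}_{og_id}"})
        og_groups[og_id] = by_species
        for g in copies[cfg.focal_species][i]:
            ranks[g] = rank

    # background genes: species-specific per layer; focal background genes
    # get either an orphan rank (K) or an intermediate-age orthogroup
    bg_genes: dict[str, list[str]] = {}
    next_og = n_cons
    for sp in species:
        n_bg = n - n_cons
        genes = [f"{sp}_B{j:05d}" for j in range(n_bg)]
        bg_genes[sp] = genes
        for g in genes:
            conserved[sp][g] = False
        if sp != cfg.focal_species:
            continue
        for g in genes:
            if rng_ranks.random() < 0.5:
                ranks[g] = cfg.n_ranks  # orphan, no orthogroup
                continue
            rank = int(
                rng_ranks.integers(cfg.old_rank_max + 1, cfg.n_ranks + 1)
            )
            ranks[g] = rank
            og_id = f"OG{next_og:05d}"
            next_og += 1
            by_species = {sp: frozenset({g})}
            if rank < cfg.n_ranks:
                anchor = _rank_to_taxon(cfg, taxa, rank)
                by_species[anchor] = frozenset({f"{anchor}_{og_id}"})
            og_groups[og_id] = by_species
            og_of[sp][g] = og_id
    og_table = OrthogroupTable(og_groups)

    # --- shared ancestral core adjacency (between primary copies) --------
    p_core = min(1.0, w_c * w_c / S)
    tri = np.triu_indices(n_cons, k=1)
    core_mask = rng_core.random(tri[0].shape[0]) < p_core
    core_pairs = list(zip(tri[0][core_mask], tri[1][core_mask]))

    # --- per-layer graphs -------------------------------------------------
    # Node order: primary conserved copies, secondary (paralog) copies,
    # background.  Primary-primary pairs replicate the shared ancestral
    # adjacency; every other pair is drawn independently per layer with
    # the same Chung-Lu probability w_i * w_j / S, so at
    # degree_multiplier == 1 all nodes are statistically exchangeable.
    layers: dict[str, Layer] = {}
    planted: dict[str, list[tuple[str, str, float]]] = {}
    for li, sp in enumerate(species):
        rng = np.random.default_rng([cfg.seed, _TAG_LAYER, li])
        nodes: list[str] = [copies[sp][i][0] for i in range(n_cons)]
        weights: list[float] = [w_c] * n_cons
        for i in range(n_cons):
            for g in copies[sp][i][1:]:
                nodes.append(g)
                weights.append(w_c)
        nodes.extend(bg_genes[sp])
        weights.extend([w_b] * len(bg_genes[sp]))
        G = nx.Graph()
        G.add_nodes_from(nodes)
        edges: set[tuple[str, str]] = set()
        # shared core edges between the layers' primary copies
        for i, j in core_pairs:
            a, b = copies[sp][i][0], copies[sp][j][0]
            edges.add((a, b) if a <= b else (b, a))
        # independent draws for all pairs except primary-primary
        n_tot = len(nodes)
        w = np.asarray(weights)
        prob = np.minimum(1.0, np.outer(w, w) / S)
        draw = rng.random((n_tot, n_tot))
        adj = draw < prob
        iu = np.triu_indices(n_tot, k=1)
        sel = adj[iu]
        pp = (iu[0] < n_cons) & (iu[1] < n_cons)
        sel = sel & ~pp  # primary-primary pairs come from the shared core
        for a_idx, b_idx in zip(iu[0][sel], iu[1][sel]):
            a, b = nodes[a_idx], nodes[b_idx]
            edges.add((a, b) if a <= b else (b, a))
        scores = _sample_scores(rng, len(edges), cfg.score_beta)
        edge_list = sorted(edges)
        for (a, b), s in zip(edge_list, scores):
            G.add_edge(a, b, score=float(s), distance=to_distance(float(s)))
        for g in nodes:
            G.nodes[g]["conserved"] = conserved[sp][g]
        layers[sp] = Layer(sp, G)
        planted[sp] = [
            (a, b, float(G.edges[a, b]["score"])) for a, b in edge_list
        ]

    truth = GroundTruth(
        config=cfg,
        tree_newick=tree_newick,
        conserved=conserved,
        orthogroup_of=og_of,
        ranks=ranks,
        planted_edges=planted,
    )
    return layers, og_table, truth


def simulate_expression(
    truth: GroundTruth,
    stages: tuple[str, ...] | None = None,
    seed: int | None = None,
):
    """TPM matrix for the focal layer with a planted age-stage trend.

    Baseline expression is log-normal; at stage index ``s`` gene ``i`` is
    scaled by ``exp(slope * s * z_i)`` with ``z_i`` the gene's centred,
    K-normalized rank, so the expression share of young (high-rank)
    genes — and hence the TAI — increases stage by stage when the slope
    is positive.
    """
    from .io import ExpressionMatrix

    cfg = truth.config
    if stages is None:
        stages = cfg.stages
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng([seed, _TAG_EXPR])
    genes = truth.focal_genes()
    K = cfg.n_ranks
    z = np.array([(truth.ranks[g] - (K + 1) / 2) / K for g in genes])
    base = rng.lognormal(mean=np.log(5.0), sigma=1.2, size=len(genes))
    values: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for s_idx, stage in enumerate(stages):
        trend = np.exp(cfg.stage_age_slope * s_idx * z)
        for r in range(cfg.samples_per_stage):
            noise = rng.lognormal(mean=0.0, sigma=0.3, size=len(genes))
            sample = f"{stage}_{r + 1}"
            values[sample] = base * trend * noise
            groups[sample] = stage
    import pandas as pd

    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(df, groups)


def simulate_deg(
    truth: GroundTruth,
    deg_fraction: float | None = None,
    bias_to_core: float = 1.0,
    seed: int | None = None,
) -> GeneSet:
    """Sample a DEG set from the focal layer's genes.

    ``bias_to_core > 1`` oversamples conserved genes with that odds
    ratio; at 1 the draw is uniform.
    """
    cfg = truth.config
    if deg_fraction is None:
        deg_fraction = cfg.deg_fraction
    if not (0 <= deg_fraction <= 1):
        raise ValueError("deg_fraction must lie in [0, 1]")
    if bias_to_core <= 0:
        raise ValueError("bias_to_core must be positive")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng([seed, _TAG_DEG])
    genes = truth.focal_genes()
    k = int(round(deg_fraction * len(genes)))
    if k == 0:
        return GeneSet("deg", frozenset())
    flags = truth.conserved[truth.focal_species]
    w = np.array([bias_to_core if flags[g] else 1.0 for g in genes])
    picked = rng.choice(len(genes), size=k, replace=False, p=w / w.sum())
    return GeneSet("deg", frozenset(genes[i] for i in picked))
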