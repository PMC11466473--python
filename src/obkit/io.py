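"""Readers and writers for the tabular formats the pipeline consumes.

All tables are UTF-8 and tab-delimited.  Writers prepend a single
comment line naming the tool version; readers skip ``#`` comment lines.
Gene identifiers are opaque, case-sensitive strings: no mapping between
Ensembl/FlyBase/MGI namespaces is attempted — identifier reconciliation
is an upstream concern.

Formats
-------
* expression: header row of sample ids, first column gene ids, TPM values
* edges: three whitespace-separated columns ``gene_a gene_b score``
  (STRING-style; scores on the 0-1000 or 0-1 scale)
* orthogroups: OrthoFinder ``Orthogroups.tsv`` dialect — first column
  the orthogroup id, one column per species, comma-separated gene lists
* gene sets: one gene id per line (first column)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from ._version import __version__

logger = logging.getLogger(__name__)

_HEADER_COMMENT = f"# obkit v{__version__}"


class EdgeRecord(NamedTuple):
    """One undirected weighted interaction, score on the unit scale."""

    gene_a: str
    gene_b: str
    score: float


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix with a group (cell type / stage) label per sample.

    ``values`` is genes as rows, samples as columns; all entries are
    non-negative reals.  ``groups`` maps every sample id to exactly one
    group label.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dups}")
        if (self.values.values < 0).any():
            stacked = self.values.stack()
            bad = stacked[stacked < 0].index[0]
            raise ValueError(
                f"negative TPM at gene {bad[0]!r}, sample {bad[1]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_group(self, group: str) -> list[str]:
        out = [s for s in self.values.columns if self.groups[s] == group]
        if not out:
            raise ValueError(f"unknown group {group!r}")
        return out

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)


@dataclass
class OrthogroupTable:
    """Orthogroup id -> {species id -> set of gene ids}.

    Within one species a gene belongs to at most one orthogroup.
    """

    groups: dict[str, dict[str, frozenset[str]]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for og_id, by_species in self.groups.items():
            for sp, genes in by_species.items():
                for g in genes:
                    prev = seen.get((sp, g))
                    if prev is not None and prev != og_id:
                        raise ValueError(
                            f"gene {g!r} of species {sp!r} appears in both "
                            f"{prev!r} and {og_id!r}"
                        )
                    seen[(sp, g)] = og_id

    def species(self) -> set[str]:
        out: set[str] = set()
        for by_species in self.groups.values():
            out.update(by_species)
        return out

    def gene_to_group(self, species: str) -> dict[str, str]:
        """Map every gene of one species to its orthogroup id."""
        out: dict[str, str] = {}
        for og_id, by_species in self.groups.items():
            for g in by_species.get(species, ()):
                out[g] = og_id
        return out

    def members(self, og_id: str, species: str) -> frozenset[str]:
        return self.groups.get(og_id, {}).get(species, frozenset())

    def species_with_members(self, og_id: str) -> set[str]:
        return {sp for sp, genes in self.groups.get(og_id, {}).items() if genes}


@dataclass
class GeneSet:
    label: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# readers


def read_expression(
    path: str | Path, group_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a gene x sample TPM table and attach group labels.

    Raises on negative values (naming the offending cell), on
    non-numeric entries and on duplicate gene ids.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    parsed = df.apply(pd.to_numeric, errors="coerce")
    bad_mask = parsed.isna() & df.notna()
    if bad_mask.any().any():
        stacked = bad_mask.stack()
        gene, sample = stacked[stacked].index[0]
        raise ValueError(
            f"non-numeric TPM {df.loc[gene, sample]!r} at gene {gene!r}, "
            f"sample {sample!r}"
        )
    return ExpressionMatrix(parsed.astype(float), dict(group_map))


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>group`` table."""
    out: dict[str, str] = {}
    for parts in _data_rows(path, min_cols=2):
        out[parts[0]] = parts[1]
    return out


def _data_rows(path: str | Path, min_cols: int) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected at least {min_cols} columns, "
                    f"got {len(parts)}"
                )
            yield parts


def read_edges(path: str | Path, score_scale: str = "auto") -> list[EdgeRecord]:
    """Read a three-column edge table and normalize scores to (0, 1].

    ``score_scale``:
      * ``"unit"`` — scores already in (0, 1]
      * ``"thousand"`` — STRING convention, divide by 1000
      * ``"auto"`` — choose ``"thousand"`` iff any score exceeds 1

    Self-edges are dropped (logged); duplicate undirected pairs collapse
    to the maximum score.  The returned list is sorted, so it is
    insensitive to the input row order.
    """
    if score_scale not in ("auto", "unit", "thousand"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    raw: list[tuple[str, str, float]] = []
    first = True
    for parts in _data_rows(path, min_cols=3):
        if first:
            first = False
            try:
                float(parts[2])
            except ValueError:
                continue  # header row (e.g. "protein1 protein2 combined_score")
        a, b, s = parts[0], parts[1], float(parts[2])
        if s <= 0:
            raise ValueError(f"non-positive score {s} on edge {a!r}-{b!r}")
        raw.append((a, b, s))
    scale = score_scale
    if scale == "auto":
        scale = "thousand" if any(s > 1 for _, _, s in raw) else "unit"
    divisor = 1000.0 if scale == "thousand" else 1.0
    n_self = 0
    best: dict[tuple[str, str], float] = {}
    for a, b, s in raw:
        s /= divisor
        if s > 1:
            raise ValueError(
                f"score {s} on edge {a!r}-{b!r} exceeds 1 after normalization"
            )
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        if s > best.get(key, 0.0):
            best[key] = s
    if n_self:
        logger.info("read_edges: dropped %d self-edge row(s) from %s", n_self, path)
    return [EdgeRecord(a, b, s) for (a, b), s in sorted(best.items())]


def read_orthogroups(
    path: str | Path, species_ids: Sequence[str] | None = None
) -> OrthogroupTable:
    """Read an OrthoFinder ``Orthogroups.tsv``-style table.

    The first row is the header (orthogroup-id column followed by one
    column per species).  Species columns are matched to ``species_ids``
    by name when possible, otherwise positionally; when ``species_ids``
    is None the header names are used as-is.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    cols = list(df.columns)[1:]
    if species_ids is None:
        species_ids = cols
    if set(species_ids) <= set(cols):
        col_of = {sp: sp for sp in species_ids}
    elif len(cols) == len(species_ids):
        col_of = dict(zip(species_ids, cols))
    else:
        raise ValueError(
            f"cannot match species {list(species_ids)} to columns {cols}"
        )
    groups: dict[str, dict[str, frozenset[str]]] = {}
    for _, row in df.iterrows():
        og_id = str(row.iloc[0])
        by_species: dict[str, frozenset[str]] = {}
        for sp in species_ids:
            cell = str(row[col_of[sp]]).strip()
            genes = frozenset(
                g.strip() for g in cell.split(",") if g.strip()
            ) if cell else frozenset()
            by_species[sp] = genes
        groups[og_id] = by_species
    return OrthogroupTable(groups)


def read_gene_set(path: str | Path, label: str) -> GeneSet:
    """Read one gene id per line (first column); ids are whitespace-trimmed."""
    members: set[str] = set()
    for parts in _data_rows(path, min_cols=1):
        members.add(parts[0])
    if not members:
        logger.warning("read_gene_set: %s is empty", path)
    return GeneSet(label, frozenset(members))


# ---------------------------------------------------------------------------
# writers


def _open_out(path: str | Path):
    fh = open(path, "w", encoding="utf-8")
    fh.write(_HEADER_COMMENT + "\n")
    return fh


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    with _open_out(path) as fh:
        em.values.to_csv(fh, sep="\t", index_label="gene_id")


def write_group_map(groups: Mapping[str, str], path: str | Path) -> None:
    with _open_out(path) as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def write_edges(records: Iterable[EdgeRecord], path: str | Path) -> None:
    with _open_out(path) as fh:
        for r in sorted(records):
            fh.write(f"{r.gene_a}\t{r.gene_b}\t{r.score:.17g}\n")


def write_orthogroups(
    table: OrthogroupTable, path: str | Path, species_ids: Sequence[str]
) -> None:
    with _open_out(path) as fh:
        fh.write("Orthogroup\t" + "\t".join(species_ids) + "\n")
        for og_id in sorted(table.groups):
            cells = [
                ",".join(sorted(table.members(og_id, sp))) for sp in species_ids
            ]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with _open_out(path) as fh:
        for g in sorted(gs.members):
            fh.write(g + "\n")
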