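"""Per-ortholog alignments, supermatrix assembly and locus jackknifing.

After orthology inference each ortholog's rows are pulled out of the
homolog alignment, relabelled by taxon, column-trimmed by occupancy,
length/occupancy filtered, and concatenated into a partitioned
supermatrix.  Among-locus conflict is assessed by jackknife replicates
that resample whole loci (columns within a locus are never split) and
by bipartition support of a reference topology across replicate trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .seqio import Alignment, SequenceRecord, TaxonNameScheme, DEFAULT_SCHEME, _open_text
from .tree import Tree

__all__ = [
    "Locus",
    "Supermatrix",
    "JackknifeScheme",
    "extract_ortholog_alignment",
    "trim_columns_by_occupancy",
    "filter_loci",
    "concatenate",
    "occupancy_stats",
    "jackknife_by_locus",
    "bipartition_support",
    "write_phylip",
    "write_partitions",
]

# a cell is "occupied" unless it is a gap or a full unknown
_UNOCCUPIED = {"-", "?"}


def _occupied(ch: str) -> bool:
    return ch not in _UNOCCUPIED


@dataclass
class Locus:
    """One ortholog's trimmed alignment, rows keyed by taxon."""

    locus_id: str
    alignment: Alignment
    char_type: str = "aa"  # "aa" | "nt"

    def __post_init__(self) -> None:
        if self.char_type not in ("aa", "nt"):
            raise ValueError(f"char_type must be 'aa' or 'nt', got {self.char_type!r}")

    @property
    def taxa(self) -> set[str]:
        return set(self.alignment.ids())

    @property
    def length(self) -> int:
        return self.alignment.n_columns


@dataclass
class Supermatrix:
    """Concatenated loci: one row per taxon, 1-based partition table."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (locus_id, start, end) inclusive
    char_type: str

    def __post_init__(self) -> None:
        total = self.n_columns
        expect = 1
        for locus_id, start, end in self.partitions:
            if start != expect or end < start:
                raise ValueError(
                    f"partition {locus_id} = {start}-{end} breaks contiguity "
                    f"(expected start {expect})"
                )
            expect = end + 1
        if self.partitions and expect != total + 1:
            raise ValueError("partitions do not cover the matrix")
        for taxon in self.taxa:
            if len(self.rows[taxon]) != total:
                raise ValueError(f"row {taxon} has wrong length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.taxa[0]]) if self.taxa else 0


@dataclass(frozen=True)
class JackknifeScheme:
    """Locus-intact resampling design.

    ``proportion`` mode keeps round(value * n_loci) loci per replicate
    (round half up), ``count`` mode exactly ``value`` loci; sampling is
    without replacement within a replicate.
    """

    mode: str  # "proportion" | "count"
    value: float
    replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("proportion", "count"):
            raise ValueError(f"unknown jackknife mode {self.mode!r}")
        if self.mode == "proportion" and not (0 < self.value <= 1):
            raise ValueError("proportion must be in (0, 1]")
        if self.mode == "count" and (self.value < 1 or self.value != int(self.value)):
            raise ValueError("count must be a positive integer")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def sample_size(self, n_loci: int) -> int:
        if self.mode == "proportion":
            k = math.floor(self.value * n_loci + 0.5)  # round half up
            if k < 1:
                raise ValueError(
                    f"proportion {self.value} of {n_loci} loci is below one locus"
                )
            return k
        k = int(self.value)
        if k > n_loci:
            raise ValueError(f"cannot draw {k} loci from {n_loci}")
        return k


# ---------------------------------------------------------------------------
# Locus construction and filtering
# ---------------------------------------------------------------------------


def extract_ortholog_alignment(
    homolog_alignment: Alignment,
    ortholog_tips: Iterable[str],
    locus_id: str,
    char_type: str = "aa",
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
) -> Locus:
    """Pull the ortholog's rows from the homolog alignment.

    Rows are relabelled by taxon and columns that became gap-only in
    the kept rows are removed.  A duplicate taxon after relabelling
    means the ortholog invariant was violated upstream.
    """
    sub = homolog_alignment.subset(ortholog_tips)
    relabelled = []
    seen: set[str] = set()
    for rec in sub:
        taxon = scheme.taxon_of(rec.identifier)
        if taxon in seen:
            raise ValueError(
                f"ortholog {locus_id}: taxon {taxon!r} appears twice"
            )
        seen.add(taxon)
        relabelled.append(SequenceRecord(taxon, rec.residues, rec.alphabet))
    rows = [r.residues for r in relabelled]
    keep_cols = [
        j for j in range(len(rows[0])) if any(_occupied(row[j]) for row in rows)
    ] if rows else []
    cleaned = [
        SequenceRecord(r.identifier, "".join(r.residues[j] for j in keep_cols), r.alphabet)
        for r in relabelled
    ]
    return Locus(locus_id, Alignment(cleaned), char_type)


def trim_columns_by_occupancy(locus: Locus, min_fraction: float) -> Locus:
    """Drop columns whose occupied fraction falls below ``min_fraction``.

    Occupied means neither gap nor ``?``; ambiguity codes count as
    occupied.  Mirrors the behaviour of column cleaners used on the
    published datasets (occupancy thresholds 0.1 for homolog
    alignments, 0.3 for ortholog alignments).
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    rows = [r.residues for r in locus.alignment]
    if not rows:
        return locus
    n_rows = len(rows)
    keep = [
        j
        for j in range(len(rows[0]))
        if sum(_occupied(row[j]) for row in rows) / n_rows >= min_fraction
    ]
    cleaned = [
        SequenceRecord(r.identifier, "".join(r.residues[j] for j in keep), r.alphabet)
        for r in locus.alignment
    ]
    return Locus(locus.locus_id, Alignment(cleaned), locus.char_type)


def filter_loci(
    loci: Iterable[Locus],
    min_length: int,
    max_missing_taxa: int,
    full_taxa: Iterable[str],
) -> list[Locus]:
    """Keep loci long enough and with few enough missing taxa.

    Published settings: at least 100 aa (or 300 nt) of trimmed length;
    at most one missing taxon, or none for full-occupancy matrices.
    """
    full = set(full_taxa)
    out = []
    for locus in loci:
        if locus.length < min_length:
            continue
        if len(full - locus.taxa) > max_missing_taxa:
            continue
        out.append(locus)
    return out


# ---------------------------------------------------------------------------
# Concatenation and occupancy
# ---------------------------------------------------------------------------


def concatenate(loci: Sequence[Locus], full_taxa: Iterable[str]) -> Supermatrix:
    """Concatenate loci (sorted by id) into a gap-padded supermatrix."""
    loci = sorted(loci, key=lambda l: l.locus_id)
    if not loci:
        raise ValueError("nothing to concatenate")
    char_types = {l.char_type for l in loci}
    if len(char_types) > 1:
        raise ValueError(f"mixed character types {sorted(char_types)}")
    taxa = sorted(set(full_taxa) | set().union(*(l.taxa for l in loci)))
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    col = 1
    for locus in loci:
        width = locus.length
        parts.append((locus.locus_id, col, col + width - 1))
        col += width
        for taxon in taxa:
            if taxon in locus.alignment:
                chunks[taxon].append(locus.alignment[taxon].residues)
            else:
                chunks[taxon].append("-" * width)
    rows = {t: "".join(chunks[t]) for t in taxa}
    return Supermatrix(taxa, rows, parts, char_types.pop())


def occupancy_stats(matrix: Supermatrix) -> dict:
    """Overall and per-taxon occupancy, plus per-locus taxon counts.

    Occupancy is the fraction of cells that are neither gap nor ``?``.
    The per-locus taxon counts, sorted descending, are the data behind
    ranked taxon-occupancy curves.
    """
    total = len(matrix.taxa) * matrix.n_columns
    per_taxon = {
        t: sum(_occupied(c) for c in matrix.rows[t]) / matrix.n_columns
        for t in matrix.taxa
    }
    occupied = sum(per_taxon[t] * matrix.n_columns for t in matrix.taxa)
    per_locus = {}
    for locus_id, start, end in matrix.partitions:
        per_locus[locus_id] = sum(
            any(_occupied(c) for c in matrix.rows[t][start - 1 : end])
            for t in matrix.taxa
        )
    curve = sorted(per_locus.values(), reverse=True)
    return {
        "overall": occupied / total if total else 0.0,
        "per_taxon": per_taxon,
        "per_locus_taxa": per_locus,
        "occupancy_curve": curve,
    }


# ---------------------------------------------------------------------------
# Jackknife and bipartition support
# ---------------------------------------------------------------------------


def jackknife_by_locus(
    locus_ids: Sequence[str], scheme: JackknifeScheme
) -> list[list[str]]:
    """Seeded locus-intact jackknife; returns one sorted id list per replicate."""
    ids = list(locus_ids)
    k = scheme.sample_size(len(ids))
    rng = np.random.default_rng(scheme.seed)
    manifests = []
    for _ in range(scheme.replicates):
        chosen = rng.choice(len(ids), size=k, replace=False)
        manifests.append(sorted(ids[i] for i in chosen))
    return manifests


def _splits(tree: Tree, taxa: frozenset[str]) -> set[frozenset]:
    """Nontrivial unordered bipartitions of ``taxa`` induced by tree edges."""
    out: set[frozenset] = set()
    memo: dict[int, frozenset[str]] = {}
    for node in tree.root.iter_postorder():
        if node.is_tip:
            memo[id(node)] = frozenset([node.label]) & taxa
        else:
            memo[id(node)] = frozenset().union(*(memo[id(c)] for c in node.children))
        if node.parent is not None:
            side = memo[id(node)]
            other = taxa - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset((side, other)))
    return out


def bipartition_support(
    reference: Tree, replicates: Sequence[Tree]
) -> Tree:
    """Annotate reference internal edges with replicate support percentages.

    Each internal edge's label becomes the percentage of replicate
    trees containing the same unordered bipartition of the shared
    taxon set.  Replicates on supersets are restricted to the
    reference's taxa.
    """
    if len(replicates) < 1:
        raise ValueError("need at least one replicate tree")
    ref = reference.copy()
    taxa = frozenset(ref.tip_labels())
    rep_splits = [_splits(r, taxa) for r in replicates]
    n = len(replicates)

    memo: dict[int, frozenset[str]] = {}
    for node in ref.root.iter_postorder():
        if node.is_tip:
            memo[id(node)] = frozenset([node.label])
            continue
        memo[id(node)] = frozenset().union(*(memo[id(c)] for c in node.children))
        if node.parent is None:
            continue
        side = memo[id(node)]
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        split = frozenset((side, other))
        support = 100.0 * sum(split in s for s in rep_splits) / n
        node.label = f"{support:g}"
    return ref


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_phylip(matrix: Supermatrix, path: Union[str, Path]) -> None:
    """Relaxed PHYLIP: names of any length, two-space separator."""
    with _open_text(path, "wt") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.n_columns}\n")
        for taxon in matrix.taxa:
            fh.write(f"{taxon}  {matrix.rows[taxon]}\n")


def write_supermatrix_fasta(matrix: Supermatrix, path: Union[str, Path]) -> None:
    from .seqio import write_fasta

    write_fasta(
        [SequenceRecord(t, matrix.rows[t], matrix.char_type) for t in matrix.taxa],
        path,
    )


def write_partitions(
    matrix: Supermatrix,
    path: Union[str, Path],
    model: Optional[str] = None,
) -> None:
    """RAxML-style partition lines: ``MODEL, locus = start-end``."""
    if model is None:
        model = "WAG" if matrix.char_type == "aa" else "DNA"
    with _open_text(path, "wt") as fh:
        for locus_id, start, end in matrix.partitions:
            fh.write(f"{model}, {locus_id} = {start}-{end}\n")
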