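"""From all-by-all similarity hits to MCL-ready graphs and filtered clusters.

The coarse clustering stage of the pipeline: tabular similarity results
(BLAST outfmt-6 style with query/subject lengths) are filtered by a
minimum coverage fraction and an E-value cutoff, written out as a
weighted undirected edge list for Markov clustering, and the resulting
clusters are read back, end-trimmed and size-filtered.  The clustering
itself is an external step; this module produces its input and consumes
its output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from .seqio import (
    DEFAULT_SCHEME,
    SequenceRecord,
    TaxonNameScheme,
    _open_text,
)

__all__ = [
    "SimilarityHit",
    "Cluster",
    "read_blast_tab",
    "merge_intervals",
    "hit_fraction",
    "filter_hits",
    "write_mcl_input",
    "parse_mcl_clusters",
    "trim_unsupported_ends",
    "coverage_map",
]

# -log10(E) is capped here: BLAST E values bottom out many orders of
# magnitude before underflow matters, and extremely significant hits
# should not dominate the clustering graph without bound.
MAX_EDGE_WEIGHT = 180.0

Interval = tuple[int, int]  # 1-based inclusive


@dataclass
class SimilarityHit:
    """One query-subject similarity record (HSPs merged by interval union)."""

    query: str
    subject: str
    evalue: float
    bitscore: float
    query_intervals: list[Interval]
    subject_intervals: list[Interval]
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E value {self.evalue}")
        for ivs, length, name in (
            (self.query_intervals, self.query_length, "query"),
            (self.subject_intervals, self.subject_length, "subject"),
        ):
            for lo, hi in ivs:
                if not (1 <= lo <= hi <= length):
                    raise ValueError(
                        f"{name} interval ({lo},{hi}) outside [1,{length}] "
                        f"for {self.query}->{self.subject}"
                    )


@dataclass
class Cluster:
    """A putative homolog group emitted by graph clustering."""

    cluster_id: str
    members: list[str]
    scheme: TaxonNameScheme = field(default=DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"cluster {self.cluster_id} has duplicate members")

    @property
    def taxa(self) -> set[str]:
        return {self.scheme.taxon_of(m) for m in self.members}


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of 1-based inclusive intervals, sorted and non-overlapping."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for lo, hi in ivs:
        if out and lo <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _covered(intervals: Iterable[Interval]) -> int:
    return sum(hi - lo + 1 for lo, hi in merge_intervals(intervals))


def hit_fraction(hit: SimilarityHit, mode: str = "min") -> float:
    """Coverage fraction of a hit.

    ``min`` (default) demands that *both* sequences are well covered,
    which is the stricter guard against motif-only matches chaining
    gene families into giant clusters; ``max`` accepts coverage of
    either sequence.
    """
    if hit.query_length <= 0 or hit.subject_length <= 0:
        raise ValueError(
            f"non-positive sequence length for {hit.query}->{hit.subject}"
        )
    fq = _covered(hit.query_intervals) / hit.query_length
    fs = _covered(hit.subject_intervals) / hit.subject_length
    if mode == "min":
        return min(fq, fs)
    if mode == "max":
        return max(fq, fs)
    raise ValueError(f"unknown hit-fraction mode {mode!r}")


# ---------------------------------------------------------------------------
# BLAST tabular input
# ---------------------------------------------------------------------------

# outfmt "6 std qlen slen"
DEFAULT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qlen slen"
).split()


def read_blast_tab(
    path: Union[str, Path],
    columns: Sequence[str] = DEFAULT_COLUMNS,
) -> list[SimilarityHit]:
    """Read BLAST tabular output, merging HSPs of each query-subject pair.

    Coordinates on the minus strand (sstart > send, BLASTN) are
    normalised to forward order.  The best (lowest) E value and highest
    bit score over a pair's HSPs are kept.
    """
    col = {name: i for i, name in enumerate(columns)}
    for required in ("qseqid", "sseqid", "qstart", "qend", "sstart", "send",
                     "evalue", "bitscore", "qlen", "slen"):
        if required not in col:
            raise ValueError(f"column map lacks required column {required!r}")

    by_pair: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(columns):
                raise ValueError(
                    f"{path}:{line_no}: expected {len(columns)} columns, "
                    f"got {len(parts)}"
                )
            q, s = parts[col["qseqid"]], parts[col["sseqid"]]
            qs, qe = int(parts[col["qstart"]]), int(parts[col["qend"]])
            ss, se = int(parts[col["sstart"]]), int(parts[col["send"]])
            rec = by_pair.get((q, s))
            if rec is None:
                rec = by_pair[(q, s)] = {
                    "qiv": [], "siv": [],
                    "evalue": math.inf, "bitscore": -math.inf,
                    "qlen": int(parts[col["qlen"]]),
                    "slen": int(parts[col["slen"]]),
                }
                order.append((q, s))
            rec["qiv"].append((min(qs, qe), max(qs, qe)))
            rec["siv"].append((min(ss, se), max(ss, se)))
            rec["evalue"] = min(rec["evalue"], float(parts[col["evalue"]]))
            rec["bitscore"] = max(rec["bitscore"], float(parts[col["bitscore"]]))

    return [
        SimilarityHit(
            query=q,
            subject=s,
            evalue=by_pair[(q, s)]["evalue"],
            bitscore=by_pair[(q, s)]["bitscore"],
            query_intervals=merge_intervals(by_pair[(q, s)]["qiv"]),
            subject_intervals=merge_intervals(by_pair[(q, s)]["siv"]),
            query_length=by_pair[(q, s)]["qlen"],
            subject_length=by_pair[(q, s)]["slen"],
        )
        for q, s in order
    ]


# ---------------------------------------------------------------------------
# Filtering and MCL graph export
# ---------------------------------------------------------------------------


def filter_hits(
    hits: Iterable[SimilarityHit],
    min_fraction: float = 0.4,
    evalue_cutoff: float = 1e-5,
    mode: str = "min",
) -> list[SimilarityHit]:
    """Keep well-covered, significant hits as undirected edges.

    A hit survives when its coverage fraction is at least
    ``min_fraction`` and its E value at most ``evalue_cutoff``.
    Self-hits are dropped; reciprocal records A->B / B->A collapse to
    one edge keeping the record with the lower E value (ties: higher
    bit score, then first seen).
    """
    best: dict[frozenset, SimilarityHit] = {}
    order: list[frozenset] = []
    for hit in hits:
        if hit.query == hit.subject:
            continue
        if hit.evalue > evalue_cutoff:
            continue
        if hit_fraction(hit, mode=mode) < min_fraction:
            continue
        key = frozenset((hit.query, hit.subject))
        prev = best.get(key)
        if prev is None:
            best[key] = hit
            order.append(key)
        elif (hit.evalue, -hit.bitscore) < (prev.evalue, -prev.bitscore):
            best[key] = hit
    return [best[k] for k in order]


def edge_weight(evalue: float) -> float:
    """-log10(E), capped at :data:`MAX_EDGE_WEIGHT`; E = 0 maps to the cap."""
    if evalue <= 0:
        return MAX_EDGE_WEIGHT
    return max(0.0, min(MAX_EDGE_WEIGHT, -math.log10(evalue)))


def write_mcl_input(
    hits: Iterable[SimilarityHit], path: Union[str, Path]
) -> int:
    """Write an MCL "abc" edge list (id1 TAB id2 TAB weight); returns edge count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for hit in hits:
            handle.write(
                f"{hit.query}\t{hit.subject}\t{edge_weight(hit.evalue):.6g}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# End trimming and cluster parsing
# ---------------------------------------------------------------------------


def coverage_map(
    hits: Iterable[SimilarityHit],
) -> dict[str, list[Interval]]:
    """Union of covered intervals per sequence over all given hits."""
    cov: dict[str, list[Interval]] = {}
    for hit in hits:
        cov.setdefault(hit.query, []).extend(hit.query_intervals)
        cov.setdefault(hit.subject, []).extend(hit.subject_intervals)
    return {sid: merge_intervals(ivs) for sid, ivs in cov.items()}


def trim_unsupported_ends(
    seq: SequenceRecord, intervals: Sequence[Interval]
) -> SequenceRecord:
    """Cut off sequence ends never covered by any similarity hit.

    Uncovered ends are the signature of misassembly or frameshift.
    Only the ends are cut: the retained region runs from the first to
    the last covered position, keeping any interior uncovered stretch.
    A sequence with no hits at all becomes empty (and is then discarded
    by the length filter downstream).
    """
    if not intervals:
        return SequenceRecord(seq.identifier, "", seq.alphabet)
    merged = merge_intervals(intervals)
    start = merged[0][0]
    end = merged[-1][1]
    end = min(end, len(seq.residues))
    return SequenceRecord(seq.identifier, seq.residues[start - 1 : end], seq.alphabet)


def parse_mcl_clusters(
    text_or_path: Union[str, Path],
    sequences: dict[str, SequenceRecord],
    min_taxa: int = 8,
    min_seq_length: int = 40,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    *,
    is_path: bool = False,
) -> list[Cluster]:
    """Read MCL output (one tab-separated cluster per line) and filter.

    Members shorter than ``min_seq_length`` residues (lengths measured
    on the end-trimmed sequences supplied) are dropped first, then
    clusters with fewer than ``min_taxa`` distinct taxa are dropped.
    Cluster ids follow input line order.
    """
    if is_path:
        with _open_text(text_or_path) as handle:
            lines = handle.read().splitlines()
    else:
        lines = str(text_or_path).splitlines()

    clusters: list[Cluster] = []
    for i, line in enumerate(lines):
        members = [m for m in line.strip().split("\t") if m]
        if not members:
            continue
        for m in members:
            if m not in sequences:
                raise KeyError(f"cluster member {m!r} absent from sequences")
        kept = [m for m in members if len(sequences[m]) >= min_seq_length]
        if not kept:
            continue
        cluster = Cluster(f"cluster{i}", kept, scheme)
        if len(cluster.taxa) >= min_taxa:
            clusters.append(cluster)
    return clusters
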