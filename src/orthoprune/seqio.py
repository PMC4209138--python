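"""Sequence records, alignments, FASTA I/O and the taxon-naming scheme.

Sequence identifiers carry their taxon of origin as a prefix,
``taxon@sequenceId`` by default, the convention used throughout
transcriptome phylogenomics pipelines.  :class:`TaxonNameScheme` makes
the delimiter and fallback behaviour configurable.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Alignment",
    "TaxonNameScheme",
    "NamingSchemeError",
    "parse_taxon",
    "count_unambiguous",
    "read_fasta",
    "write_fasta",
]

# Characters that carry no phylogenetic signal in a column: gaps,
# unknowns, stops, and the total-ambiguity code of each alphabet.
# IUPAC partial ambiguities (R, Y, ...) still restrict the state set
# and are counted as unambiguous.
_ALWAYS_AMBIGUOUS = {"-", "?", "*"}


class NamingSchemeError(ValueError):
    """An identifier did not follow the taxon-naming convention."""


@dataclass(frozen=True)
class TaxonNameScheme:
    """How to recover the taxon from a sequence identifier.

    The taxon is the token before the first ``delimiter``.  With
    ``whole_id_fallback`` on, identifiers lacking the delimiter are
    treated as their own taxon (useful for genome-derived proteomes
    with bare gene ids); with it off they are an error.
    """

    delimiter: str = "@"
    whole_id_fallback: bool = False

    def taxon_of(self, identifier: str) -> str:
        return parse_taxon(identifier, self)

    def join(self, taxon: str, local_id: str) -> str:
        return f"{taxon}{self.delimiter}{local_id}"


DEFAULT_SCHEME = TaxonNameScheme()


def parse_taxon(identifier: str, scheme: TaxonNameScheme = DEFAULT_SCHEME) -> str:
    """Taxon token of ``identifier`` under ``scheme`` (first-delimiter rule)."""
    if scheme.delimiter in identifier:
        return identifier.split(scheme.delimiter, 1)[0]
    if scheme.whole_id_fallback:
        return identifier
    raise NamingSchemeError(
        f"identifier {identifier!r} lacks taxon delimiter {scheme.delimiter!r}"
    )


@dataclass
class SequenceRecord:
    identifier: str
    residues: str
    alphabet: str = "aa"  # "aa" or "nt"

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("sequence identifier must be nonempty")

    def __len__(self) -> int:
        return len(self.residues)

    def taxon(self, scheme: TaxonNameScheme = DEFAULT_SCHEME) -> str:
        return parse_taxon(self.identifier, scheme)


def count_unambiguous(row: str, alphabet: str = "aa") -> int:
    """Number of informative characters in one aligned row.

    Gaps ``-``, unknowns ``?``, stops ``*`` and the total-ambiguity
    code (``X`` for amino acids, ``N`` for nucleotides) do not count;
    everything else, including IUPAC partial ambiguity codes, does.
    """
    ambiguous = set(_ALWAYS_AMBIGUOUS)
    ambiguous.add("X" if alphabet == "aa" else "N")
    return sum(1 for c in row.upper() if c not in ambiguous)


class Alignment:
    """An ordered set of equal-length rows with unique identifiers."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        if self.records:
            width = len(self.records[0])
            for rec in self.records:
                if len(rec) != width:
                    raise ValueError(
                        f"row {rec.identifier!r} has length {len(rec)}, "
                        f"expected {width}"
                    )
        ids = [r.identifier for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate row identifiers: {dupes}")
        self._index = {r.identifier: r for r in self.records}

    @property
    def n_columns(self) -> int:
        return len(self.records[0]) if self.records else 0

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._index

    def __getitem__(self, identifier: str) -> SequenceRecord:
        return self._index[identifier]

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.identifier for r in self.records]

    def unambiguous_counts(self) -> dict[str, int]:
        return {
            r.identifier: count_unambiguous(r.residues, r.alphabet)
            for r in self.records
        }

    def subset(self, identifiers: Iterable[str]) -> "Alignment":
        wanted = set(identifiers)
        missing = wanted - set(self._index)
        if missing:
            raise KeyError(f"rows absent from alignment: {sorted(missing)}")
        return Alignment([r for r in self.records if r.identifier in wanted])


# ---------------------------------------------------------------------------
# FASTA I/O (plain or gzip)
# ---------------------------------------------------------------------------


def _open_text(path: Union[str, Path], mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(
    path: Union[str, Path], alphabet: str = "aa"
) -> dict[str, SequenceRecord]:
    """Read FASTA into an id-keyed dict, preserving input order."""
    out: dict[str, SequenceRecord] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
            out[rec.id] = SequenceRecord(rec.id, str(rec.seq), alphabet)
    return out


def read_alignment(path: Union[str, Path], alphabet: str = "aa") -> Alignment:
    return Alignment(read_fasta(path, alphabet).values())


def write_fasta(
    records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60
) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
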