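"""FASTA/FASTQ readers and writers shared by every pipeline stage.

Thin wrappers around Biopython's parsers that add the invariants the
pipeline relies on: unique record ids, non-empty sequences, matching
sequence/quality lengths, and transparent gzip handling.  All qualities are
Phred+33.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "TranscriptSet",
    "FastqRead",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]

_DNA = frozenset("ACGT")


@dataclass
class TranscriptSet:
    """A species' reference transcript (or protein) collection.

    ``records`` maps transcript id -> sequence.  Nucleotide sets are
    restricted to the A/C/G/T alphabet; protein sets relax this (set
    ``alphabet=None``).
    """

    species_id: str
    records: dict[str, str] = field(default_factory=dict)
    alphabet: frozenset | None = _DNA

    def __post_init__(self) -> None:
        for tid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for {tid!r} in {self.species_id}")
            if self.alphabet is not None and not set(seq) <= self.alphabet:
                bad = sorted(set(seq) - self.alphabet)
                raise ValueError(f"{tid!r} contains non-ACGT characters: {bad}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records.items())

    def __contains__(self, tid: str) -> bool:
        return tid in self.records

    def __getitem__(self, tid: str) -> str:
        return self.records[tid]

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    def min_length(self) -> int:
        return min(len(s) for s in self.records.values())


@dataclass(frozen=True)
class FastqRead:
    """One sequenced read: id, bases, per-base Phred+33 quality string."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"{self.read_id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, species_id: str | None = None,
               alphabet: frozenset | None = _DNA) -> TranscriptSet:
    """Read a FASTA file into a :class:`TranscriptSet`.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records: dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
    name = species_id if species_id is not None else Path(path).stem
    return TranscriptSet(species_id=name, records=records, alphabet=alphabet)


def write_fasta(path: str | Path, tset: TranscriptSet, width: int = 70) -> None:
    """Write a TranscriptSet as FASTA, wrapping lines at ``width``."""
    with _open_text(path, "wt") as handle:
        for tid, seq in tset:
            handle.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Read a FASTQ file; errors on seq/qual length mismatch or duplicates."""
    reads: list[FastqRead] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            rid = title.split()[0]
            if rid in seen:
                raise ValueError(f"duplicate read id {rid!r} in {path}")
            seen.add(rid)
            reads.append(FastqRead(rid, seq.upper(), qual))
    return reads


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with _open_text(path, "wt") as handle:
        for r in reads:
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
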