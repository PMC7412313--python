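"""Read quality control: adapter/quality trimming, length filter, rRNA removal.

Mirrors a standard short-read cleanup: 3' adapter removal (exact-prefix
match with a tolerated mismatch fraction), Trimmomatic-style sliding-window
quality clipping, discard of trimmed reads shorter than 40 bases, and
removal of read pairs in which either mate matches a ribosomal RNA
reference end-to-end with at most three mismatches (substitutions only, on
either strand, at any offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import FastqRead, TranscriptSet
from .simulate import revcomp

__all__ = [
    "Sample",
    "ReadPair",
    "TrimParams",
    "trim_read",
    "RrnaFilter",
    "filter_rrna",
    "qc_pairs",
    "pair_reads",
]

DEFAULT_MIN_LENGTH = 40
DEFAULT_RRNA_MAX_MISMATCH = 3


@dataclass(frozen=True)
class Sample:
    """Sample coordinates: growth condition, replicate index, grafted flag."""

    condition: str
    replicate: int
    grafted: bool


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    mate1: FastqRead
    mate2: FastqRead
    sample: Sample


@dataclass(frozen=True)
class TrimParams:
    """Trimming knobs; the quality window mirrors Trimmomatic SLIDINGWINDOW:4:20."""

    adapter: str = ""
    quality_threshold: int = 20
    window: int = 4
    min_length: int = DEFAULT_MIN_LENGTH
    adapter_mismatch_frac: float = 0.1
    adapter_min_overlap: int = 3


def pair_reads(reads1: list[FastqRead], reads2: list[FastqRead],
               sample: Sample) -> list[ReadPair]:
    """Zip two mate files into ReadPairs; ids must agree positionally."""
    if len(reads1) != len(reads2):
        raise ValueError("mate files have different read counts")
    pairs = []
    for r1, r2 in zip(reads1, reads2):
        if r1.read_id != r2.read_id:
            raise ValueError(f"mate id mismatch: {r1.read_id!r} vs {r2.read_id!r}")
        pairs.append(ReadPair(pair_id=r1.read_id, mate1=r1, mate2=r2, sample=sample))
    return pairs


def _find_adapter(seq: str, params: TrimParams) -> int:
    """Leftmost position where the adapter prefix starts; len(seq) if absent.

    Vectorised over candidate positions: mismatch counts between every read
    suffix and the adapter prefix of the same overlap are accumulated one
    adapter column at a time.
    """
    adapter = params.adapter
    if not adapter:
        return len(seq)
    L = len(seq)
    A = len(adapter)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
    mism = np.zeros(L, dtype=np.int32)
    for j in range(min(A, L)):
        mism[: L - j] += arr[j:] != ad[j]
    overlap = np.minimum(L - np.arange(L), A)
    allowed = np.floor(params.adapter_mismatch_frac * overlap).astype(np.int32)
    hit = (mism <= allowed) & (overlap >= params.adapter_min_overlap)
    idx = np.flatnonzero(hit)
    return int(idx[0]) if idx.size else L


def _quality_clip(qual: str, threshold: int, window: int) -> int:
    """First sliding-window start whose mean quality drops below threshold."""
    scores = [ord(c) - 33 for c in qual]
    n = len(scores)
    if n < window:
        return n if (not scores or sum(scores) / n >= threshold) else 0
    acc = sum(scores[:window])
    if acc / window < threshold:
        return 0
    for i in range(1, n - window + 1):
        acc += scores[i + window - 1] - scores[i - 1]
        if acc / window < threshold:
            return i
    return n


def trim_read(mate: FastqRead, params: TrimParams) -> FastqRead | None:
    """Adapter-trim then quality-trim a mate; None signals discard (<min_length)."""
    if len(mate) == 0:
        return None
    cut = _find_adapter(mate.sequence, params)
    seq, qual = mate.sequence[:cut], mate.quality[:cut]
    cut = _quality_clip(qual, params.quality_threshold, params.window)
    seq, qual = seq[:cut], qual[:cut]
    if len(seq) < params.min_length:
        return None
    return FastqRead(mate.read_id, seq, qual)


class RrnaFilter:
    """Hamming-distance contaminant screen against an rRNA reference set.

    A mate is contaminant if it matches some reference end-to-end (no
    indels) with at most ``max_mismatch`` substitutions at any offset on
    either strand.  Candidate placements come from an exhaustive seed index:
    a read with m mismatches split into m+1 blocks has a clean block, and
    the block's leading ``seed_k``-mer is an exact index hit, so the screen
    is complete for reads of length >= (max_mismatch + 1) * seed_k.
    """

    def __init__(self, rrna: TranscriptSet,
                 max_mismatch: int = DEFAULT_RRNA_MAX_MISMATCH,
                 seed_k: int = 10):
        self.max_mismatch = max_mismatch
        self.seed_k = seed_k
        self._seqs = {tid: seq for tid, seq in rrna}
        self._arrs = {tid: np.frombuffer(seq.encode(), dtype=np.uint8)
                      for tid, seq in rrna}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in rrna:
            for off in range(0, len(seq) - seed_k + 1):
                self._index.setdefault(seq[off : off + seed_k], []).append((tid, off))

    def _matches_oriented(self, seq: str) -> bool:
        L = len(seq)
        k = self.seed_k
        if L < k:
            return False
        block = max(L // (self.max_mismatch + 1), k)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        tried: set[tuple[str, int]] = set()
        for b in range(self.max_mismatch + 1):
            p = b * block
            if p + k > L:
                break
            for tid, off in self._index.get(seq[p : p + k], ()):
                o = off - p
                key = (tid, o)
                if key in tried:
                    continue
                tried.add(key)
                ref = self._arrs[tid]
                if o < 0 or o + L > len(ref):
                    continue
                if int(np.count_nonzero(arr != ref[o : o + L])) <= self.max_mismatch:
                    return True
        return False

    def is_contaminant(self, mate: FastqRead) -> bool:
        return (self._matches_oriented(mate.sequence)
                or self._matches_oriented(revcomp(mate.sequence)))


def filter_rrna(pairs: list[ReadPair], rrna: TranscriptSet,
                max_mismatch: int = DEFAULT_RRNA_MAX_MISMATCH,
                ) -> tuple[list[ReadPair], list[ReadPair]]:
    """Split pairs into (survivors, discarded); order of survivors preserved.

    A pair is discarded if either mate matches the rRNA set.  An empty rRNA
    set keeps every pair.
    """
    if len(rrna) == 0:
        return list(pairs), []
    screen = RrnaFilter(rrna, max_mismatch=max_mismatch)
    kept, dropped = [], []
    for pair in pairs:
        if screen.is_contaminant(pair.mate1) or screen.is_contaminant(pair.mate2):
            dropped.append(pair)
        else:
            kept.append(pair)
    return kept, dropped


def qc_pairs(pairs: list[ReadPair], params: TrimParams,
             rrna: TranscriptSet | None = None,
             rrna_max_mismatch: int = DEFAULT_RRNA_MAX_MISMATCH,
             ) -> tuple[list[ReadPair], list[tuple[str, str]]]:
    """Full QC for one sample: trim both mates, drop short pairs, rRNA screen.

    Returns (surviving pairs, discard log of (pair_id, reason)) with reasons
    ``short`` and ``rrna``.  A pair is dropped whenever either mate fails,
    preserving mate pairing downstream.
    """
    log: list[tuple[str, str]] = []
    trimmed: list[ReadPair] = []
    for pair in pairs:
        m1 = trim_read(pair.mate1, params)
        m2 = trim_read(pair.mate2, params)
        if m1 is None or m2 is None:
            log.append((pair.pair_id, "short"))
            continue
        trimmed.append(ReadPair(pair.pair_id, m1, m2, pair.sample))
    if rrna is not None and len(rrna) > 0:
        kept, dropped = filter_rrna(trimmed, rrna, max_mismatch=rrna_max_mismatch)
        log.extend((p.pair_id, "rrna") for p in dropped)
    else:
        kept = trimmed
    return kept, log
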