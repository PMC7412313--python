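"""K-mer-seeded banded edit-distance read aligner.

Reads are aligned end-to-end (global in the read, local in the reference)
against a transcript reference under a hard Levenshtein edit cap.  The
search is seed-and-verify: exact k-mers shared between read and reference
propose candidate diagonals, candidate start positions within ``max_edit``
of a seeded diagonal are verified exactly, and each verified placement is
reported with its edit distance and a CIGAR that consumes the whole read.

With the default seed length ``k=15`` and sampling ``step=5``, an 85-bp
read with at most two edits always retains an exact seeded match: the edits
split the read into at most three clean segments, the longest of which has
length >= ceil((85-2)/3) = 28 >= k + step - 1, so at least one read k-mer
coincides with an indexed reference k-mer (pigeonhole).  Seeding therefore
loses nothing at the edit caps the classification cascade uses (<=2 against
the rootstock, <=1 against the scion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seqio import TranscriptSet
from .simulate import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "KmerIndex",
    "AlignmentRecord",
    "build_index",
    "align_read",
    "align_pair",
    "PairAlignment",
]

DEFAULT_K = 15
DEFAULT_STEP = 5


@dataclass
class KmerIndex:
    """Sampled k-mer postings over a reference transcript set."""

    k: int
    step: int
    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.postings.get(kmer, [])


@dataclass(frozen=True)
class AlignmentRecord:
    """One read placement: target, 0-based start, strand, edit distance, CIGAR.

    ``target_end`` is the 0-based exclusive end of the consumed reference
    window; ``cigar`` consumes exactly the read length (M + I operations).
    """

    read_id: str
    target_id: str
    target_start: int
    strand: str
    edit_distance: int
    cigar: str
    mate: int = 1
    target_end: int = -1


def build_index(refs: TranscriptSet, k: int = DEFAULT_K,
                step: int = DEFAULT_STEP) -> KmerIndex:
    """Index every reference k-mer starting at a position divisible by ``step``."""
    if k < 8:
        raise ValueError("k must be >= 8")
    if step < 1:
        raise ValueError("step must be >= 1")
    postings: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in refs:
        if len(seq) < k:
            raise ValueError(f"transcript {tid!r} is shorter than k={k}")
        for off in range(0, len(seq) - k + 1, step):
            postings.setdefault(seq[off : off + k], []).append((tid, off))
    return KmerIndex(k=k, step=step, postings=postings)


def _start_distances(read: str, segment: str) -> np.ndarray:
    """Exact placement distances for every start offset within ``segment``.

    Returns ``d`` with ``d[s] = min_w lev(read, segment[s:s+w])`` for
    ``s = 0..len(segment)``: the edit distance of the best end-free
    alignment of the whole read starting exactly at ``s``.  Computed as a
    free-start semiglobal DP over the reversed strings, row-vectorised with
    the running-minimum trick for the horizontal (deletion) moves.
    """
    m = len(segment)
    rread = np.frombuffer(read[::-1].encode(), dtype=np.uint8)
    rseg = np.frombuffer(segment[::-1].encode(), dtype=np.uint8)
    prev = np.zeros(m + 1, dtype=np.int32)
    ar = np.arange(m + 1, dtype=np.int32)
    for i in range(1, len(rread) + 1):
        t = (rseg != rread[i - 1]).astype(np.int32)
        cur = np.empty(m + 1, dtype=np.int32)
        cur[0] = i
        np.minimum(prev[:m] + t, prev[1:] + 1, out=cur[1:])
        x = cur - ar
        np.minimum.accumulate(x, out=x)
        cur = x + ar
        prev = cur
    # prev[j] = min over starts of lev(reversed read, reversed segment[:j])
    # which is the best end-free distance for the original start m - j.
    return prev[::-1]


def _anchored_align(read: str, ref: str, start: int, band: int,
                    ) -> tuple[int, int, str] | None:
    """Banded DP anchored at ``start``: (distance, end, cigar) or None.

    The band half-width bounds the net indel excursion, so any alignment
    with at most ``band`` edits is found exactly.  Ties on distance prefer
    the shortest reference window.
    """
    L = len(read)
    offsets = range(-band, band + 1)
    INF = L + band + 1
    width = 2 * band + 1
    dist = [[INF] * width for _ in range(L + 1)]
    back: list[list[str]] = [["?"] * width for _ in range(L + 1)]
    for o in offsets:
        j = o  # row i=0, ref consumed = j
        if 0 <= j and start + j <= len(ref):
            dist[0][o + band] = j
            back[0][o + band] = "D" if j > 0 else "*"
    for i in range(1, L + 1):
        for o in offsets:
            j = i + o
            if j < 0 or start + j > len(ref):
                continue
            best, op = INF, "?"
            if j >= 1:
                d = dist[i - 1][o + band]  # diagonal: consumes read+ref
                if d < INF:
                    cost = d + (read[i - 1] != ref[start + j - 1])
                    if cost < best:
                        best, op = cost, "M"
            if o + 1 <= band:
                d = dist[i - 1][o + 1 + band]  # insertion: read char only
                if d + 1 < best:
                    best, op = d + 1, "I"
            if o - 1 >= -band and j >= 1:
                d = dist[i][o - 1 + band]  # deletion: ref char only
                if d + 1 < best:
                    best, op = d + 1, "D"
            dist[i][o + band] = best
            back[i][o + band] = op
    best_o, best_d = None, INF
    for o in offsets:  # smallest window wins ties
        d = dist[L][o + band]
        if d < best_d:
            best_d, best_o = d, o
    if best_o is None or best_d > band:
        return None
    # traceback
    ops: list[str] = []
    i, o = L, best_o
    while i > 0 or (i == 0 and o > 0):
        op = back[i][o + band]
        if op == "*":
            break
        ops.append(op)
        if op == "M":
            i -= 1
        elif op == "I":
            i -= 1
            o += 1
        else:  # D
            o -= 1
    ops.reverse()
    cigar = _compress_cigar(ops)
    return best_d, start + L + best_o, cigar


def _compress_cigar(ops: list[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def _candidate_intervals(diagonals: set[int], max_edit: int, ref_len: int,
                         read_len: int) -> list[tuple[int, int]]:
    """Merge per-diagonal start windows into disjoint [lo, hi] intervals."""
    hi_start = ref_len - max(read_len - max_edit, 1)
    starts: set[int] = set()
    for d in diagonals:
        for s in range(d - max_edit, d + max_edit + 1):
            if 0 <= s <= hi_start:
                starts.add(s)
    if not starts:
        return []
    ordered = sorted(starts)
    intervals = [[ordered[0], ordered[0]]]
    for s in ordered[1:]:
        if s <= intervals[-1][1] + 1:
            intervals[-1][1] = s
        else:
            intervals.append([s, s])
    return [(a, b) for a, b in intervals]


def _seed_diagonals(query: str, index: KmerIndex) -> dict[str, set[int]]:
    """All seeded diagonals (ref offset - read offset) per target."""
    k = index.k
    diags: dict[str, set[int]] = {}
    postings = index.postings
    for p in range(0, len(query) - k + 1):
        hits = postings.get(query[p : p + k])
        if hits:
            for tid, off in hits:
                diags.setdefault(tid, set()).add(off - p)
    return diags


def _hamming(a: np.ndarray, seq: str, start: int) -> int:
    b = np.frombuffer(seq.encode(), dtype=np.uint8)[start : start + len(a)]
    return int(np.count_nonzero(a != b))


def align_read(sequence: str, index: KmerIndex, refs: TranscriptSet,
               max_edit: int, read_id: str = "", mate: int = 1,
               with_cigar: bool = True) -> list[AlignmentRecord]:
    """All seeded placements of a read with edit distance <= ``max_edit``.

    Both strands are searched; records are sorted by
    (edit_distance, target_id, target_start, strand).  A read shorter than
    the index k returns an empty list with a logged warning.
    """
    if len(sequence) < index.k:
        logger.warning("read %s shorter than k=%d; skipped", read_id, index.k)
        return []
    records: list[AlignmentRecord] = []
    band = max(max_edit, 1)
    for strand in "+-":
        query = sequence if strand == "+" else revcomp(sequence)
        for tid, diags in _seed_diagonals(query, index).items():
            ref = refs[tid]
            for lo, hi in _candidate_intervals(diags, max_edit, len(ref), len(query)):
                seg = ref[lo : hi + len(query) + max_edit]
                dists = _start_distances(query, seg)
                for s in range(lo, hi + 1):
                    if dists[s - lo] <= max_edit:
                        if with_cigar:
                            res = _anchored_align(query, ref, s, band)
                            if res is None or res[0] > max_edit:
                                continue
                            d, end, cigar = res
                        else:
                            d, end, cigar = int(dists[s - lo]), s + len(query), ""
                        records.append(AlignmentRecord(
                            read_id=read_id, target_id=tid, target_start=s,
                            strand=strand, edit_distance=d, cigar=cigar,
                            mate=mate, target_end=end))
    records.sort(key=lambda r: (r.edit_distance, r.target_id, r.target_start, r.strand))
    return records


def _best_placements(sequence: str, index: KmerIndex, refs: TranscriptSet,
                     max_edit: int) -> dict[tuple[str, str], tuple[int, int]]:
    """Best qualifying placement per (target, strand): (distance, start).

    Fast path: when the best substitution-only (Hamming) placement on a
    seeded diagonal has distance 0 or 1 it is provably optimal and is taken
    directly; otherwise the exact per-start DP verifies the candidate band.
    """
    out: dict[tuple[str, str], tuple[int, int]] = {}
    if len(sequence) < index.k:
        return out
    L = len(sequence)
    for strand in "+-":
        query = sequence if strand == "+" else revcomp(sequence)
        qarr = np.frombuffer(query.encode(), dtype=np.uint8)
        for tid, diags in _seed_diagonals(query, index).items():
            ref = refs[tid]
            best: tuple[int, int] | None = None
            ham_best: tuple[int, int] | None = None
            for d in sorted(diags):
                if 0 <= d and d + L <= len(ref):
                    h = _hamming(qarr, ref, d)
                    if ham_best is None or (h, d) < ham_best:
                        ham_best = (h, d)
            if ham_best is not None and ham_best[0] <= min(1, max_edit):
                best = ham_best
            else:
                for lo, hi in _candidate_intervals(diags, max_edit, len(ref), L):
                    seg = ref[lo : hi + L + max_edit]
                    dists = _start_distances(query, seg)
                    for s in range(lo, hi + 1):
                        d = int(dists[s - lo])
                        if d <= max_edit and (best is None or (d, s) < best):
                            best = (d, s)
            if best is not None and best[0] <= max_edit:
                out[(tid, strand)] = best
    return out


@dataclass(frozen=True)
class PairAlignment:
    """Outcome of aligning a mate pair against one reference set."""

    proper: bool
    target_id: str | None = None
    summed_edit: int | None = None
    rec1: AlignmentRecord | None = None
    rec2: AlignmentRecord | None = None
    #: all targets tied at the minimal summed edit distance
    tied_targets: tuple[str, ...] = ()


def _proper_candidates(seq1: str, seq2: str, index: KmerIndex,
                       refs: TranscriptSet, max_edit: int,
                       insert_bounds: tuple[int, int],
                       ) -> list[tuple[int, str, int, tuple, tuple]]:
    """All proper-pair candidates: (summed_edit, target, fwd_start, m1, m2)."""
    hits1 = _best_placements(seq1, index, refs, max_edit)
    if not hits1:
        return []
    hits2 = _best_placements(seq2, index, refs, max_edit)
    lo, hi = insert_bounds
    cands = []
    for (tid, s1), (d1, p1) in hits1.items():
        s2 = "-" if s1 == "+" else "+"
        got = hits2.get((tid, s2))
        if got is None:
            continue
        d2, p2 = got
        if s1 == "+":
            fwd_len, rev_len = len(seq1), len(seq2)
            fwd_start, rev_start = p1, p2
        else:
            fwd_len, rev_len = len(seq2), len(seq1)
            fwd_start, rev_start = p2, p1
        insert = rev_start + rev_len - fwd_start
        if fwd_start <= rev_start and lo <= insert <= hi:
            cands.append((d1 + d2, tid, fwd_start,
                          (s1, d1, p1, len(seq1)), (s2, d2, p2, len(seq2))))
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    return cands


def align_pair(seq1: str, seq2: str, index: KmerIndex, refs: TranscriptSet,
               max_edit: int, insert_bounds: tuple[int, int],
               pair_id: str = "", with_cigar: bool = True) -> PairAlignment:
    """Align a mate pair; proper iff both mates hit the same target on
    opposite strands within the insert bounds, each within ``max_edit``.

    Among qualifying placements the minimal summed edit distance wins, ties
    broken by (target_id, leftmost forward start).  Targets tied at the
    minimal summed edit are reported in ``tied_targets``.
    """
    cands = _proper_candidates(seq1, seq2, index, refs, max_edit, insert_bounds)
    if not cands:
        return PairAlignment(proper=False)
    best = cands[0]
    tied = tuple(sorted({c[1] for c in cands if c[0] == best[0]}))
    summed, tid = best[0], best[1]
    recs = []
    for mate_no, (strand, d, pos, rlen) in ((1, best[3]), (2, best[4])):
        if d == 0 or not with_cigar:  # exact placement: no traceback needed
            d_final, end, cigar = d, pos + rlen, f"{rlen}M" if d == 0 else ""
        else:
            seq = seq1 if mate_no == 1 else seq2
            query = seq if strand == "+" else revcomp(seq)
            res = _anchored_align(query, refs[tid], pos, max(max_edit, 1))
            if res is None:  # placement verified already; band suffices
                d_final, end, cigar = d, pos + rlen, f"{rlen}M"
            else:
                d_final, end, cigar = res
        recs.append(AlignmentRecord(
            read_id=pair_id, target_id=tid, target_start=pos, strand=strand,
            edit_distance=d_final, cigar=cigar, mate=mate_no, target_end=end))
    return PairAlignment(proper=True, target_id=tid, summed_edit=summed,
                         rec1=recs[0], rec2=recs[1], tied_targets=tied)
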