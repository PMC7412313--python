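"""Reciprocal-best-hit orthology at a strict E-value cutoff.

The primary input path is precomputed 12-column tabular protein hits
(query, subject, %identity, alignment length, mismatches, gap opens,
qstart, qend, sstart, send, evalue, bitscore).  An internal Smith-Waterman
scorer over synthetic proteomes removes the need for an external search
tool in tests: raw local-alignment scores are converted to bit scores with
fixed published Karlin-Altschul constants for the ungapped default matrix,
and E-values use the simple E = m * n * 2^-bits length product, so the
E-values are approximate but monotone in score — exactly what best-hit
ranking needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import TranscriptSet

__all__ = [
    "HitRecord",
    "OrthologPair",
    "load_hits",
    "write_hits",
    "score_pair",
    "all_vs_all_hits",
    "best_hits",
    "reciprocal_best",
    "strip_isoform_suffix",
]

DEFAULT_EVALUE_CUTOFF = 1e-5

#: Ungapped Karlin-Altschul (lambda, K) for the supported matrices.
KARLIN_ALTSCHUL = {
    "BLOSUM62": (0.3176, 0.134),
    "BLOSUM50": (0.232, 0.112),
}

_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class HitRecord:
    """One reduced (best-HSP) hit between a query and a subject protein."""

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bit_score: float


class OrthologPair(NamedTuple):
    id_a: str
    id_b: str
    forward_hit: HitRecord | None = None
    reverse_hit: HitRecord | None = None


def load_hits(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular hit file, keeping the best HSP per pair.

    Reduction keeps, per (query, subject), the row with maximal bit score,
    breaking ties by minimal E-value.  Malformed rows raise with their line
    number.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                rec = HitRecord(
                    query_id=fields[0], subject_id=fields[1],
                    identity_pct=float(fields[2]), aln_length=int(fields[3]),
                    mismatches=int(fields[4]), gap_opens=int(fields[5]),
                    qstart=int(fields[6]), qend=int(fields[7]),
                    sstart=int(fields[8]), send=int(fields[9]),
                    evalue=float(fields[10]), bit_score=float(fields[11]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
            key = (rec.query_id, rec.subject_id)
            old = best.get(key)
            if old is None or (rec.bit_score, -rec.evalue) > (old.bit_score, -old.evalue):
                best[key] = rec
    return list(best.values())


def write_hits(path: str | Path, hits: Iterable[HitRecord]) -> None:
    with open(path, "w") as handle:
        for h in hits:
            handle.write("\t".join(str(v) for v in (
                h.query_id, h.subject_id, h.identity_pct, h.aln_length,
                h.mismatches, h.gap_opens, h.qstart, h.qend, h.sstart,
                h.send, h.evalue, h.bit_score)) + "\n")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length g costs gap_open + g * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[float, int, int, int, tuple[int, int, int, int]]:
    """(identity %, columns, mismatches, gap opens, 1-based q/s bounds)."""
    a, b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    gaps = sum(1 for x, y in zip(a, b) if x == "-" or y == "-")
    cols = len(a)
    mismatches = cols - matches - gaps
    gap_opens = 0
    prev_gap = False
    for x, y in zip(a, b):
        is_gap = x == "-" or y == "-"
        if is_gap and not prev_gap:
            gap_opens += 1
        prev_gap = is_gap
    (qs, qe) = int(alignment.aligned[0][0][0]), int(alignment.aligned[0][-1][1])
    (ss, se) = int(alignment.aligned[1][0][0]), int(alignment.aligned[1][-1][1])
    pct = 100.0 * matches / cols if cols else 0.0
    return pct, cols, mismatches, gap_opens, (qs + 1, qe, ss + 1, se)


def score_pair(protein_a: str, protein_b: str, matrix: str = "BLOSUM62",
               gap_open: float = 11.0, gap_extend: float = 1.0,
               db_size: int | None = None, query_id: str = "a",
               subject_id: str = "b") -> HitRecord:
    """Smith-Waterman local alignment of two proteins as a HitRecord.

    The bit score is (lambda * S - ln K) / ln 2 with the fixed ungapped
    constants for ``matrix``; E = m * n' * 2^-bits where n' is ``db_size``
    (total subject residues) or len(protein_b).
    """
    for name, seq in (("protein_a", protein_a), ("protein_b", protein_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"{name} contains non-amino-acid characters: {sorted(bad)}")
    if matrix not in KARLIN_ALTSCHUL:
        raise ValueError(f"no Karlin-Altschul constants for matrix {matrix!r}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = next(iter(aligner.align(protein_a, protein_b)))
    score = alignment.score
    pct, cols, mism, gapo, (qs, qe, ss, se) = _alignment_stats(alignment)
    lam, kappa = KARLIN_ALTSCHUL[matrix]
    import math
    bits = (lam * score - math.log(kappa)) / math.log(2)
    n_eff = db_size if db_size is not None else len(protein_b)
    evalue = len(protein_a) * n_eff * 2.0 ** (-bits)
    return HitRecord(query_id=query_id, subject_id=subject_id,
                     identity_pct=round(pct, 2), aln_length=cols,
                     mismatches=mism, gap_opens=gapo, qstart=qs, qend=qe,
                     sstart=ss, send=se, evalue=evalue, bit_score=round(bits, 1))


def _word_candidates(a_set: TranscriptSet, b_set: TranscriptSet,
                     word_size: int) -> set[tuple[str, str]]:
    """BLAST-like word screen: pairs sharing at least one exact word."""
    words: dict[str, list[str]] = {}
    for tid, seq in b_set:
        seen: set[str] = set()
        for i in range(len(seq) - word_size + 1):
            w = seq[i : i + word_size]
            if w not in seen:
                words.setdefault(w, []).append(tid)
                seen.add(w)
    cands: set[tuple[str, str]] = set()
    for qid, seq in a_set:
        hit: set[str] = set()
        for i in range(len(seq) - word_size + 1):
            for sid in words.get(seq[i : i + word_size], ()):
                hit.add(sid)
        cands.update((qid, sid) for sid in hit)
    return cands


def all_vs_all_hits(proteome_a: TranscriptSet, proteome_b: TranscriptSet,
                    matrix: str = "BLOSUM62", gap_open: float = 11.0,
                    gap_extend: float = 1.0, word_size: int = 6,
                    ) -> tuple[list[HitRecord], list[HitRecord]]:
    """Score all candidate pairs in both directions: (a->b hits, b->a hits).

    Pairs are screened by a shared exact ``word_size``-mer (both on the
    forward pair and its mirror) before Smith-Waterman scoring; raw scores
    are symmetric so each surviving pair is scored once.
    """
    db_a = sum(len(s) for _, s in proteome_a)
    db_b = sum(len(s) for _, s in proteome_b)
    cands = _word_candidates(proteome_a, proteome_b, word_size)
    ab: list[HitRecord] = []
    ba: list[HitRecord] = []
    for qid, sid in sorted(cands):
        fwd = score_pair(proteome_a[qid], proteome_b[sid], matrix=matrix,
                         gap_open=gap_open, gap_extend=gap_extend,
                         db_size=db_b, query_id=qid, subject_id=sid)
        ab.append(fwd)
        # the raw score is symmetric; mirror the record instead of realigning
        rev_evalue = len(proteome_b[sid]) * db_a * 2.0 ** (-fwd.bit_score)
        ba.append(HitRecord(
            query_id=sid, subject_id=qid, identity_pct=fwd.identity_pct,
            aln_length=fwd.aln_length, mismatches=fwd.mismatches,
            gap_opens=fwd.gap_opens, qstart=fwd.sstart, qend=fwd.send,
            sstart=fwd.qstart, send=fwd.qend, evalue=rev_evalue,
            bit_score=fwd.bit_score))
    return ab, ba


def best_hits(hits: Iterable[HitRecord],
              evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> dict[str, str]:
    """Best subject per query among hits with E strictly below the cutoff.

    Ranking: maximal bit score, then minimal E-value, then lexicographically
    smallest subject id.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        if not h.evalue < evalue_cutoff:
            continue
        old = best.get(h.query_id)
        if old is None or ((-h.bit_score, h.evalue, h.subject_id)
                           < (-old.bit_score, old.evalue, old.subject_id)):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best(best_ab: dict[str, str], best_ba: dict[str, str],
                    ) -> set[OrthologPair]:
    """Pairs (a, b) with best_ab[a] == b and best_ba[b] == a."""
    return {
        OrthologPair(a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    }


def strip_isoform_suffix(tid: str) -> str:
    """Optional id normalization: drop a trailing isoform suffix (``.1``)."""
    head, dot, tail = tid.rpartition(".")
    return head if dot and tail.isdigit() else tid
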