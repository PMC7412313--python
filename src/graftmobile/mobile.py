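"""Classification cascade and mobile-mRNA calling.

Each QC-passing rootstock-sample read pair is classified sequentially:

1. **rootstock** — the pair aligns as a proper pair to the rootstock
   reference within 2 edits per mate;
2. **control_match** — otherwise, either mate's sequence (or its reverse
   complement) occurs verbatim among the reads of non-grafted control
   samples;
3. **transmitted** — otherwise, the pair aligns as a proper pair to the
   scion reference within 1 edit per mate; these pairs are the evidence of
   shoot-to-root transport;
4. **unassigned** — none of the above.

A scion transcript is *detected* in a replicate when at least ``min_pairs``
transmitted pairs are assigned to it, and called *mobile* in a condition
when detected in at least ``min_replicates`` of the replicates (default 2
of 3).  Abundance is expressed in RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import KmerIndex, align_pair
from .qc import ReadPair
from .seqio import FastqRead, TranscriptSet
from .simulate import revcomp

__all__ = [
    "ClassifiedPair",
    "MobileCall",
    "MobileCallTable",
    "build_control_set",
    "match_control",
    "classify_pair",
    "classify_sample",
    "call_mobile",
    "rpkm",
    "condition_sets",
]

DEFAULT_ROOT_MAX_EDIT = 2
DEFAULT_SCION_MAX_EDIT = 1
DEFAULT_MIN_REPLICATES = 2
DEFAULT_MIN_PAIRS = 1

LABELS = ("rootstock", "control_match", "transmitted", "unassigned")


@dataclass(frozen=True)
class ClassifiedPair:
    pair_id: str
    label: str
    assigned_targets: frozenset[str] = frozenset()
    summed_edit: int | None = None
    ambiguous: bool = False


def build_control_set(control_reads: list[FastqRead]) -> frozenset[str]:
    """Hash every control read sequence (mates pooled) for exact lookup."""
    return frozenset(r.sequence for r in control_reads)


def match_control(pair: ReadPair, control_set: frozenset[str]) -> bool:
    """True iff either mate's full sequence, in either orientation, is a
    verbatim control-sample read."""
    for mate in (pair.mate1, pair.mate2):
        if mate.sequence in control_set or revcomp(mate.sequence) in control_set:
            return True
    return False


def classify_pair(pair: ReadPair, rootstock_index: KmerIndex,
                  rootstock_refs: TranscriptSet, scion_index: KmerIndex,
                  scion_refs: TranscriptSet, control_set: frozenset[str],
                  root_max_edit: int = DEFAULT_ROOT_MAX_EDIT,
                  scion_max_edit: int = DEFAULT_SCION_MAX_EDIT,
                  insert_bounds: tuple[int, int] = (40, 600),
                  ) -> ClassifiedPair:
    """Run one pair through the rootstock -> control -> scion cascade."""
    root = align_pair(pair.mate1.sequence, pair.mate2.sequence, rootstock_index,
                      rootstock_refs, root_max_edit, insert_bounds, pair.pair_id,
                      with_cigar=False)
    if root.proper:
        return ClassifiedPair(pair.pair_id, "rootstock",
                              frozenset(root.tied_targets), root.summed_edit,
                              ambiguous=len(root.tied_targets) > 1)
    if match_control(pair, control_set):
        return ClassifiedPair(pair.pair_id, "control_match")
    scion = align_pair(pair.mate1.sequence, pair.mate2.sequence, scion_index,
                       scion_refs, scion_max_edit, insert_bounds, pair.pair_id,
                       with_cigar=False)
    if scion.proper:
        return ClassifiedPair(pair.pair_id, "transmitted",
                              frozenset(scion.tied_targets), scion.summed_edit,
                              ambiguous=len(scion.tied_targets) > 1)
    return ClassifiedPair(pair.pair_id, "unassigned")


def classify_sample(pairs: list[ReadPair], rootstock_index: KmerIndex,
                    rootstock_refs: TranscriptSet, scion_index: KmerIndex,
                    scion_refs: TranscriptSet, control_set: frozenset[str],
                    **kwargs) -> list[ClassifiedPair]:
    return [classify_pair(p, rootstock_index, rootstock_refs, scion_index,
                          scion_refs, control_set, **kwargs) for p in pairs]


def rpkm(pair_count: int, transcript_length: int, total_mapped_pairs: int) -> float:
    """Reads per kilobase of transcript per million mapped fragments."""
    if transcript_length <= 0 or total_mapped_pairs <= 0:
        raise ValueError("transcript_length and total_mapped_pairs must be > 0")
    return 1e9 * pair_count / (transcript_length * total_mapped_pairs)


@dataclass
class MobileCall:
    transcript_id: str
    condition: str
    detected_replicates: tuple[int, ...]
    pair_counts: dict[int, int]
    mobile: bool
    rpkm: dict[int, float]


@dataclass
class MobileCallTable:
    """Per (scion transcript, condition) detection summary."""

    rows: list[MobileCall] = field(default_factory=list)
    conditions: tuple[str, ...] = ()
    n_replicates: int = 0

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "transcript_id": r.transcript_id,
                "condition": r.condition,
                "detected_replicates": ",".join(map(str, r.detected_replicates)),
                "n_detected": len(r.detected_replicates),
                "mobile": r.mobile,
                "total_pairs": sum(r.pair_counts.values()),
                "mean_rpkm": (sum(r.rpkm.values()) / len(r.rpkm)) if r.rpkm else 0.0,
            })
        return pd.DataFrame.from_records(
            recs, columns=["transcript_id", "condition", "detected_replicates",
                           "n_detected", "mobile", "total_pairs", "mean_rpkm"])


def call_mobile(classified: dict[tuple[str, int], list[ClassifiedPair]],
                scion_lengths: dict[str, int],
                min_replicates: int = DEFAULT_MIN_REPLICATES,
                min_pairs: int = DEFAULT_MIN_PAIRS) -> MobileCallTable:
    """Aggregate per-replicate transmitted evidence into mobile calls.

    ``classified`` maps (condition, replicate) to that sample's classified
    pairs; the replicate grid must be identical across conditions.  RPKM per
    replicate uses the sample's total mapped pairs (rootstock + transmitted).
    """
    conditions = tuple(dict.fromkeys(c for c, _ in classified))
    replicates = sorted({r for _, r in classified})
    for c in conditions:
        reps = sorted(r for cc, r in classified if cc == c)
        if reps != replicates:
            raise ValueError(f"replicate structure differs for condition {c!r}")
    if min_replicates > len(replicates):
        raise ValueError("min_replicates exceeds the number of replicates")

    counts: dict[str, dict[str, dict[int, int]]] = {c: {} for c in conditions}
    totals: dict[tuple[str, int], int] = {}
    for (cond, rep), pairs in classified.items():
        total_mapped = 0
        for cp in pairs:
            if cp.label in ("rootstock", "transmitted"):
                total_mapped += 1
            if cp.label == "transmitted":
                for tid in cp.assigned_targets:
                    counts[cond].setdefault(tid, {}).setdefault(rep, 0)
                    counts[cond][tid][rep] += 1
        totals[(cond, rep)] = total_mapped

    rows: list[MobileCall] = []
    for cond in conditions:
        for tid in sorted(counts[cond]):
            per_rep = counts[cond][tid]
            detected = tuple(r for r in replicates if per_rep.get(r, 0) >= min_pairs)
            length = scion_lengths.get(tid)
            rpkms = {}
            if length:
                for r, n in per_rep.items():
                    if totals[(cond, r)] > 0:
                        rpkms[r] = rpkm(n, length, totals[(cond, r)])
            rows.append(MobileCall(
                transcript_id=tid, condition=cond, detected_replicates=detected,
                pair_counts=dict(per_rep), mobile=len(detected) >= min_replicates,
                rpkm=rpkms))
    rows.sort(key=lambda r: (r.transcript_id, r.condition))
    return MobileCallTable(rows=rows, conditions=conditions,
                           n_replicates=len(replicates))


def condition_sets(table: MobileCallTable) -> dict[str, set[str]]:
    """Mobile transcript ids per condition, plus their union under ``"union"``."""
    out: dict[str, set[str]] = {c: set() for c in table.conditions}
    for r in table.rows:
        if r.mobile:
            out.setdefault(r.condition, set()).add(r.transcript_id)
    out["union"] = set().union(*out.values()) if out else set()
    return out
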