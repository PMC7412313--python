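"""Synthetic heterograft RNA-seq experiments with known ground truth.

The generator emulates the data structure of a two-species graft experiment:
a scion (shoot) species and a rootstock species whose transcriptomes diverged
from a common ancestor by ~4% at the nucleotide level, stranded 85-bp paired
reads from rootstock tissue, three biological replicates across four
hydroponic growth conditions (full nutrient, low N, low P, low Fe), and a
small "mobile" subset of scion transcripts present at low abundance in the
rootstock samples.  Every read name encodes its source transcript, so any
downstream classification can be scored against the truth exactly.

Ancestral transcripts are generated as clean open reading frames (ATG, a run
of uniformly chosen sense codons, one stop codon).  Divergence applies
per-site substitutions independently in each lineage at half the target rate,
resampling any substitution that would create an in-frame stop codon
(nonsense mutations are strongly purged in real coding orthologs), and
in-frame 3-bp indels so that reading frames — and hence the derived
proteomes used by the orthology stage — stay intact.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .seqio import FastqRead, TranscriptSet

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "SimConfig",
    "SimTruth",
    "DEFAULT_TRUTH_REGIONS",
    "generate_ancestor",
    "diverge",
    "assign_truth",
    "simulate_sample",
    "generate_proteomes",
    "generate_rrna",
    "revcomp",
    "parse_read_name",
    "replicate_seed",
]

#: The four growth conditions of the emulated experiment.
CONDITIONS = ("full", "lowN", "lowP", "lowFe")

_BASES = "ACGT"
_STOPS = frozenset({"TAA", "TAG", "TGA"})
#: All 61 sense codons, deterministic order.
_SENSE = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

_COMP = str.maketrans("ACGT", "TGCA")

#: Illumina TruSeq universal adapter prefix (read-through contaminant).
TRUSEQ_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic heterograft experiment.

    Defaults are the emulated study conditions: 85-bp stranded paired reads,
    three replicates, ~4% nucleotide divergence between the grafted species,
    and mobile scion transcripts at two-thirds of the rootstock per-transcript
    depth (mean 20 pairs against a rootstock mean of 30).
    """

    n_transcripts: int = 300
    length_range: tuple[int, int] = (500, 2000)
    divergence: float = 0.04
    indel_rate: float = 0.0005
    read_length: int = 85
    error_rate: float = 0.005
    depth: float = 30.0
    mobile_abundance_factor: float = 2.0 / 3.0
    insert_range: tuple[int, int] = (150, 400)
    adapter: str = TRUSEQ_ADAPTER
    adapter_fraction: float = 0.01
    rrna_fraction: float = 0.02
    n_replicates: int = 3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be >= 0")
        lo, hi = self.length_range
        if not (3 <= lo <= hi):
            raise ValueError("length_range must satisfy 3 <= lo <= hi")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if self.read_length < 40:
            raise ValueError("read_length must be >= 40")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("indel_rate", "error_rate", "adapter_fraction", "rrna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth < 0 or self.mobile_abundance_factor < 0:
            raise ValueError("depth and mobile_abundance_factor must be >= 0")
        ilo, ihi = self.insert_range
        if not (self.read_length <= ilo <= ihi):
            raise ValueError("insert_range must satisfy read_length <= lo <= hi")

    def with_seed(self, master_seed: int) -> "SimConfig":
        return replace(self, master_seed=master_seed)


@dataclass
class SimTruth:
    """Ground-truth mobile sets: condition -> scion transcript ids."""

    mobile_by_condition: dict[str, set[str]]
    condition_list: tuple[str, ...] = CONDITIONS

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for ids in self.mobile_by_condition.values():
            out |= ids
        return out


#: Venn-region sizes (keys are condition subsets) with the qualitative
#: structure of the real experiment scaled to a 300-transcript reference:
#: a large core mobile in all four conditions, sizeable single-condition
#: regions, and thin pairwise/triple overlaps.  Union = 130 transcripts.
DEFAULT_TRUTH_REGIONS: dict[tuple[str, ...], int] = {
    ("full", "lowN", "lowP", "lowFe"): 37,
    ("full",): 8,
    ("lowN",): 20,
    ("lowP",): 15,
    ("lowFe",): 19,
    ("full", "lowN"): 4,
    ("full", "lowP"): 3,
    ("full", "lowFe"): 5,
    ("lowN", "lowP"): 2,
    ("lowN", "lowFe"): 3,
    ("lowP", "lowFe"): 2,
    ("full", "lowN", "lowP"): 3,
    ("full", "lowN", "lowFe"): 4,
    ("full", "lowP", "lowFe"): 3,
    ("lowN", "lowP", "lowFe"): 2,
}


def scaled_truth_regions(n_transcripts: int,
                         base: dict[tuple[str, ...], int] | None = None,
                         mobile_fraction: float = 130 / 300,
                         ) -> dict[tuple[str, ...], int]:
    """Shrink (or keep) the default Venn-region structure to fit a reference.

    Region sizes are scaled proportionally so the mobile union is about
    ``mobile_fraction`` of the reference, using largest-remainder rounding;
    at the default 300-transcript scale this returns the base structure
    unchanged.
    """
    if base is None:
        base = DEFAULT_TRUTH_REGIONS
    total = sum(base.values())
    target = min(total, max(1, round(n_transcripts * mobile_fraction)))
    quotas = {k: v * target / total for k, v in base.items()}
    sizes = {k: int(q) for k, q in quotas.items()}
    remainder = target - sum(sizes.values())
    by_frac = sorted(base, key=lambda k: (quotas[k] - sizes[k], base[k]),
                     reverse=True)
    for k in by_frac[:remainder]:
        sizes[k] += 1
    return {k: v for k, v in sizes.items() if v > 0}


def replicate_seed(master_seed: int, condition: str, replicate: int,
                   grafted: bool = True) -> int:
    """Stable, documented per-sample seed: CRC32 of the sample coordinates."""
    tag = f"{master_seed}:{condition}:{replicate}:{int(grafted)}"
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


def generate_ancestor(config: SimConfig) -> TranscriptSet:
    """Generate the ancestral reference transcript set.

    Each transcript is a single clean ORF: ATG, uniformly drawn sense
    codons, and a TAA stop, with total length as close to uniform over
    ``length_range`` as the codon structure allows.  Deterministic for a
    fixed ``master_seed``.
    """
    rng = np.random.default_rng(config.master_seed)
    lo, hi = config.length_range
    lo_codons = max(3, -(-lo // 3))  # ceil; >= ATG + 1 codon + stop
    hi_codons = max(lo_codons, hi // 3)
    records: dict[str, str] = {}
    width = max(4, len(str(max(config.n_transcripts, 1))))
    for i in range(config.n_transcripts):
        n_codons = int(rng.integers(lo_codons, hi_codons + 1))
        body = rng.integers(0, len(_SENSE), size=n_codons - 2)
        seq = "ATG" + "".join(_SENSE[j] for j in body) + "TAA"
        records[f"t{i:0{width}d}"] = seq
    return TranscriptSet(species_id="ancestor", records=records)


def _substitute(seq_list: list[str], pos: int, rng: np.random.Generator) -> None:
    """Substitute the base at ``pos``, avoiding in-frame stop creation."""
    old = seq_list[pos]
    codon_start = (pos // 3) * 3
    choices = []
    for b in _BASES:
        if b == old:
            continue
        codon = "".join(seq_list[codon_start : codon_start + 3])
        k = pos - codon_start
        new_codon = codon[:k] + b + codon[k + 1 :]
        if len(new_codon) == 3 and new_codon in _STOPS:
            continue
        choices.append(b)
    if choices:
        seq_list[pos] = choices[int(rng.integers(0, len(choices)))]


def _mutate_lineage(seq: str, sub_rate: float, indel_rate: float,
                    rng: np.random.Generator) -> str:
    chars = list(seq)
    n = len(chars)
    if sub_rate > 0:
        hits = np.flatnonzero(rng.random(n) < sub_rate)
        for pos in hits:
            _substitute(chars, int(pos), rng)
    if indel_rate > 0:
        n_indels = rng.binomial(n, indel_rate)
        for _ in range(n_indels):
            n_codons = len(chars) // 3
            if n_codons <= 4:
                break
            ci = int(rng.integers(1, n_codons - 1))  # keep start/stop codons
            at = ci * 3
            if rng.random() < 0.5:
                del chars[at : at + 3]
            else:
                codon = _SENSE[int(rng.integers(0, len(_SENSE)))]
                chars[at:at] = list(codon)
    return "".join(chars)


def diverge(ancestor: TranscriptSet, config: SimConfig) -> tuple[TranscriptSet, TranscriptSet]:
    """Split the ancestor into (scion, rootstock) lineages.

    Each lineage independently receives substitutions at ``divergence/2``
    per site and in-frame 3-bp indels at ``indel_rate/2`` per site, so the
    expected pairwise substitution divergence between the lineages is
    approximately ``divergence``.  Transcript ids are preserved in both
    lineages; the id correspondence is the true orthology.
    """
    if len(ancestor) == 0:
        raise ValueError("ancestor transcript set is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 0xD1]))
    out: list[dict[str, str]] = []
    for _lineage in ("scion", "rootstock"):
        recs = {
            tid: _mutate_lineage(seq, config.divergence / 2.0,
                                 config.indel_rate / 2.0, rng)
            for tid, seq in ancestor
        }
        out.append(recs)
    scion = TranscriptSet(species_id="scion", records=out[0])
    rootstock = TranscriptSet(species_id="rootstock", records=out[1])
    return scion, rootstock


def assign_truth(scion: TranscriptSet,
                 region_sizes: dict[tuple[str, ...], int] | None = None,
                 seed: int = 0) -> SimTruth:
    """Sample disjoint Venn regions of mobile transcripts over the conditions.

    ``region_sizes`` maps a condition subset (tuple of condition labels) to
    the number of transcripts mobile in exactly those conditions.  Sampling
    is without replacement from the scion ids, so regions are disjoint and
    the union size equals the sum of region sizes.
    """
    if region_sizes is None:
        region_sizes = DEFAULT_TRUTH_REGIONS
    for key in region_sizes:
        bad = set(key) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions in region key: {sorted(bad)}")
    total = sum(region_sizes.values())
    if total > len(scion):
        raise ValueError(
            f"truth regions need {total} transcripts but scion has {len(scion)}"
        )
    rng = np.random.default_rng(seed)
    ids = np.array(scion.ids)
    chosen = rng.choice(len(ids), size=total, replace=False)
    mobile: dict[str, set[str]] = {c: set() for c in CONDITIONS}
    cursor = 0
    for key in sorted(region_sizes, key=lambda k: (len(k), k)):
        size = region_sizes[key]
        members = ids[chosen[cursor : cursor + size]]
        cursor += size
        for cond in key:
            mobile[cond].update(members.tolist())
    return SimTruth(mobile_by_condition=mobile)


def _sequence_pairs(seq: str, tid: str, origin: str, n_pairs: int,
                    condition: str, replicate: int, serial_start: int,
                    config: SimConfig, rng: np.random.Generator,
                    reads1: list[FastqRead], reads2: list[FastqRead]) -> int:
    """Append ``n_pairs`` read pairs drawn from ``seq``; return next serial."""
    L = config.read_length
    ilo, ihi = config.insert_range
    qual = "I" * L
    serial = serial_start
    for _ in range(n_pairs):
        read_through = rng.random() < config.adapter_fraction
        if read_through:
            insert = int(rng.integers(40, L))
        else:
            insert = int(rng.integers(ilo, ihi + 1))
        insert = min(insert, len(seq))
        pos = int(rng.integers(0, len(seq) - insert + 1))
        frag = seq[pos : pos + insert]
        if insert >= L:
            m1 = frag[:L]
            m2 = revcomp(frag[-L:])
        else:
            fill = (config.adapter * ((L // len(config.adapter)) + 2))[: L - insert]
            m1 = frag + fill
            m2 = revcomp(frag) + fill
        m1 = _apply_errors(m1, config.error_rate, rng)
        m2 = _apply_errors(m2, config.error_rate, rng)
        name = f"{tid}:{origin}:{condition}:{replicate}:{serial}:{pos}"
        reads1.append(FastqRead(name, m1, qual))
        reads2.append(FastqRead(name, m2, qual))
        serial += 1
    return serial


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=k, replace=False)
    for pos in positions:
        old = chars[pos]
        alts = [b for b in _BASES if b != old]
        chars[pos] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_sample(rootstock: TranscriptSet, scion: TranscriptSet,
                    truth: SimTruth, condition: str, replicate: int,
                    config: SimConfig, grafted: bool = True,
                    rrna: TranscriptSet | None = None,
                    ) -> tuple[list[FastqRead], list[FastqRead]]:
    """Simulate one rootstock-tissue RNA-seq sample as paired reads.

    Grafted samples contain pairs from every rootstock transcript at mean
    depth ``config.depth`` plus pairs from the condition's true mobile scion
    transcripts at ``depth * mobile_abundance_factor``; non-grafted controls
    contain rootstock pairs only.  Mate 1 is sense-strand, mate 2 the reverse
    complement of the fragment end (dUTP-like stranded protocol).  rRNA
    contaminant pairs and adapter read-through pairs are injected at the
    configured fractions.  Each read name encodes
    ``source_id:origin:condition:replicate:serial:position``.
    """
    if len(rootstock) == 0 or len(scion) == 0:
        raise ValueError("reference transcript sets must be non-empty")
    if condition not in truth.condition_list:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(
        replicate_seed(config.master_seed, condition, replicate, grafted))
    L = config.read_length
    reads1: list[FastqRead] = []
    reads2: list[FastqRead] = []
    serial = 0
    expected_pairs = 0.0
    for tid, seq in rootstock:
        if len(seq) < L:
            logger.warning("rootstock transcript %s shorter than read length; skipped", tid)
            continue
        n = int(rng.poisson(config.depth))
        expected_pairs += config.depth
        serial = _sequence_pairs(seq, tid, "rootstock", n, condition, replicate,
                                 serial, config, rng, reads1, reads2)
    if grafted:
        mobile_depth = config.depth * config.mobile_abundance_factor
        for tid in sorted(truth.mobile_by_condition[condition]):
            seq = scion[tid]
            if len(seq) < L:
                logger.warning("scion transcript %s shorter than read length; skipped", tid)
                continue
            n = int(rng.poisson(mobile_depth))
            serial = _sequence_pairs(seq, tid, "scion", n, condition, replicate,
                                     serial, config, rng, reads1, reads2)
    if rrna is not None and config.rrna_fraction > 0 and len(rrna) > 0:
        n_contam = int(rng.poisson(config.rrna_fraction * max(expected_pairs, 1.0)))
        rrna_ids = [tid for tid, s in rrna if len(s) >= L]
        for _ in range(n_contam):
            tid = rrna_ids[int(rng.integers(0, len(rrna_ids)))]
            serial = _sequence_pairs(rrna[tid], tid, "rrna", 1, condition,
                                     replicate, serial, config, rng, reads1, reads2)
    return reads1, reads2


def parse_read_name(name: str) -> dict:
    """Decode the truth bookkeeping carried in a simulated read name."""
    src, origin, condition, replicate, serial, pos = name.rsplit(":", 5)
    return {
        "source_id": src,
        "origin": origin,
        "condition": condition,
        "replicate": int(replicate),
        "serial": int(serial),
        "position": int(pos),
    }


def generate_proteomes(scion: TranscriptSet, rootstock: TranscriptSet,
                       ) -> tuple[TranscriptSet, TranscriptSet]:
    """Translate both transcript sets (frame 0, standard code, stop-truncated)."""
    out = []
    for tset in (scion, rootstock):
        recs = {}
        for tid, seq in tset:
            if len(seq) < 3:
                raise ValueError(f"{tid!r} too short to translate")
            trimmed = seq[: len(seq) - len(seq) % 3]
            prot = str(Seq(trimmed).translate(table=1, to_stop=True))
            if prot:
                recs[tid] = prot
        out.append(TranscriptSet(species_id=f"{tset.species_id}_protein",
                                 records=recs, alphabet=None))
    return out[0], out[1]


def generate_rrna(n: int = 4, length: int = 1800, seed: int = 7) -> TranscriptSet:
    """Random rRNA surrogate references for the contamination filter."""
    rng = np.random.default_rng(seed)
    recs = {
        f"rrna{i}": "".join(_BASES[j] for j in rng.integers(0, 4, size=length))
        for i in range(n)
    }
    return TranscriptSet(species_id="rrna", records=recs)
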