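"""End-to-end orchestration: QC -> rootstock map -> control match -> scion map
-> replicate-based mobile calling.

Two entry points:

* :func:`run_pipeline` — file-based: reads references, an rRNA set and a
  sample manifest from disk, writes per-stage artifacts and a run manifest.
* :func:`run_synthetic_experiment` — in-memory: generates a full synthetic
  heterograft experiment from a :class:`~graftmobile.simulate.SimConfig`,
  runs the same stages, and scores the calls against the simulation truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import align, mobile, qc, simulate
from .seqio import TranscriptSet, read_fasta, read_fastq
from .simulate import CONDITIONS, SimConfig, SimTruth

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "run_pipeline",
    "SyntheticRun",
    "run_synthetic_experiment",
    "recall_precision",
]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """All paths and thresholds of a file-based run, in one audited place."""

    rootstock_fasta: str
    scion_fasta: str
    samples_manifest: str
    rrna_fasta: str | None = None
    outdir: str = "graftmobile_out"
    min_length: int = 40
    rrna_max_mismatch: int = 3
    root_max_edit: int = 2
    scion_max_edit: int = 1
    min_replicates: int = 2
    min_pairs: int = 1
    k: int = align.DEFAULT_K
    step: int = align.DEFAULT_STEP
    insert_bounds: tuple[int, int] = (40, 600)
    adapter: str = simulate.TRUSEQ_ADAPTER
    quality_threshold: int = 20
    quality_window: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        if "insert_bounds" in data:
            data["insert_bounds"] = tuple(data["insert_bounds"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def validate(self) -> None:
        for name in ("rootstock_fasta", "scion_fasta", "samples_manifest"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigError(f"{name}: path {p!r} does not exist")
        if self.rrna_fasta is not None and not Path(self.rrna_fasta).exists():
            raise ConfigError(f"rrna_fasta: path {self.rrna_fasta!r} does not exist")
        if self.min_length < 1 or self.min_replicates < 1 or self.min_pairs < 1:
            raise ConfigError("min_length, min_replicates, min_pairs must be >= 1")
        for name in ("rrna_max_mismatch", "root_max_edit", "scion_max_edit"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.insert_bounds
        if not 0 < lo <= hi:
            raise ConfigError("insert_bounds must satisfy 0 < lo <= hi")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_manifest(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as handle:
        header = None
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["condition", "replicate", "grafted", "fastq1", "fastq2"]
                if header != expected:
                    raise ConfigError(
                        f"{path}: manifest header must be {expected}, got {header}")
                continue
            if len(fields) != 5:
                raise ConfigError(f"{path}:{lineno}: expected 5 columns")
            rows.append({
                "condition": fields[0],
                "replicate": int(fields[1]),
                "grafted": fields[2].lower() in ("1", "true", "yes"),
                "fastq1": fields[3],
                "fastq2": fields[4],
            })
    if not rows:
        raise ConfigError(f"{path}: manifest lists no samples")
    return rows


def _qc_sample(pairs: list[qc.ReadPair], config: PipelineConfig,
               rrna: TranscriptSet | None) -> tuple[list[qc.ReadPair], list]:
    params = qc.TrimParams(adapter=config.adapter,
                           quality_threshold=config.quality_threshold,
                           window=config.quality_window,
                           min_length=config.min_length)
    return qc.qc_pairs(pairs, params, rrna=rrna,
                       rrna_max_mismatch=config.rrna_max_mismatch)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full cascade on files; returns the run manifest dict.

    Stage order is fixed: trim -> rRNA filter -> rootstock mapping ->
    control subtraction -> scion mapping -> replicate calling.  Outputs
    (mobile call table, per-condition id lists, stage counts, manifest)
    are written under ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rootstock = read_fasta(config.rootstock_fasta, species_id="rootstock")
    scion = read_fasta(config.scion_fasta, species_id="scion")
    rrna = (read_fasta(config.rrna_fasta, species_id="rrna")
            if config.rrna_fasta else None)
    manifest_rows = _read_manifest(config.samples_manifest)
    for row in manifest_rows:
        for key in ("fastq1", "fastq2"):
            if not Path(row[key]).exists():
                raise ConfigError(f"sample file {row[key]!r} does not exist")

    root_index = align.build_index(rootstock, k=config.k, step=config.step)
    scion_index = align.build_index(scion, k=config.k, step=config.step)

    stage_counts: dict[str, dict] = {}
    control_reads = []
    grafted_samples: dict[tuple[str, int], list[qc.ReadPair]] = {}
    for row in manifest_rows:
        sample = qc.Sample(row["condition"], row["replicate"], row["grafted"])
        pairs = qc.pair_reads(read_fastq(row["fastq1"]), read_fastq(row["fastq2"]),
                              sample)
        kept, log = _qc_sample(pairs, config, rrna)
        tag = f"{row['condition']}/r{row['replicate']}/" \
              f"{'grafted' if row['grafted'] else 'control'}"
        stage_counts[tag] = {
            "input_pairs": len(pairs),
            "qc_pairs": len(kept),
            "discarded_short": sum(1 for _, r in log if r == "short"),
            "discarded_rrna": sum(1 for _, r in log if r == "rrna"),
        }
        if row["grafted"]:
            grafted_samples[(row["condition"], row["replicate"])] = kept
        else:
            for p in kept:
                control_reads.extend((p.mate1, p.mate2))
    control_set = mobile.build_control_set(control_reads)

    classified: dict[tuple[str, int], list[mobile.ClassifiedPair]] = {}
    for key, pairs in grafted_samples.items():
        cps = mobile.classify_sample(
            pairs, root_index, rootstock, scion_index, scion, control_set,
            root_max_edit=config.root_max_edit,
            scion_max_edit=config.scion_max_edit,
            insert_bounds=config.insert_bounds)
        classified[key] = cps
        tag = f"{key[0]}/r{key[1]}/grafted"
        counts = {label: 0 for label in mobile.LABELS}
        for cp in cps:
            counts[cp.label] += 1
        stage_counts[tag].update(counts)

    scion_lengths = {tid: len(seq) for tid, seq in scion}
    table = mobile.call_mobile(classified, scion_lengths,
                               min_replicates=config.min_replicates,
                               min_pairs=config.min_pairs)
    sets = mobile.condition_sets(table)

    table.to_frame().to_csv(outdir / "mobile_calls.tsv", sep="\t", index=False)
    for cond in table.conditions:
        with open(outdir / f"mobile_{cond}.txt", "w") as handle:
            for tid in sorted(sets[cond]):
                handle.write(tid + "\n")
    manifest = {
        "config_hash": config.config_hash(),
        "config": {k: str(v) for k, v in config.__dict__.items()},
        "stage_counts": stage_counts,
        "n_control_reads": len(control_set),
        "mobile_per_condition": {c: len(sets[c]) for c in table.conditions},
        "mobile_union": len(sets["union"]),
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


@dataclass
class SyntheticRun:
    """Everything produced by one in-memory synthetic experiment."""

    config: SimConfig
    scion: TranscriptSet
    rootstock: TranscriptSet
    rrna: TranscriptSet
    truth: SimTruth
    classified: dict[tuple[str, int], list[mobile.ClassifiedPair]]
    table: mobile.MobileCallTable
    sets: dict[str, set[str]]
    stage_counts: dict = field(default_factory=dict)

    def metrics(self) -> dict[str, dict[str, float]]:
        return recall_precision(self.sets, self.truth)


def recall_precision(called_sets: dict[str, set[str]], truth: SimTruth,
                     ) -> dict[str, dict[str, float]]:
    """Per-condition recall and precision of called mobile sets vs truth."""
    out = {}
    for cond in truth.condition_list:
        true_ids = truth.mobile_by_condition[cond]
        called = called_sets.get(cond, set())
        tp = len(called & true_ids)
        out[cond] = {
            "recall": tp / len(true_ids) if true_ids else 1.0,
            "precision": tp / len(called) if called else 1.0,
            "n_true": len(true_ids),
            "n_called": len(called),
        }
    return out


def run_synthetic_experiment(config: SimConfig,
                             truth_regions: dict | None = None,
                             conditions: tuple[str, ...] = CONDITIONS,
                             rrna: TranscriptSet | None = None,
                             ) -> SyntheticRun:
    """Generate a synthetic heterograft experiment and run the full cascade.

    Control samples (one per replicate, non-grafted) provide the
    perfect-match subtraction set; grafted samples are simulated for every
    condition x replicate and classified against the generated references.
    """
    ancestor = simulate.generate_ancestor(config)
    scion, rootstock = simulate.diverge(ancestor, config)
    if rrna is None:
        rrna = simulate.generate_rrna(seed=config.master_seed + 101)
    truth = simulate.assign_truth(scion, truth_regions, seed=config.master_seed)

    trim = qc.TrimParams(adapter=config.adapter, min_length=40)
    stage_counts: dict[str, dict] = {}

    control_reads = []
    for rep in range(1, config.n_replicates + 1):
        r1, r2 = simulate.simulate_sample(rootstock, scion, truth, "full", rep,
                                          config, grafted=False, rrna=rrna)
        sample = qc.Sample("full", rep, grafted=False)
        kept, log = qc.qc_pairs(qc.pair_reads(r1, r2, sample), trim, rrna=rrna)
        stage_counts[f"control/r{rep}"] = {"input_pairs": len(r1), "qc_pairs": len(kept)}
        for p in kept:
            control_reads.extend((p.mate1, p.mate2))
    control_set = mobile.build_control_set(control_reads)

    root_index = align.build_index(rootstock)
    scion_index = align.build_index(scion)

    classified: dict[tuple[str, int], list[mobile.ClassifiedPair]] = {}
    for cond in conditions:
        for rep in range(1, config.n_replicates + 1):
            r1, r2 = simulate.simulate_sample(rootstock, scion, truth, cond, rep,
                                              config, grafted=True, rrna=rrna)
            sample = qc.Sample(cond, rep, grafted=True)
            kept, log = qc.qc_pairs(qc.pair_reads(r1, r2, sample), trim, rrna=rrna)
            cps = mobile.classify_sample(kept, root_index, rootstock,
                                         scion_index, scion, control_set)
            classified[(cond, rep)] = cps
            counts = {label: 0 for label in mobile.LABELS}
            for cp in cps:
                counts[cp.label] += 1
            stage_counts[f"{cond}/r{rep}"] = {
                "input_pairs": len(r1), "qc_pairs": len(kept), **counts}

    scion_lengths = {tid: len(seq) for tid, seq in scion}
    table = mobile.call_mobile(classified, scion_lengths)
    sets = mobile.condition_sets(table)
    return SyntheticRun(config=config, scion=scion, rootstock=rootstock,
                        rrna=rrna, truth=truth, classified=classified,
                        table=table, sets=sets, stage_counts=stage_counts)
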