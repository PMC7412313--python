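# Methods

## The inference problem

A heterograft joins a scion (shoot) of one species to the rootstock of
another. RNA-seq of rootstock tissue then contains an overwhelming majority
of rootstock transcripts, a background of sequences shared between the
species, and — the signal of interest — a small population of reads from
scion transcripts that travelled down the phloem. The classifier must
attribute each read pair to one species although the two transcriptomes are
~96% identical, which is why the decision is made on *edit-distance
asymmetry*: a read is accepted as transmitted only if it fails to align to
the rootstock within 2 edits per mate, fails to match any read from
non-grafted control plants exactly, and then aligns to the scion within
1 edit per mate as a proper pair. An 85-bp read from a 4%-divergent region
carries ~3.4 cross-species differences in expectation, so true scion reads
usually fail the rootstock cap while passing the scion cap; the
perfect-match control subtraction removes reads from sequence identical
between the species or shared contaminants.

A scion transcript is *detected* in a replicate when at least `min_pairs`
(default 1) transmitted pairs are assigned to it, and called **mobile** in
a growth condition when detected in at least `min_replicates` of the
replicates (default 2 of 3). Calling is at the transcript-id level of the
scion reference; no gene-level collapsing is performed. Abundance is
RPKM = 10⁹·c/(L·M) with c assigned pairs, L the transcript length in bp and
M the sample's mapped pairs (rootstock-proper plus transmitted).

## Aligner

The mapper is a seed-and-verify end-to-end (global in the read) aligner
under a hard Levenshtein cap; "edit" counts substitutions and indels alike.

* **Index**: every reference k-mer starting at a position divisible by
  `step` (defaults k = 15, step = 5).
* **Seeding**: all read k-mers (both strands) are looked up. A read of
  length L with e edits contains a clean segment of length
  ≥ ⌈(L−e)/(e+1)⌉; for L = 85, e ≤ 2 that is 28 ≥ k + step − 1 = 19, so an
  exact seeded k-mer always survives and seeding is lossless at the
  cascade's caps.
* **Verification**: candidate starts within `max_edit` of a seeded diagonal
  are scored exactly by a vectorised free-start semiglobal DP over the
  reversed strings, which yields, for every start s, the minimum edit
  distance over all window ends. All placements with distance ≤ `max_edit`
  are reported; CIGARs come from a banded anchored DP with traceback
  (band half-width = `max_edit`), computed lazily because the cascade needs
  only distances. A Hamming fast path accepts substitution-only placements
  with distance ≤ 1 directly (provably optimal: a distance-0 placement
  elsewhere would carry its own seeds).
* **Proper pair**: both mates on the same target, opposite strands, implied
  insert within `insert_bounds` (default 40–600 bp), each mate within the
  cap. Minimal summed edit wins; ties break by (target id, leftmost forward
  start) and all targets tied at the minimum are recorded so that ambiguous
  transmitted evidence counts toward every tied transcript (flagged
  ambiguous).

## Read QC

The trimming parameters are declared defaults, not inferred values: 3′
adapter removal accepts the leftmost position where the read suffix matches
the adapter prefix with ≤ 10% mismatches (minimum overlap 3); quality
clipping scans 4-base windows and cuts at the start of the first window
with mean quality < 20; mates trimmed below 40 bases discard the whole
pair, preserving pairing downstream. The rRNA screen is substitution-only
by design (a mismatch cap, not an edit cap): a pair is discarded when
either mate matches an rRNA reference end-to-end with ≤ 3 mismatches at any
offset on either strand, implemented completely via pigeonhole-seeded
candidate offsets (a read with ≤ 3 mismatches has a clean quarter, whose
leading 10-mer indexes the placement).

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes,
not the biology of any particular transcriptome:

* **References**: ancestral transcripts are single clean ORFs (ATG, uniform
  sense codons, TAA) with lengths ~uniform on 500–2000 bp. Two lineages
  receive independent substitutions at `divergence/2` per site (default
  divergence 0.04) and in-frame 3-bp indels at `indel_rate/2` (default
  0.0005). Substitutions that would create an in-frame stop codon are
  resampled to another base: nonsense mutations are strongly purged in real
  coding orthologs, and coding-intact references are what makes the derived
  proteomes usable by the orthology stage. Realised nucleotide divergence
  still converges to the target (checked against a binomial oracle at 3
  standard errors).
* **Reads**: stranded 85-bp pairs (mate 1 sense, mate 2 reverse-complement
  of the fragment end, dUTP-like); fragment length uniform on 150–400 bp;
  per-base substitution errors at `error_rate` (default 0.005); adapter
  read-through pairs (insert < read length, default 1%) and rRNA
  contaminant pairs (default 2%) injected. Per-transcript pair counts are
  Poisson with mean `depth` (default 30) for rootstock transcripts and
  `depth × mobile_abundance_factor` (default 2/3, i.e. mean 20) for the
  condition's mobile scion transcripts — mobile mRNAs arrive at the root in
  low abundance, and their true abundance there is a free parameter of the
  simulation. Non-grafted control samples contain rootstock reads only.
* **Truth**: mobile transcripts are drawn without replacement into disjoint
  Venn regions over the four conditions (full, lowN, lowP, lowFe). The
  default structure plants 130 mobile transcripts out of 300, with a
  112-like core mobile under all conditions scaled to 37 and sizeable
  condition-specific regions — the qualitative shape of the real
  experiment at desk scale.
* **Bookkeeping**: every read name encodes
  `source:origin:condition:replicate:serial:position`, so any downstream
  stage can be scored exactly. Per-sample RNG seeds are CRC32 hashes of
  (master seed, condition, replicate, grafted), making every FASTQ
  byte-reproducible.

What the generator does **not** emulate: splice isoforms, PCR duplicates,
GC and positional coverage bias, quality-score decay, and real paralog
structure (ancestral transcripts are unrelated, so multi-mapping is rare).
Passing the recovery tests therefore shows the cascade's logic is correct
under its stated assumptions, not that real libraries are free of
artefacts these factors can cause.

## Orthology

The primary input is precomputed 12-column tabular protein hits, reduced to
the best HSP per (query, subject) by bit score then E-value. Best hits per
query require E strictly < 10⁻⁵ and break ties by bit score, E-value, then
lexicographic subject id; reciprocal best hits form the ortholog pairs (a
partial matching by construction). The internal scorer exists so synthetic
tests need no external search tool: Smith–Waterman with affine gaps
(BLOSUM62, open 11, extend 1; a length-g gap costs 11 + g), bit scores from
fixed published ungapped Karlin–Altschul constants (λ = 0.3176, K = 0.134),
and E = m·n·2^(−bits) with n the total subject-set residues. These E-values
are approximate (no finite-size edge correction) but strictly monotone in
score, which is all that best-hit ranking and the cutoff require. An exact
BLAST-like word prefilter (shared 6-mer) limits Smith–Waterman to candidate
pairs.

## Set statistics

The hypergeometric test reports both one-sided tails, P(X ≥ k) and
P(X ≤ k) (they share the point mass at k), the direction with the smaller
tail, and min(p_over, p_under) as the reported p-value; tails are computed
by log-gamma accumulation via `scipy.stats.hypergeom` and verified against
exhaustive draw enumeration for every parameter combination with N ≤ 12.
The universe size N is always an explicit argument — it is not derivable
from the id lists, and for cross-system comparisons must be supplied by the
caller (e.g. the ortholog-pair count); within-system analyses naturally use
the scion reference size. Covered % is 100·k/K rounded half-up to two
decimals. Venn partitions support 2–4 named sets, matching the arity of the
standard figures.

## Numerical and design choices

* Coordinates are 0-based half-open internally; 1-based in SAM-like export.
* Pair-level semantics throughout the cascade: a pair escapes the rootstock
  stage unless it is a *proper pair* there, and transmitted status likewise
  requires a proper scion pair — single-mate hits neither capture nor
  rescue a pair. Control matching is pair-level on either mate, in either
  orientation, by exact string equality (no alignment).
* Degenerate inputs: an empty rRNA set filters nothing; an empty control
  set matches nothing; transcripts shorter than the read length are skipped
  with a warning by the simulator; reads shorter than k return no
  alignments with a warning.
* Default problem sizes (300 + 300 transcripts, 4 conditions × 3
  replicates, depth 30, ~150 k read pairs overall) were chosen as the
  smallest experiment in which every analytical feature — divergence
  escape, control subtraction, replicate logic, Venn structure — is
  exercised with comfortable statistical margins.

## Limitations

* The aligner is transcript-level and unspliced; genomic features
  (introns, intergenic reads) are out of scope.
* Mobile calls are presence/absence per replicate; no differential
  abundance testing between conditions is performed, and transcript
  integrity (full-length transport) is not assessed.
* The internal protein scorer's E-values are approximations; when a real
  search tool's tabular output is available it should be preferred.
* Published p-values from cross-study tables cannot be recomputed without
  the original universe sizes, which those tables do not state; only the
  coverage arithmetic is reproduced.
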