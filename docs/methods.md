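# Methods

## Model and procedure

The pipeline treats integration-site discovery as split-read breakpoint
detection against a composite reference: the host genome assembly plus the
linearized vector appended as one extra scaffold. A read spanning a
vector–genome junction yields a chimeric alignment — a primary record on
one reference with the partner placement encoded in the `SA:Z` tag
(`rname,pos,strand,CIGAR,mapQ,NM;`, the BWA-MEM dialect). Detection is
purely positional: no re-alignment, assembly, or sequence inspection is
performed, so the caller is fast and deterministic but cannot resolve
junctions whose vector half maps ambiguously (duplicated vector elements)
or structures beyond a single clean junction (concatemers, complex
rearrangements). Those limits are intrinsic to split-read mapping, not to
this implementation.

### Junction coordinates

All coordinates are 1-based inclusive (SAM convention), stated in every
output header; BED output converts to 0-based half-open at write time.
For each alignment half the junction is derived from its CIGAR:

* clip first → the reported position is the first aligned base and is the
  junction;
* aligned bases first → junction = `pos + reference_span(CIGAR)`, where
  the reference span counts all reference-consuming operations
  (M, D, N, =, X), not just the leading match. A deletion inside the
  aligned block shifts the reference coordinate, and counting only M would
  mis-place gapped split alignments by the deletion length.

The clipped end of each half (the larger clip, when both ends are clipped)
is taken as the side facing the partner reference; an alignment with no
clipped end is inconsistent with split-read evidence and raises an error.

### Filters and support

Both halves of a split alignment must pass MAPQ > 30 and NM < 4 (strict
inequalities). Applying the filter to both halves is deliberately
conservative: spurious chimeras are usually low-quality on exactly one
side. A record without an NM tag fails the filter — the filter is explicit
and absence is not evidence of zero mismatches. Secondary alignments
(flag 0x100) are ignored; supplementary records (0x800) are processed, but
because supporters are a *set of query names* they can never add support
beyond their primary. The same mechanism implements the pair rule: both
mates of a pair supporting one junction count once. Duplicate-flagged
records (0x400) are skipped by default; duplicate detection itself is an
upstream responsibility (the flag is the contract).

A junction becomes an integration site at support ≥ `min_support`
("a minimum of N reads or pairs" is read inclusively): 15 in the `deep`
profile (a single deeply sequenced sample) and 5 in the `multiplex`
profile (dozens of barcoded samples pooled on one run, each with a small
library). `merge_window` (default 0, i.e. exact-position tabulation of
unique junctions) optionally merges candidates on the same scaffold and
vector end within the window before thresholding, for aligners that
scatter a junction over ±a few bp through microhomology; the merged
position is the support-weighted mode, ties to the smallest coordinate.

### Vector-end labeling

Each junction is labeled by which terminus of the linearized vector abuts
the genome: vector-side junction coordinate in the lower half of the
vector → `left`, else `right`. One insertion can therefore appear as up to
two called sites (its two ends), tens of bp apart on the genome.

### Capture statistics

Unique read pairs (duplicates excluded) are partitioned into
vector-touching (any mate's primary or SA alignment on the vector
scaffold), genome-only, and unmapped; the partition is exact and order-
independent. Percent on-target and the enrichment ratio
(vector / non-vector) are computed over pairs, with read-level
counterparts reported alongside since both conventions appear in practice.
Orphan records are counted as single-read pairs with a warning. A zero
denominator yields 0 with an `undefined` flag (empty input) or an `inf`
sentinel (fully on-target library), serialized as the string `"inf"` in
JSON.

### Clonality

Two sites match when scaffold and vector end agree and positions differ by
at most `tolerance` (default 0 bp — junctions from the same lineage agree
at base resolution; the knob exists for noisier aligners). Pairwise
relations are identical / subset / partial / disjoint with Jaccard =
matched / (|A| + |B| − matched); matching within each (scaffold,
vector-end) stratum is the greedy sorted one-to-one matching, which is
optimal in one dimension. A subset relation does **not** break a clonality
verdict: it is reported as consistent-with-same-lineage, the
interpretation for a locus whose support fell just below threshold in one
sample. Lineages are connected components of the graph linking samples
with ≥ `min_shared` matched sites (default 1, the stated evidence
standard: even a single shared site is overwhelming evidence of common
origin). Within a sample, opposite vector ends within `end_pair_distance`
(default 500 bp, covering the observed ~30 bp and ~100 bp end
separations with margin) collapse to one locus, and further junctions
within `link_distance` (default 10 kbp, covering observed 1 kbp and
4.7 kbp cases) are flagged rearrangement/duplication-linked and excluded
from the independent-locus count while remaining in the site table.

## Synthetic data

The simulator emits alignments directly as SAM text — not FASTQ through a
real aligner — which keeps tests hermetic and byte-deterministic under a
seed. Per planted junction it writes the configured number of unique
junction-spanning pairs: mate 1 as a genome-side primary with a mutually
consistent vector-side SA tag plus the mirrored supplementary record
(complementary clip lengths, matching positions, MAPQ 60 and NM 0 unless
overridden per junction), mate 2 as a flanking genomic read. Flank
background pairs are placed at geometric distances from the junction
(`capture_decay`, default 0.01/bp), reproducing the decaying pileup that
capture produces around a junction; vector-internal, distant-genome and
unmapped pairs populate the other mapping categories; a configurable
fraction of pairs (default 0.1) is re-emitted duplicate-flagged; decoy
chimeras carry low MAPQ. Defaults mirror the multiplexed study design
(100 bp paired-end reads, ~250 bp fragments); the deep validation preset
uses 250 bp reads from ~500 bp fragments.

What the simulator does **not** model: real base content (sequences are
i.i.d. uniform, so there is no repeat structure, GC bias or mappability
variation), base-call errors and quality strings, concatemer structure,
and aligner behavior itself. The ambiguous-vector-half failure mode is
modeled abstractly by a `suppress_sa` flag (genome-side alignments emitted
without their SA tag), not at sequence level. Consequently, passing tests
demonstrate the *bookkeeping* of the pipeline — coordinate arithmetic,
filtering, support accounting, set comparison — under a faithful
alignment-level signature; they do not demonstrate robustness to real
aligner artifacts.

### Presets

Named presets emulate the study's integration structures on a shared
7-scaffold (50 kbp each) + 8 kbp-vector reference: `sh87` (three loci,
both vector ends each — six junctions, deep profile), `lineage_A` (one
locus, ends 30 bp apart), `lineage_B`/`lineage_D` (one end of one locus),
`lineage_C` (one called end plus a suppressed-SA second end < 50 bp away),
`lineage_E` (three loci on three scaffolds, ends 100 bp apart at one).
The `study` preset produces 32 multiplexed samples — 13 lineage-A sublines
plus a technical duplicate of A-1, 3 B, unrelated C-1 and D-1, and 13 E —
with per-sample support drawn from 8–18 pairs per junction, plus the
study-observed irregularities: an extra junction 1 kbp downstream in A-2,
4.7 kbp downstream in E-2/E-10, and a below-threshold (support 3) locus
end in E-1, whose site set is then a strict subset of its siblings'.

## Numerical and design choices

* Thresholds are inclusive (support ≥ N); MAPQ/NM filters strict
  (> 30, < 4), matching the published wording of each.
* CIGAR validation rejects interior clips, hard clips inside soft clips,
  and fully clipped alignments; `reference_span` itself accepts any op
  sequence (a fully clipped CIGAR spans 0 bases).
* Tie-breaks are everywhere deterministic: merge positions to the
  smallest coordinate, outputs sorted by (sample, scaffold, position,
  vector end), lineage groups sorted by first member.
* Genome strand is recorded and reported but excluded from the junction
  key: both read orientations observe the same physical junction.
* All randomness (simulator, sweeps) flows from explicit integer seeds;
  fixture and acceptance problem sizes (≤ 32 samples, ≤ 30 pairs per
  junction, a few thousand records) were chosen so the full structure of
  the study is represented while any run completes in seconds.

## Known limitations

Single-junction model only (no concatemer or copy-number inference);
BAM accepted but text SAM is the canonical tested surface; no barcode
demultiplexing (one SAM per sample is the contract); the collision
probability of independent integrations is asserted biologically, not
modeled probabilistically.
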