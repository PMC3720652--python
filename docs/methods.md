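# Methods

This note documents the models, procedures and numerical choices behind
gobylite, in the package's own terms.

## Chunked scatter/gather execution

Embarrassingly parallel analyses over a large input file are modelled as an
array job: the file is split into `n = ceil(file_size / chunk_size)` byte
chunks (default `chunk_size` = 50,000,000 bytes, configurable), and task
*i* (1-based) covers bytes `(i-1)*chunk_size .. i*chunk_size - 1`. The last
task's end offset is deliberately *not* clamped to `file_size - 1`: the
formula is uniform across tasks and readers simply stop at end-of-file.
A 30 GiB file therefore plans 645 tasks; a decimal 30 GB file plans 600.

A plugin implements four functions — plan a split, count chunks, process a
chunk, combine part results. The engine emulates the scheduler with a local
*thread* pool: plugins are arbitrary Python callables (often closures),
threads impose no picklability constraint, and chunk processing is
dominated by I/O. Determinism comes from combining parts in task-id order
regardless of completion order. A failed task produces a `failed`
TaskResult and a log event but never sinks the run; the combiner receives
the completed parts, so the output covers exactly the data that could be
processed. The run is marked failed only when no chunk completed.

Record-boundary rule for text formats: a record belongs to the chunk
containing its first byte. A worker whose chunk starts mid-record scans
forward to the next record boundary. For FASTQ the boundary heuristic is a
line starting with `@` whose second successor line starts with `+`; a
quality line may itself start with `@`, but it is always followed by a
header line and then a sequence line (which cannot start with `+`), so the
two-line lookahead disambiguates. For SAM, any non-header line is a record.
This yields a disjoint partition: concatenating per-chunk record sets
reproduces the file's record sequence byte-for-byte, which is the property
the test suite checks.

Recursive concatenation merges at most `fan_in` (default 100) parts at a
time, bounding simultaneously open parts; the result is invariant in
`fan_in` for any value ≥ 2.

Status events (`submitted`, `started`, `step`, `failed`, `completed`) are
appended to a JSON-lines log with non-decreasing timestamps; terminal
phases are mutually exclusive.

## Expression quantification

One primary alignment record is one fragment; secondary and supplementary
records are ignored, and each aligned mate counts once. A fragment is
assigned to every annotation its reference span overlaps by at least one
base (strand-blind by default, `stranded=True` available). Overlap queries
use an interval tree; the tests verify against a brute-force double loop.
Junction counts key each N (skip) CIGAR operation of a primary alignment by
its intron interval; a read spanning k junctions increments k counts.

RPKM is `r = (c + 1) / (L / 1000) / (N / 1e6)`; the +1 pseudocount keeps
log2(r) finite at zero counts. `N` is the total number of aligned fragments
("total") or the nearest-rank 75th percentile of the sample's *nonzero*
annotation counts ("upper-quartile"); restricting to nonzero counts keeps N
positive for sparse annotation sets, and the convention is part of the
output contract.

Heptamer priming-bias weights: the weight of a read starting with heptamer
h is `f_distal(h) / f_start(h)`, where `f_start` is h's frequency among
read-start heptamers and `f_distal` its frequency among heptamers starting
at 1-based positions 24–30 (configurable), pooled across reads. Reads
shorter than the window (36 bp at the default) get weight 1 with a warning.
Weighted counting replaces a fragment's contribution of 1 by its weight;
totals stay unweighted.

Differential expression between two groups: a two-sided Fisher exact test
on pooled raw integer counts against pooled totals (weighted counts are
refused here — exact tests need integers, so the unweighted table is passed
alongside), and a pooled-variance (classic Student, not Welch) t-test on
per-sample log2(RPKM). The t statistic is computed on the log scale because
the reported quantities are counts, RPKM and log2(RPKM), and the log scale
is the one on which the normality assumption is tenable. Groups with fewer
than 2 samples yield NaN, flagged missing rather than zero.
Benjamini–Hochberg adjustment is the standard step-up procedure (backed by
statsmodels; the test suite checks it against the raw definition).

## Bisulfite methylation

Bisulfite conversion turns unmethylated cytosine into uracil (read T);
methylated cytosine stays C. Calling is strand-aware: forward-strand
cytosines are reference C positions, informed by forward alignments (read
C → Cm, read T → Cu); reverse-strand cytosines are reference G positions,
informed by reverse alignments (read G → Cm, read A → Cu, in the forward
representation stored in SAM). Any other read base at a cytosine is
non-informative. Sites are emitted only where at least one informative
observation exists; the rate is `Cm / (Cm + Cu)` with no pseudocount, and
zero coverage is a no-call (NaN), never 0. Context (CpG/CHG/CHH) is
assigned from the reference sequence only and reported, not filtered on.
Duplicate reads are not collapsed (deduplication is protocol-dependent).

Region aggregation sums member-site counts per sample and recomputes the
rate from the sums (count-weighted, not a mean of rates); empty regions are
emitted with a no-call rate.

Differential methylation: within each comparison of the design (at most 10
groups, arbitrary pairs), counts are pooled by summing member samples, and
a two-sided Fisher exact test is applied to
`[[Cm_g1, Cu_g1], [Cm_g2, Cu_g2]]`. Sites with pooled coverage below
`min_coverage` (default 1) in either group are flagged missing and excluded
from the BH family; adjustment is applied per comparison across all tested
sites, so the family size equals the number of non-missing statistics.
Pooling groups rather than modelling per-sample variability is a count-based
reading: the exact test addresses sampling noise, not biological variation
(an explicitly known limitation of Fisher-based differential calls).

Output: VCF 4.1, one record per site, 1-based positions (internal
coordinates are 0-based half-open; conversions are tested both ways). REF
is the cytosine base (C forward, G reverse), genotype fields MR/MC/NC carry
the per-sample rate and counts, and INFO carries strand, context and
per-comparison p/q. Unsorted site tables are an error, never silently
reordered. Region output is a tab-delimited IGV track: chromosome, start,
end, feature, one rate column per sample.

## Pathogen screening

Unmapped reads are those with no aligned record; extraction preserves reads
file order and errors on any alignment id missing from the reads file.
Adapter trimming removes the longest read suffix exactly matching an
adapter prefix, but only when that overlap exceeds 4 bp — a 4 bp terminal
match is ignored, 5 bp is trimmed, with quality trimmed in lockstep.
Exact matching (no mismatches) is the default model. Assembly and database
search are out of scope; the module consumes 12-column tabular search
output. A match is annotated iff `alignment_length > 150` and
`evalue < 1e-6`, both strict, applied per match (per-HSP). The species
summary counts, per organism, distinct samples with at least one annotated
contig, sorted by that count then name.

## Simulator

The generators define the study conditions; all are bit-reproducible under
their seed.

* Genome: i.i.d. bases at a target GC fraction (default 0.5).
* Methylome: every cytosine on both strands draws an independent rate,
  uniform on [0, 1] by default.
* Bisulfite reads: single-end 36 bp reads (the read length of the RRBS-era
  datasets this models), starts uniform over the region, strands
  equiprobable, `n_reads = coverage * region_length / read_length`.
  `coverage` is *physical* coverage; because a cytosine is informative for
  one strand only, informative depth averages coverage/2 (≈25X at 50X,
  ≈125X at 250X). At each covered cytosine the emitted base stays
  unconverted with probability equal to the site's rate; unmethylated
  cytosines convert with probability `conversion_efficiency` (default 1.0).
  Sequencing error is off by default, available as a uniform substitution
  rate. Truth tallies record emitted informative bases exactly as a caller
  sees them (after any errors), so the conservation check — per-site
  (Cm+Cu) equality between caller and simulator — is exact by construction,
  and rate recovery can be judged against binomial sampling error. Emitted
  alignments are ungapped, MAPQ 60, coordinate-sorted SAM, so calling is
  testable without an aligner. The reference protocol uses a 100 kb region
  at 50X and 250X — large enough for ~50,000 cytosine sites while keeping
  the full simulate-and-call cycle under half a minute; larger regions are
  a parameter away.
* Count tables: per-gene lognormal baseline means (log-sd 0.5 around a
  100-fragment mean), gamma-Poisson (negative binomial) sampling with
  overdispersion `dispersion` (variance = m + d·m²). The default is the
  Poisson limit (d = 0): the Fisher test's null models technical counting
  noise only, so null calibration is performed in that regime; biological
  overdispersion is a parameter, not a default. With `effect_fold` = 1 no
  gene is flagged; otherwise a `de_fraction` subset carries the fold in a
  random direction.
* Contig matches: lengths and E-values drawn from pools straddling the
  annotation thresholds (148–152/300/500 bp; 1e-5..1e-8), with pass/fail
  truth recorded per match.

What the simulations do *not* emulate: paired-end reads, RRBS fragment
selection/MspI digestion, empirical error and quality profiles, mapping
ambiguity, and PCR duplicates. Passing recovery tests therefore
demonstrates correctness of the counting and estimation logic under ideal
placement, not robustness to alignment artefacts.

## Numerical choices and degenerate inputs

* Fisher exact tests use two-sided p-values; the test suite checks them
  against full fixed-margin hypergeometric enumeration.
* BH adjustment caps at 1 and enforces step-up monotonicity; empty families
  return empty results; p outside [0, 1] is an error.
* Upper-quartile normalization on an all-zero sample is an error (N would
  be 0), as is RPKM with non-positive L or N.
* `methylation_rate(0, 0)` is NaN; downstream writers emit `.` for it.
* Chunk plans for empty files have zero tasks; `recursive_concat` of a
  single part returns it unchanged without invoking the combiner.
* Run tags are 7 uppercase letters (26^7 ≈ 8×10^9 values), drawn from a
  seeded generator.
* Read QC assumes Phred+33 qualities; Phred+64 is a flag.

## Problem sizes used by the tests and the acceptance script

Scatter/gather fidelity runs on ~0.5–1 MB randomized FASTQ files with
32–64 KB chunks (dozens of chunks, same arithmetic as production sizes);
the Fisher oracle is enumerated exhaustively for row margins ≤ 10 plus
1,000 random tables with margins ≤ 30; null calibration uses 2,000 genes in
two groups of 3; methylation recovery uses the 100 kb / 50X / 250X
protocol. These sizes were chosen so a full verification cycle completes in
about a minute while every check remains a property of the algorithm, not
of the size.
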