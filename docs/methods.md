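# Methods

`ervprofiler` implements the computational readouts of a repeat-element
epigenomics study — ChIP-seq profiling of a repressive histone mark over
endogenous retrovirus (ERV) families and their genomic flanks, bisulphite
clone methylation analysis, and qPCR statistics — together with synthetic
data generators that carry ground truth for every stage.  This note records
the models, conventions, parameter choices and known limitations.

## Coordinate and format conventions

All internal coordinates are 0-based half-open.  SAM ingestion is the only
1-based boundary: POS is converted on the way in, FLAG bit 16 maps to
strand `-`, and the hit count is taken from an `NH:i:` tag when present.
Only M/=/X CIGAR operations are accepted; records with indel or clipping
operations are rejected loudly rather than mis-placed, consistent with the
gap-free aligner below.  BED6 annotations carry the family in the name
column and the copy's divergence in the score column.

## Minimal read aligner

`align_reads_minimal` enumerates every placement of each read on both
strands with Hamming distance ≤ `max_mismatches` (≤ 3) and keeps the
minimum-distance set; `n_hits` is the size of that set, and one placement
is chosen uniformly at random per read.  This deliberately omits gapped
alignment: the profiling logic under test concerns read placement, counting
and normalization, not indel handling, and the synthetic copies contain no
indels by construction.  A pigeonhole seed prefilter (`m+1` disjoint exact
seeds for ≤ `m` mismatches) makes the scan fast; it is lossless, and the
test suite checks exact agreement with an exhaustive per-position scan.

## Multi-mapper resolution

Reads with tied best placements (typically LTR-derived) are assigned one
location uniformly at random.  The RNG stream is keyed by `(seed, read id)`
(CRC32 of the id folded into the seed sequence), so the selection for a
given read is independent of the order reads are presented in — input
shuffling cannot change a profile.

## Consensus metaprofile

Reads are directionally extended at the 3' end by `extension` bp (default
150, so 50 bp reads give 200 bp footprints; an alternative reading —
total footprint of 150 bp — is rejected because it would truncate the
read's own 3' bases).  Footprints are clipped, never wrapped, at the
consensus ends.  Per-bin RPKM for a w-bp bin is

    mean per-base footprint depth × 1e9 / library_size

where `library_size` is the number of reads uniquely mapped to the genome.
This is the per-base-bin reading of "reads per kilobase per million mapped
reads"; it is isolated in `profile_consensus` and recorded in the profile's
JSON sidecar.  Condition comparison uses a pseudocount of 1e-6 × the larger
profile maximum to keep empty bins finite; the pseudocount is reported.

## Flank agglomeration

For each intact element, extended-read coverage in the ±`flank_size`
windows (default 7 kb) is mapped to element-relative coordinates; elements
on the minus strand are orientation-flipped (configurable) so the 5' flank
is biologically upstream.  Reads enter only after a strict quality filter
(quality > 7, not ≥), a uniqueness filter (`n_hits == 1`), and positional
deduplication on (chrom, start, strand) — the strand is part of the dedup
key because discarding coincident opposite-strand reads would lose signal
that independent fragments legitimately produce.  Dedup keeps a
deterministic representative (highest quality, fewest hits, smallest id) so
the operation is order-invariant, and it happens before agglomeration
because the counting rule concerns reads, not per-element contributions.
Footprint positions inside the element body are not counted.  Density is
double-normalized: by the number of included elements and by the total
number of genome-aligned reads per million.  Footprint coverage is the
default; read-start counting is available (`count_mode="start"`).

The intactness thresholds (minimum length, maximum divergence) are plain
user parameters — real catalogues derive them from family-specific curation
that has no analogue on synthetic data.

### Decay-scale estimation

`fit_flank_decay` bins the mean of the 5' and 3' density tracks by boundary
distance (default 250 bp bins) and fits `A·exp(-d/λ) + B` by least squares.
Bins closer than `min_distance` can be excluded: within one fragment length
of the boundary, footprint coverage mixes in fragments that start inside
the element body, which flattens the apparent decay; the standard study
excludes the first 200 bp (one fragment length) so the estimator sees the
pure exponential regime.  Positional deduplication slightly compresses the
densest near-element bins (an occupancy effect), leaving a small upward
bias (~5–10% at the standard study's depth) that the recovery tolerance
accommodates.

## Mappability

Position `p` is mappable for read length `k` when the k-mer starting at `p`
occurs exactly once in the genome over both strands.  Per-window means over
the flank windows verify that the synthetic flank profiles are not shaped
by alignability artefacts (they are ≈ 1.0 on random background).

## Bisulphite analysis

Clones are assumed to be the converted plus strand (C→T space); a strand
diagnostic (fraction of reference Gs read as A, over ≥ 5 informative
positions) rejects G→A clones.  Alignment is end-gap-free with mismatches
only; length mismatches error out rather than risking a shifted CpG
register.  At each reference CpG: C → methylated, T → unmethylated, other
→ missing; missing calls are excluded from both numerator and denominator
of the clone's methylated fraction.  The conversion rate is the fraction of
non-CpG reference Cs read as T among positions with an unambiguous C/T
base; the QC filter keeps clones with rate strictly above 0.98.  The
four-category report bins the methylated fraction into equal-width
quartiles [0, .25], (.25, .5], (.5, .75], (.75, 1] — the category bounds
are not standardized in the literature, so they are configurable and
printed with the output.

In-silico PCR enumerates loci where one primer matches one strand and the
other primer's reverse complement matches downstream within `max_product`,
each with ≤ `max_mismatches` mismatches, on both orientations, with
products deduplicated.

## qPCR statistics

ddCt assumes amplification efficiency 2.0 per cycle (primer efficiencies
~100%); per-primer efficiency correction is out of scope.  Replicate SDs
combine in Ct space as sqrt(sd_target² + sd_reference²) and map through
2^(−·) at mean ± sd (the reported fold SD is half the resulting range) —
the propagation rule is a package convention since figure legends report
"mean ± SD" without one.  ChIP enrichment is percent of input with an
optional input-fraction dilution correction, or the mark's percent-input
divided by pan-H3 percent-input at the same amplicon (both modes provided
because published enrichment panels use both conventions).  The t-test is
the classical pooled-variance Student statistic (Welch available), applied
to technical replicates as in the source figures — a statistical caveat
that is documented, not silently corrected; flags are `*` for p < 0.05 and
`**` for p < 0.01.  No multiple-testing adjustment is applied by default.

## Synthetic data model

Fragment starts are drawn from a per-base weight field: uniform background
(rate 1), plus `enrichment_fold × body_profile` through each copy's
coordinates (linearly — copies carry substitutions only, matching the
gap-free aligner), plus `enrichment_fold × exp(-d/λ)` at distance `d` from
the nearest element boundary.  The knockout condition multiplies the
element and flank terms by `ko_attenuation`.  The exponential flank form is
a modelling choice — the data it emulates show only a monotone decline —
chosen because it makes the decay scale an identifiable recovery target.
Each fragment (read length + extension, default 200 bp) yields one
error-free read from its 5' end on a uniformly chosen strand, so
directional extension downstream reconstructs the fragment exactly.
Sequencing error, quality variation, paired ends and real repeat sequence
composition are deliberately not modelled: passing tests show the counting
and normalization logic is correct, not that the pipeline is robust to
base-calling noise or to the full repeat structure of a mammalian genome.

The default body profile is a raised cosine (mean 1, peak mid-element,
0.2× at the ends): smooth at the footprint scale so shape recovery is
meaningful, nonuniform as observed in real metaprofiles.  Consensus
sequences are built with identical terminal LTRs (default 350 bp) so that
within-element multi-mapping genuinely occurs.  True-position alignment
records carry `n_hits` equal to the read sequence's exact occurrence count
in the genome and map quality 37/0 for unique/multi reads.

## Standard study scales

* **Consensus study**: 80 kb genome, 3 copies of a 2 kb consensus at 2%
  divergence, 2×10⁵ reads per condition, enrichment 10×, knockout
  attenuation 0.1.  The compact genome makes element-derived reads a large
  share of the library, so the 200-bin metaprofile is well determined.
* **Flank study**: 4 Mb genome, 12 copies, same depth, decay scale 2 kb,
  ±7 kb windows.  The large genome keeps per-position read multiplicity
  low, the regime positional deduplication is designed for; the dozen
  agglomerated copies stabilize the decay fit the way hundreds of copies do
  in genome-scale data.
* **Methylation study**: 600 bp amplicon (≥ 10 CpGs), 100 clones per line
  at conversion 0.995, methylation probability 0.9 (wild type) versus 0.6
  (knockout); a separate 200-clone batch at conversion 0.95 exercises the
  QC filter.
* **qPCR study**: planted folds 8 (noiseless) and 47 (replicate Ct noise
  SD 0.05), three technical replicates.

All stages derive their RNGs from a single top-level seed (31-bit children
via `SeedSequence`) and are bit-reproducible.

## Known limitations

* Hamming-only alignment; no gapped or quality-aware placement.
* The consensus RPKM scale depends on a library-size convention that real
  pipelines vary in; cross-study comparisons should use ratios, as the
  condition comparison does.
* The flank decay fit assumes a single exponential plus flat background;
  overlapping flanks of unrelated enriched features would violate it.
* Technical-replicate t-tests understate biological variability by
  construction.
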