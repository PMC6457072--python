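# Methods

## The model

The package treats a mark's multi-cell-type signal as a T×N matrix of
non-negative integer counts over a fixed genome segmentation into equal
bins (200 bp by default). The analysis is built on a deliberately simple
premise: after binarizing each track, a bin is "dynamic" to the extent
that cell types disagree about its state, and disagreement is measured by
Hamming distance. For bin *n* with *c* of *M* cell types in state 1 the
dynamics score is

    DS_n = sum_t sum_{m != t} |b_tn - b_mn| = 2 c (M - c),

the number of discordant ordered cell-type pairs. The ordered-pair double
counting is part of the score's definition and is preserved; it only
scales every score by 2 and cannot change any ranking, p-value or call.
The closed form is the implementation; the explicit double loop is kept
as the independent oracle in the test suite and acceptance script, where
the two are compared exhaustively for all M ≤ 12.

DS is symmetric in the cell types and invariant under globally
complementing the bits; it is maximized at c = ⌊M/2⌋ or ⌈M/2⌉ and is an
even integer in [0, 2⌊M/2⌋⌈M/2⌉].

## Binarization

Each (mark, cell type) track is thresholded at its own genome-wide mean
count (total reads / number of bins); a bin is 1 only when its count is
*strictly* higher than the mean, so exact ties go to 0. Per-track
thresholds double as a depth correction: each cell type is compared
against its own sequencing depth. After stacking a mark's binarized
tracks, maximal per-chromosome runs of bins where *no* cell type has
signal are treated as unmappable sequence and masked when strictly longer
than 5 kb (at 200 bp, 26 consecutive zero bins are removed, 25 are kept).
Runs never span chromosome boundaries. All downstream counts of "genome
bins" (the N in p-values) refer to retained bins.

The mean threshold behaves well on real ChIP-seq-like tracks because
their count distributions are heavy-tailed: enriched bins push the mean
far above the background mode, so background bins rarely exceed it. On a
*flat* background this logic degrades — see "What the simulation shows"
below, because the reference simulation is exactly such a flat
background.

## Significance and HDMS calling

No parametric null is assumed. Bins with zero score are removed first;
the remaining retained bins form the empirical genome background, and a
bin's p-value is the fraction of background bins scoring at least as high
(orientation-aware, see below). Bins with p < α (strict, default
α = 0.05) are significant, and maximal runs of genomically consecutive
significant bins (same chromosome, zero gap by default; `merge_gap`
allows tolerance) are merged into HDMS regions. A region records its peak
bin (the most dynamic bin), the peak score, the sum and mean over its
significant bins, and the minimum p. Regions are ranked by peak score,
ties broken by region size then genomic position. Note the granularity of
the empirical p: with fewer than 21 nonzero background bins no bin can
reach p < 0.05, so tiny problems legitimately produce empty call sets.
No multiple-testing correction is applied; the empirical tail fraction is
used as a ranking-calibrated cutoff, not a familywise error control.

## Baseline scorers and orientation

Two baselines run through the identical p-value/calling/annotation
pipeline, both scoring the *continuous* signal after dividing each track
by its own mean (every track ends at mean 1):

* **Entropy (QDMR-style).** Shannon entropy (bits) of a bin's normalized
  cross-cell-type distribution. Low entropy = concentrated in few cell
  types = dynamic. This is the entropy essence only, not the published
  QDMR software's adjusted score. All-zero bins have no distribution and
  carry a NaN sentinel that becomes p = 1 downstream.
* **Index of dispersion (IOD).** Sample variance (denominator M−1;
  `ddof=0` available) divided by the mean; all-zero bins score 0 by
  convention.

Because the shared calling stage is upper-tail, smaller-is-dynamic
entropy scores are flipped to `log2(M) − H` before p-values. The ceiling
is principled: `log2 M` is the entropy of the uniform distribution, so a
flipped score of 0 means "maximally even = not dynamic at all", matching
the zero-score filtering semantics of the other scorers. The flip is
monotone, so it is exactly a rank inversion.

Gene-expression dynamics reuses the IOD implementation verbatim
(variance/mean of a gene's expression across cell types), so the two axes
of the modification-vs-expression correlation are computed by one audited
code path, with the same empirical p-value scheme over the nonzero-score
background.

## Annotation

Two distinct placement rules coexist on purpose: a region is *assigned*
to a gene by its center (the gene whose span, extended by a strand-aware
promoter flank upstream of the TSS, contains the region midpoint; nearest
TSS wins among several candidates), while its *feature class* is decided
by its peak bin with precedence promoter > coding > exon > intron. The
promoter is TSS ± 2 kb by default (`promoter_flank`); "coding" means
annotated CDS intervals, so with a span-only BED6 annotation the finest
non-promoter class is exon. Regions with no assigned gene are intergenic,
and only those are. The per-class Pearson correlation between region
dynamics and assigned-gene expression dynamics uses the peak score by
default (`region_stat` ∈ {max, sum, mean}) and requires at least three
pairs with variation on both sides.

## Benchmark harness

For each scorer: score → empirical p → call → merge → rank → annotate,
then match the top regions' assigned genes against the highly dynamic
expression genes (empirical p < α on expression IOD). MatchedNum is the
number of distinct dynamic genes hit; "bitwise matching" between the two
ranked lists is realized as gene-identity matching, the only key the two
lists share. AveDS is the mean expression entropy of the matched genes;
lower values mean the matched genes are expressed more
cell-type-specifically. All methods pass through byte-identical
downstream code, so differences in the report isolate the scorers
themselves.

## The synthetic generator

The generator emulates pre-binned multi-cell-type signal with the
simplest models having the right support:

* counts: iid Poisson(λ_bg = 0.5) background; inside each of n_regions
  planted regions (10 bins each) a uniformly drawn cell subset (size 3–7
  of M = 10) draws Poisson(λ_hi = 8);
* unmappable sequence: planted all-zero runs (default 4 runs of 30 bins);
* genes: one gene per planted region (promoter or gene-body placement in
  a configurable mix, strands alternating) plus background genes in the
  gaps; a `tight` mode makes gene spans equal the region footprint for
  truth-accounting fixtures;
* expression: gene g coupled to region r gets
  `base · (1 + β·1[cell ∈ active subset]) · exp(ε)`, ε ~ N(0, noise_sd²)
  — multiplicative log-normal noise keeps expression positive and scales
  with the mean; background genes lack the coupling term.

One integer seed drives named child streams, so every dataset is
bit-reproducible. Default sizes (M = 10, N = 50,000 bins, 50 regions)
keep the full reference run under a few seconds on one CPU; tests use
smaller genomes (4,000–20,000 bins) chosen so every code path still
exercises multi-chromosome layouts, zero runs and both gene placements.

### What the simulation shows — and does not

The generator's background is *flat* iid Poisson, with none of the
overdispersion, spatial autocorrelation or mappability structure of real
chromatin data. This matters for the mean-threshold binarization: with
λ_bg = 0.5 the per-track mean sits at ≈ 0.54, inside the bulk of the
background distribution, so ≈ 39% of background bins binarize to 1
(P[Poisson(0.5) ≥ 1] = 0.39). The binary matrix is then near-random, the
Hamming score saturates (≈ 19% of nonzero bins sit at the maximum
2⌊M/2⌋⌈M/2⌉), the minimum attainable empirical p is ≈ 0.19, and the
Hamming-score route calls no regions at α = 0.05 — its measured recall on
the reference simulation is 0. The continuous-signal scorers do not pass
through the binarization and recover the planted regions (IOD at recall
1.0 with low precision driven by single-bin noise calls). A passing
pipeline on this simulation therefore validates the *mechanics* of every
stage (thresholds, runs, p-values, merging, annotation, matching,
determinism) and the contrast between scorers on flat backgrounds; it
does not demonstrate Hamming-score recovery, which on real data relies on
the heavy-tailed count distributions that push the track mean above the
background bulk.

## Numerical and design choices

* Coordinates are 0-based half-open (BED convention) everywhere; bins are
  bin-aligned and sparse count files zero-fill omitted bins.
* Empirical p-values use `sorted-background` counting with ties counted
  as "at least as extreme" (≥), making p monotone non-increasing in the
  score; significance is strict (p < α), as is every boundary rule in the
  package ("higher than" the threshold, "more than" 5 kb).
* Pearson correlations guard exact zero-range inputs (peak-to-peak 0)
  and report them as undefined rather than warn-and-NaN.
* Group analyses (named cell-type subsets) recompute thresholds,
  backgrounds and p-values on the subset, so a group's results are
  identical to a standalone run on only that group's tracks.
* The pipeline writes no timestamps; reruns with the same config, inputs
  and seed are byte-identical.

## Known limitations

* The empirical background mixes signal and background bins; when
  planted/true regions occupy a large genome fraction the p-values are
  conservative.
* MatchedNum depends on the gene-assignment flank: with a nonzero flank,
  noise calls upstream of a gene can match it without overlapping any
  truly dynamic site. Truth-accounting fixtures therefore set the flank
  to 0 and make gene spans equal region footprints.
* The entropy scorer's significant set on sparse backgrounds is dominated
  by single-cell-type singleton bins (entropy exactly 0); this is a
  property of entropy on sparse counts, not an implementation artifact.
* No replicate structure, input-control normalization or mark-specific
  peak shapes are modeled anywhere.
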