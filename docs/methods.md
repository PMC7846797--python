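# Methods

`sacs` implements a pipeline for discovering splicing-associated
chromatin signatures (SACS): pairs of chromatin marks that are
reciprocally co-enriched at one position around a cassette exon,
uniquely in one class of exon-inclusion levels. This note describes the
model behind each stage, the tunable parameters and their defaults, what
the synthetic data emulates (and does not), and the numerical and design
choices that were genuinely open.

## Splicing quantification

Cassette events are exon triplets — an alternative exon flanked by two
constitutive exons — taken from transcript annotation. Exons at
transcript positions 1–2 are discarded (promoter-proximal chromatin
would confound the signal), as are biotypes other than protein-coding /
noncoding RNA. An exon counts as constitutive when annotated so and
included at PSI > 0.95 in more than 75% of conditions.

PSI is estimated from unique splice-junction reads after a
5-read-support filter:

    PSI = mean(inc_acceptor, inc_donor) / (mean(inc) + exc)

The two inclusion junctions are averaged because both report the same
included isoform. Events are binned into four groups: excluded
[0, 0.2), mid-excluded [0.2, 0.4), mid-included [0.4, 0.8), included
[0.8, 1.0]. The source intervals are open at the bin edges and leave
boundary values unassigned; we adopt half-open bins (1.0 folded into
"included") so the groups partition [0, 1]. The bin edges are a fixed
vocabulary, not tunables. Genes with TPM < 10 are dropped.

A limitation worth stating: binomial junction noise makes PSI estimates
near a bin edge cross into the neighbouring group. At junction depth
100 about 8% of assignments are wrong near the edges, which is enough
to drag a strong signature into the adjacent group and trip the
uniqueness filter; at depth 200 (the default simulated depth, and the
regime a coverage filter on real data targets) assignment accuracy
exceeds 95% and the effect disappears.

## Chromatin features

Aligned reads (36-nt, BED intervals) are extended to 200 nt in the
5'→3' direction. Two summaries are built:

* **Feature matrix** — per event and mark, RPKM-like densities
  (reads / kb of window / million mapped reads) in four 100-nt windows:
  the intronic and exonic side of the 3'ss (exon start in transcription
  order) and of the 5'ss. The phrase "100 nt upstream and downstream of
  each splice site" is read as split intron/exon windows, preserving
  the intron/exon asymmetry the signature positions rely on. Exonic
  windows truncate to short exons, with the density normalised by the
  truncated length. Raw extended reads (not clusters) feed the feature
  matrix.
* **Peak clusters** — maximal runs of transitively overlapping extended
  reads; single-read clusters are discarded. When an input (control)
  track exists, clusters must exceed the library-size-scaled input
  density by `min_fold` (default 2.0 — the source method says only
  "significantly above input", so the fold is exposed in config).
  Clusters drive peak-level presence calls in discovery.

Average profiles (`reference_point_profile`) report per-bin mean read
count ± SEM anchored at a splice site, per splicing group, orientation
corrected; bins average per-event counts so groups of different sizes
are comparable. Splice-site strength scoring is pluggable; the default
scorer is PWM log2-odds against a uniform background (probabilities
floored at 1e-4), with the standard 23-nt acceptor and 9-nt donor
context windows. An external maximum-entropy scorer can be dropped in
through the same interface.

## Feature selection (shadow features)

All six pairwise group comparisons are run as binary classifications.
Each iteration draws a balanced subsample (equal events per group),
appends one freshly permuted shadow column per feature, fits a random
forest, and awards a hit to every real feature whose importance exceeds
the best shadow's. Hits accumulate over iterations; a two-sided
binomial test (p = 0.5, Bonferroni-adjusted across the entered
features) confirms or rejects features, and rejected features leave the
forest as real competitors. The loop stops early when nothing is
tentative.

One deliberate difference from implementations that shrink the shadow
pool along with the active set: shadows are drawn for *all* original
columns every iteration. If the pool shrank, a pure-noise feature whose
accidental sample correlation happens to be the largest of the batch
would outlive its competitors and then beat the weakened max-shadow in
well over half the iterations, accumulating enough hits to be falsely
confirmed (we observed exactly this in 8/20 randomised-label runs). A
stationary full-strength shadow pool keeps such a feature at a ~50% hit
rate — permanently tentative — while leaving the power to confirm
genuinely informative features intact.

Defaults: 500 trees, ≤100 iterations, alpha 0.01. These desk-scale
values run the identical algorithm as the reference configuration
(100,000 trees, 10,000 iterations), which remains reachable through
`SelectionConfig`. The acceptance experiments use 100–150 trees, which
the planted effect sizes comfortably support.

Importance defaults to the forest's impurity decrease (MDI). We
originally used hold-out permutation importance; at desk-scale forest
sizes it confirmed only 1–3 of 9 genuinely informative features,
because permuting one of several correlated informative columns barely
moves hold-out accuracy, while MDI separated all 9 from the best shadow
at the cost of a single fit. Both permutation variants
(`"permutation"`, `"permutation_z"`) remain config options.

Cross-condition intersection keeps features confirmed in at least one
comparison in *every* condition (the union-over-comparisons reading of
"common in both cell lines"), ranked by mean importance.

## Signature discovery

For each splicing group, three region sets anchor the analysis: the
200-nt intronic stretch upstream of the 3'ss, the exon body, and the
200-nt intronic stretch downstream of the 5'ss (clipped at the
neighbouring exon when an intron is shorter). Controls: up to 600
constitutive-exon triplets from the same genes, sampled without
replacement.

The co-occurrence statistic for a mark pair (A, B) in a region set is
the number of regions overlapped by peaks of both marks. The null
holds A's per-region presence fixed and resamples B's presence by a
moving-block bootstrap: blocks of ceil(r·N) consecutive regions in
genomic order, drawn with replacement and concatenated (r = 0.1,
n = 1000 replicates by default; the reference analysis used 10,000).
z = (observed − null mean) / null sd, computed in both directions
(resampling B vs resampling A). Blocks preserve local autocorrelation
along the genome; the statistic is the "observed overlap vs
block-resampled expectation" contract, since the original tool's
internals are not published. An independent permutation oracle —
uniform re-placement of peaks inside the concatenated region space —
guards the calibration: the two nulls agree in sign and significance
call on random instances (tested).

Filters, in order:

1. **Reciprocity**: both z directions ≥ `z_min` (default 3.0; the
   source never prints a cutoff, so the threshold is exposed, with an
   empirical-p alternative available via the bootstrap replicates).
2. **Uniqueness**: a (pair, region) is kept only when reciprocally
   significant in exactly one splicing group and in no control set.
   The randomised-inclusion control is a separate full re-analysis with
   shuffled labels (expected to produce nothing), not an extra row in
   the uniqueness table: a genuine signature diluted into shuffled
   pseudo-groups can still reach z ≥ 3 there, so treating the shuffle
   as a control group would veto every true signature.
3. **Localization**: one region per (pair, group). Read extension
   blurs a physical co-enrichment into adjacent regions and merged
   clusters cross region boundaries by a few bases, so any-overlap
   counts tie between neighbours; the signature's position is the
   region where the most events carry cluster *midpoints* of both
   marks.

Members of a signature are the group's events whose defining region
overlaps above-input clusters of both marks; the one-mark-only and
neither counts are reported alongside.

With ~450 z-tests per scan at z_min = 3, about 0.15 spurious reciprocal
combinations arise per run before selection; in the full pipeline the
feature-selection gate (no informative marks → no scan) removes these
under the null. Only marks surviving selection enter the pair scan.

## Motif enrichment

Member exons plus intronic flanks are scanned: flanks take at most
250 nt of intron adjacent to the exon after removing 9 nt at donor
sides and 30 nt at acceptor sides (branch point / PPT / splice-site
signals); introns under 60 nt contribute no flank; minus-strand events
are reverse-complemented so all sequences read in transcription
direction. Counted are overlapping 5-mers and PWM motif matches (match
threshold = 0.9 quantile of the analytically convolved null score
distribution per motif — no threshold is given in the source, so it is
exposed in config). Enrichment against non-marked alternatively
spliced controls: log2 ratio of per-sequence densities with a 0.5
pseudocount, and a two-sided Fisher exact test on sequence-level
presence/absence (a per-occurrence binomial alternative sits behind a
flag; the presence/absence form is robust to multi-occurrence
sequences). p-values are BH-adjusted across all motif × region
records; a record passes when the adjusted p is below both 0.01 and
the 0.05 FDR level.

## Comparative statistics

Fisher exact tests (scipy's hypergeometric-tail implementation; an
exhaustive enumeration oracle cross-checks it in the tests) drive the
maintenance analysis — member exons cross-classified by their splicing
group in another condition and by whether both signature marks still
overlap the defining region (both-marks is the default reading of
"maintains the enrichment"; either-mark sits behind a flag) — and the
binding-site overlap counts. Odds ratios use the Haldane–Anscombe 0.5
correction for zero cells in reporting only. Group comparisons of
genetic features (exon/intron lengths, splice-site strengths, TSS
distance in kb, GC log2 ratios exon/intron, log10 TPM — the log base is
configurable since the source does not state it) use two-sided
rank-sum tests with Bonferroni correction over the number of
comparisons.

## Synthetic data

The generator produces what the pipeline consumes, with truth tables
for every planted quantity. Study-condition defaults: 600 genes (one
cassette event each, 5–9 exons, exon lengths 60–300 nt, introns
300–1500 nt, alternating strands), group proportions
0.37/0.13/0.24/0.26 (the relative sizes of the four splicing groups in
the reference H1 analysis), junction depth 200, six marks, background
2 reads/kb, 36-nt reads.

* **Junctions**: included-transcript count N ~ Binomial(depth, PSI);
  acceptor reads ~ Binomial(2N, 1/2), donor = 2N − acceptor, exclusion
  = depth − N, so inc_a + inc_d + 2·exc = 2·depth holds exactly and
  the PSI estimator N/depth is unbiased. True PSI is uniform within
  the group's interval, 0.02 off the edges. Constitutive introns get
  full-depth support.
* **Planted signatures**: both marks of a pair receive
  Poisson-distributed extra reads in the chosen region of the *same*
  random `member_fraction` (default 0.5) of the group's events. The
  shared membership is deliberate: with whole-group plants the two
  marks' presences are independent given the region set and the
  observed co-occurrence equals the bootstrap null. The planted rate
  is `fold ×` the background expectation of reads whose extended
  footprint overlaps the region; planted footprints centre on the
  middle half of the region, as fragments piling on a positioned
  nucleosome would.
* **Genome**: i.i.d. bases with configurable exon/intron GC and
  canonical GT..AG (strand-aware) intron boundaries, one chromosome.
* **RNG**: one stream per output file, keyed by name off the master
  seed, so adding a mark cannot perturb junction counts (tested).

Not modelled: nucleosome-scale positioning beyond the planted point
sources, fragment-length distributions, sequencing errors, multiple
isoforms per gene, mappability structure. Passing tests therefore show
the *method* behaves as specified under its stated statistical
assumptions — not that real chromatin data satisfies those
assumptions.

## Problem sizes in the shipped experiments

The acceptance experiments run at: 1,000 events × 10 seeds with
n_boot = 1000 for signature recovery; 600 events × 20 features × 20
seeds for the randomised-label control; 500 events at depth 200 for
PSI recovery; ~380 control events × 20 splits for motif calibration;
all 2×2 tables with margins ≤ 30 for the Fisher oracle. These sizes
are the package's desk-scale choices; every stage accepts the larger
reference values through its config.

## Degenerate inputs and tie-breaks

Zero bootstrap sd with observed = null mean gives z = 0, otherwise ±inf
flagged with a warning. Events whose PSI denominator is zero stay
undefined and are excluded from grouping. PWM probabilities are floored
at 1e-4 before log-odds. Empty groups skip their pairwise comparisons
and profile panels with a log message. An event shorter than a feature
window truncates the window and renormalises by the true length.
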