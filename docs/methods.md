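# Methods

`atackit` implements the downstream analysis of a sorted-population ATAC-seq
study: replicate peak calls come in, and out come reproducible and
population-specific peak sets, differential-accessibility calls with per-gene
cumulative scores, sample-correlation QC, motif statistics, preranked gene-set
enrichment, and cross-assembly mapping of peaks onto variant catalogs. This
note records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Coordinate and interval conventions

All coordinates are 0-based half-open (BED convention). Variant tables are the
single 1-based input; they are converted at the parser boundary
(`VariantRecord.position0`). Chromosome names match by exact string equality —
no "chr" aliasing — so assembly mismatches surface as empty overlaps rather
than silently coerced joins. Interval operations mirror the classic tools:
`overlap_filter`/`subtract_nonoverlapping` use element semantics (an interval
is kept or removed whole on a ≥ 1 bp test, like `bedops -e`/`-n`), and
`merge_within(d)` joins intervals separated by at most `d` bases (`bedtools
merge -d`; a gap of exactly `d` merges). Outputs are always sorted by
(chrom, start, end), stably for equal keys.

## Peak pipeline

A peak is *reproducible* when it overlaps (≥ 1 bp) a peak in at least one
other replicate of the same (group, stage); the union of supported peaks is
then merged with gap 100 bp. A strict pairwise mode (first replicate filtered
by the second) is available for two-replicate designs. Blacklist removal drops
a peak on any overlap — element removal, not trimming. Population-specific
peaks are those overlapping nothing in the union of a comparison panel.

Annotation assigns each peak to the gene minimizing |peak midpoint − TSS|
(midpoint, not edges, so results are deterministic and match common
annotators); distance is signed positive downstream in gene orientation, and
equidistant ties go to the lower-coordinate TSS. Feature classification takes
the highest-precedence overlapping class (default promoter > 5′UTR > exon >
3′UTR > TTS > intron, else intergenic); CpG islands are an independent overlay
flag because they are not transcript parts, so a promoter peak can also be
CpG-overlapping without double classification. When no promoter catalog is
supplied, promoters are generated as TSS −1000/+100 bp in gene orientation.
Feature enrichment compares observed class counts with a uniform-placement
expectation, `expected = n_peaks × coverage/genome`, and reports
`log2((obs + 0.5)/(exp + 0.5))`; the 0.5 floor keeps empty classes finite.

## Differential accessibility

Consensus regions are the gap-100 merge of the compared groups' replicated
peak sets. Fragments (one interval each; paired-end fragments are assumed
already reconstructed) count once toward every region they overlap by ≥ 1 bp;
fragments longer than 2 000 bp are discarded and do not enter the library
size. Regions need ≥ 1 CPM (inclusive) in ≥ n − 1 samples to be tested.

Counts are modeled NB2: Var(Y) = μ + φμ². Normalization is classic TMM with
log-ratio trim 0.30 and abundance trim 0.05 per tail, inverse
asymptotic-variance weights, reference = the sample whose upper-quartile CPM
is closest to the mean, and factors rescaled to geometric mean 1.

The common dispersion is estimated by **conditional** maximum likelihood on
counts scaled to a common (geometric-mean) effective library size: for n iid
NB replicates the law of the counts given their total is free of the mean, so
the group means drop out of the likelihood. This matters at 2–4 replicates —
profile likelihood with fitted group means underestimates φ by roughly the
within-group degrees-of-freedom ratio (measured: φ̂ ≈ 0.06 for a true 0.1 at
n = 3 + 3), which in turn inflates the exact test's type-I error to ~0.10.
With the conditional estimator, φ recovery is accurate (0.10 ± 0.005 across
seeds) and the test's null p < 0.05 fraction sits at ≈ 0.045. The search is
bracketed on [10⁻⁶, 10] in log space.

The two-group test is a conditional exact NB test: counts are scaled to the
common effective library size and rounded (pseudo-counts); under the null of
equal means the group sums are NB(nₐm, φ/nₐ) and NB(n_b m, φ/n_b) with m
estimated from the total; conditional on the total, the two-sided p-value
sums the probabilities of all splits no more probable than the observed one
(tie tolerance 10⁻¹²). φ = 0 reduces to the conditional binomial. log2 fold
changes use normalized group mean rates with a symmetric prior count of
0.125; significance status (increased/decreased/unchanged) uses
Benjamini–Hochberg FDR < 0.05 by default — the threshold is a configurable
field default, chosen as the field's customary value.

The cumulative per-gene score is the sum of **log2** fold changes of all
tested regions whose nearest TSS belongs to the gene. Log scale is the only
choice under which summing fold differences is meaningful (sums of raw ratios
depend on direction asymmetrically); the contributing region count is
reported alongside.

## Sample correlation and FRiP

Spearman correlation is computed as Pearson on average-tied ranks of the raw
per-region counts — ranks are invariant to any per-sample monotone map, so no
CPM transform is needed. Constant columns yield undefined correlations,
reported as missing with a warning. Clustering is Ward.D2 on Euclidean
distances between correlation-matrix rows, implemented by the Lance–Williams
update d(k, i∪j) = √(((nᵢ+n_k)d²ᵢk + (n_j+n_k)d²_jk − n_k d²ᵢj)/(nᵢ+n_j+n_k))
with a deterministic smallest-pair-index tie-break; scipy's `ward` linkage is
the independent cross-check in the tests, not the implementation. FRiP is the
percentage of fragments overlapping ≥ 1 peak by ≥ 1 bp.

## Motif statistics

PWMs hold per-position base probabilities; scanning scores Σ log2(p/bg) on
both strands, with uniform background by default and a −20-bit floor on zero
probabilities. A motif's detection threshold defaults to 80 % of its maximum
achievable log-odds when the library file carries none — deterministic and
scale-aware. Repeat masking is delegated to the input: lowercase or N bases
never match any column (windows lowercase→N at extraction). Windows are
centered on peak midpoints; truncation at chromosome ends is flagged and the
center index kept explicit so hit offsets remain center-relative.

Enrichment counts peaks with ≥ 1 hit in target vs background and computes the
upper-tail cumulative hypergeometric p-value. Backgrounds are GC-matched by
resampling within 5 %-wide GC bins to the target's GC profile (with
replacement only when a bin is underpopulated; seedable). Centrality profiles
report hits per bp per peak in fixed bins of center offset, so the values
integrate back to total hits. Motif similarity is the maximum Pearson
correlation of aligned probability columns over all ungapped offsets with
≥ 4 overlapping columns, in both orientations. Co-occurrence reports, per
motif pair, the fraction of peaks containing both motifs (diagonal: ≥ 2 hits
of one motif) against either the same statistic on a background peak set
(default — the genomic-baseline reading) or the product of target marginals;
ratio = (obs + 10⁻⁴)/(exp + 10⁻⁴). Both expectation modes are exposed because
the appropriate baseline depends on the question (genomic propensity vs
within-peak dependence).

## Preranked GSEA

The enrichment score is the weighted Kolmogorov–Smirnov running-sum extremum:
hits step |score|^α normalized over set members (α = 1 by default), misses
step −1/(N − m). Significance uses gene-label permutation — random same-size
sets drawn from the ranked genes (nperm = 10 000 by default, null shared per
set size) — because preranked input has no sample structure to permute. The
p-value is computed against the same-sign half of the null,
p = (1 + #{null ≥ ES})/(1 + #{null ≥ 0}) for positive ES and mirrored
otherwise; with the full-null denominator, sign-symmetric nulls cap p near
0.5 and null p-values are far from uniform (measured Kolmogorov distance
≈ 0.49 vs < 0.1 with the same-sign convention). NES divides ES by the mean
|null ES| of matching sign. Sets are filtered to effective sizes within
[25, 500] after intersection with the ranked list. Redundancy reduction
between overlapping significant sets is intentionally not implemented.

## Cross-assembly mapping and variants

Chains follow the UCSC format: the first-named (t) side is the source
assembly, the second (q) the target, with per-block aligned sizes and
source/target gaps validated against the header spans. An interval lifts when
the best-scoring overlapping chain aligns ≥ `min_match` (default 0.7) of its
bases; the mapped region is the [min, max) span of mapped target bases, so
internal deletions are bridged as liftOver does for regions. `min_match`
compares the mapped-base fraction — what the corresponding liftOver option
actually measures — not sequence identity. Failures are statuses, not errors:
`no_chain`, `below_min_match`, and `split` when several chains jointly (but
no single one) reach the threshold.

Variant overlap tests 1-based positions against mapped regions (position p
hits [start, end) iff p − 1 ∈ [start, end)) and cross-tabulates
feature × pathogenicity, with unknown labels tallied under "other" with a
warning. Variant-in-motif overlay projects a target-assembly variant back
through the chain's inverse block arithmetic and flags it when the source
position falls inside a motif hit's footprint; variants landing in unaligned
gaps are reported unprojectable rather than silently dropped.

## Synthetic data

The generator emulates the study design end to end: two sorted populations
("high" reporter and negative) × two stages × 3 replicates on a
2 × 120 kb two-chromosome genome with blockwise-variable GC (mean 0.45,
SD 0.08 per kb block) so GC matching is actually exercised.

* **Truth peaks** — 200 disjoint peaks of 250–550 bp with ≥ 400 bp clear
  spacing; 30 % are specific to the high population. These proportions give
  each downstream statistic a comfortably non-degenerate denominator at
  desk scale.
* **Replicate calls** — per replicate, truth peaks of the sample's group
  survive with probability 1 − dropout (default dropout 0.1), boundaries
  jittered N(0, 10 bp); 10 private noise peaks per replicate are placed in
  clear space and kept disjoint from every other replicate's noise so they
  are irreproducible *by construction* — reproducibility filtering must
  remove exactly them.
* **Fragments** — per region and sample, an NB(μ, φ = 0.1) total with
  region-level abundance spread (log2 SD 0.5 around mean 60) and per-sample
  depth (lognormal σ = 0.2); fragments are placed uniformly in the region
  with lengths ~N(180, 40) clipped to [50, 1000]. A uniform genome-wide
  background contributes ~35 % of fragments so FRiP is meaningful. Planted
  differential regions (10 % of shared peaks, alternating log2FC ± 2) are
  realized on the high-population side. The background adds a Poisson
  component on top of the NB signal, so empirical dispersion of *total*
  region counts is lower than the configured φ — dispersion calibration is
  therefore checked with background off.
* **Motifs** — a 20-motif library of sharp PWMs (dominant base 0.97,
  lengths 8–12). Instances are planted as consensus strings at peak centers
  with Gaussian offsets (SD 20 bp), random strand, into the high-specific
  peaks only, so shared peaks double as a motif-free background. Consensus
  (not PWM-sampled) instances mean a recovery failure indicates a scanner
  defect, not planting noise.
* **Chain** — one collinear chain per chromosome with 8 random indels of
  20–200 bp (insertions and deletions equally likely) and an exact
  base-level oracle.
* **Variants** — 200 variants: 40 % inside liftable peaks (including 5 %
  inside planted motif occurrences, projected through the chain), the rest
  ≥ 300 bp clear of peaks so overlap truth is unambiguous; labels drawn
  from fixed pathogenicity/feature frequency tables.

Everything is a pure function of (config, seed); one generator instance
drives all draws, so equal seeds give byte-identical bundles.

**What the synthetic data does not model:** read-level error and alignment
artifacts, Tn5 insertion-site sequence bias, fragment-length periodicity,
chromatin-state-correlated background, peak-shape heterogeneity, overlapping
gene annotations, rearrangements (the chain is collinear), and linkage
between variants. Passing tests therefore demonstrate algorithmic
correctness against the stated models, not robustness to every property of
real sequencing data.

## Numerical choices

* Exact-test tie tolerance 10⁻¹² when summing "as or less likely" splits;
  p-values computed in log space and renormalized to guard long totals.
* Dispersion search on log φ, bracketed [10⁻⁶, 10], with an explicit
  boundary preference when the likelihood is monotone toward φ → 0.
* TMM pair factors fall back to 1.0 for degenerate inputs (no doubly
  positive regions, empty trim window).
* Scanning treats any N in a motif footprint as disqualifying rather than
  neutrally scored, so masked sequence can never reach a threshold.
* Ward clustering breaks equal-height merges on the smallest pair index;
  merge records use the scipy linkage convention for interoperability.

## Problem sizes

Defaults throughout target desk-scale reproduction: 2 × 120 kb genome,
200 truth peaks, ~20–30 k fragments per sample, 2 000 regions × 6 samples
for count-model calibration, 1 000 permutations for GSEA checks, and 10
seeds for every stochastic claim. These sizes give stable statistics (for
example, the type-I band and dispersion recovery reproduce across seeds)
while an entire pipeline run stays in the tens of seconds on one core.

## Known limitations

* Only two-group exact-test designs; no GLM contrasts, no tagwise
  dispersion shrinkage (a single common φ).
* The exact test rounds library-equalized pseudo-counts to integers rather
  than carrying edgeR's quantile adjustment; at desk-scale depths the
  difference is below the test's tie tolerance in practice.
* GC matching resamples the background to the target's GC histogram; it
  does not reweight the hypergeometric itself, matching common practice but
  slightly overstating confidence when background pools are tiny.
* `split` liftover results report no coordinates (statuses only), matching
  the source tool's refusal to emit fragmented regions.
* The motif similarity statistic compares probability columns directly
  (no information-content weighting).
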