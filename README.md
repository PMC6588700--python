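# atackit

Downstream analysis of sorted-population ATAC-seq peak data: reproducible
peak construction, cell-type-specific peak subtraction, differential
accessibility with cumulative per-gene scores, motif enrichment / centrality
/ co-occurrence statistics, sample correlation and clustering, preranked
gene-set enrichment, and cross-assembly mapping of peaks onto variant
catalogs.

## The problem

ATAC-seq on FACS-sorted cell populations (for example, reporter-high
progenitors vs reporter-negative cells from the same tissue) yields
per-replicate peak calls and fragment alignments. The questions downstream
are always the same:

* which peaks are *reproducible* (supported by ≥ 1 bp overlap in at least
  one other replicate of the same sample type, then distance-merged)?
* which open regions are *specific* to the sorted population — overlapping
  no peak in a comparison panel of other populations and tissues?
* which regions change accessibility between groups, and what is the
  cumulative change per gene?
* which transcription-factor motifs are enriched, centered, and co-occurring
  in those regions?
* do the regions, mapped to another species' assembly, land on cataloged
  disease variants — and do any variants fall inside a binding motif?

`atackit` implements this pipeline as a typed Python library plus a thin
`atackit` command-line interface, along with a fully seeded synthetic-data
generator that plants ground truth for every stage, so the whole analysis is
testable end to end without any external download.

## Models and statistics

Fragment counts in consensus regions are modeled as negative binomial,
Var(Y) = μ + φμ². Between-sample normalization is TMM (trimmed mean of
M-values: log-ratio trim 0.30, abundance trim 0.05, precision weights,
factors scaled to geometric mean 1). The common dispersion φ is estimated by
conditional maximum likelihood on library-equalized counts, and two-group
comparisons use a conditional exact NB test: given the total, the two-sided
p-value sums the probabilities of all group-sum splits no more likely than
the one observed. Multiplicity is controlled by Benjamini–Hochberg FDR, and
each gene receives the sum of log2 fold changes of the regions nearest its
TSS (its *cumulative fold difference*).

Motifs are position weight matrices scored by log2-odds on both strands;
enrichment is an upper-tail cumulative hypergeometric against a GC-matched
background peak set, centrality is the hit frequency per bp per peak around
peak centers, and co-occurrence compares the observed joint frequency of
motif pairs to a background or independence expectation. Gene-set enrichment
is the preranked weighted Kolmogorov–Smirnov statistic with gene-label
permutation p-values. Liftover parses UCSC chains and maps an interval when
≥ minMatch (default 0.7) of its bases lie in aligned blocks of the best
chain. Details, defaults and rationale: [docs/methods.md](docs/methods.md).

## Worked example

```python
from atackit import SyntheticConfig, generate
from atackit.peaks import (AnnotationCatalog, assign_nearest_tss,
                           remove_blacklist, reproducible_peaks, specific_peaks)
from atackit.diffacc import (consensus_regions, count_fragments,
                             cumulative_gene_scores, estimate_common_dispersion,
                             exact_nb_test, filter_low_counts, tmm_factors)

ds = generate(SyntheticConfig(seed=1))          # synthetic sorted-cell study
calls = {g: [p for p in ds.peak_calls
             if p.meta.group == g and p.meta.stage == "E14.5"]
         for g in ("high", "neg")}
rep_high = remove_blacklist(reproducible_peaks(calls["high"]), ds.blacklist)
rep_neg  = remove_blacklist(reproducible_peaks(calls["neg"]),  ds.blacklist)
spec = specific_peaks(rep_high, [rep_neg])

regions = consensus_regions([rep_high, rep_neg], 100)
matrix  = filter_low_counts(count_fragments(regions, ds.fragment_sets))
factors = tmm_factors(matrix)
phi     = estimate_common_dispersion(matrix, factors)
result  = exact_nb_test(matrix, factors, phi, "high", "neg")

catalog = AnnotationCatalog(ds.tss)
scores = cumulative_gene_scores(result, assign_nearest_tss(matrix.regions, catalog))
```

Output (exact numbers for seed 1):

```
replicated peaks (high): 191
high-specific peaks:     58
regions tested:          197
common dispersion:       0.065
increased / decreased:   63 / 22
top gene scores:
          score  n_regions
gene
gene_120  13.32          9
gene_26   10.02          7
gene_97    5.28          2
```

Reading: of 200 planted peaks, 191 survive replicate filtering in the high
population; 58 of them overlap nothing in the negative panel — the
population-specific open chromatin. The exact NB test at the estimated
common dispersion calls 63 regions significantly more accessible in the
high population (these include the specific peaks, which are near-silent in
the negative cells) and 22 less accessible. `gene_120` accumulates a
+13.3 cumulative log2 fold difference across its 9 nearest regions — a
strongly gaining locus that preranked GSEA (`atackit.gsea`) would place at
the top of the ranking.

The same workflow runs from the shell:

```sh
atackit simulate --seed 1 --out sim/
atackit peaks --replicate sim/peaks/high_E14.5_1.bed \
              --replicate sim/peaks/high_E14.5_2.bed \
              --replicate sim/peaks/high_E14.5_3.bed \
              --blacklist sim/blacklist.bed --out peaks_high/
atackit crossmap --peaks peaks_high/replicated_peaks.bed \
                 --chain sim/alignment.chain --variants sim/variants.tsv \
                 --out crossmap/
```

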