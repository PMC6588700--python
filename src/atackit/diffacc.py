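"""Differential accessibility: consensus regions, counting, TMM, NB testing.

The statistical recipe is the classic two-group count workflow for region ×
sample fragment-count matrices:

1. consensus regions = distance-merged union of the compared groups'
   replicated peak sets (gap 100 bp);
2. per-region fragment counts (paired fragments as single intervals, one
   count per overlapped region, fragments longer than ``max_fragment_length``
   discarded);
3. low-count filter: keep regions with >= 1 CPM in >= n-1 samples;
4. TMM (trimmed mean of M-values) normalization factors, geometric mean 1;
5. a single common negative-binomial dispersion estimated by profile
   likelihood with per-group means and effective-library-size offsets;
6. a conditional exact NB test per region: counts are scaled to a common
   effective library size, and the two-sided p-value sums, conditional on
   the group total, the probabilities of all splits as or less likely than
   the observed one under equal group means;
7. Benjamini-Hochberg FDR and increased/decreased/unchanged status calls;
8. cumulative per-gene scores = sum of log2 fold changes of all regions
   whose nearest TSS belongs to the gene.

Variance model: Var(Y) = mu + phi * mu^2 (NB2).  phi = 0 reduces the exact
test to the conditional-binomial (Poisson) case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalCollection, merge_within, union
from .peaks import PeakAnnotation, SampleMeta

__all__ = [
    "FragmentSet",
    "CountMatrix",
    "NormFactors",
    "DispersionEstimate",
    "DifferentialResult",
    "consensus_regions",
    "region_id",
    "count_fragments",
    "filter_low_counts",
    "tmm_factors",
    "estimate_common_dispersion",
    "exact_nb_test",
    "bh_adjust",
    "cumulative_gene_scores",
]


@dataclass(slots=True)
class FragmentSet:
    """All sequenced fragments of one sample, one interval per fragment."""

    meta: SampleMeta
    fragments: IntervalCollection


@dataclass(slots=True)
class CountMatrix:
    """Consensus-region x sample fragment counts with library sizes.

    ``library_sizes[j]`` is the total number of retained fragments of sample
    j (not only those inside regions), so CPM reflects sequencing depth.
    """

    region_ids: list[str]
    regions: IntervalCollection
    samples: list[SampleMeta]
    counts: np.ndarray  # shape (n_regions, n_samples), int
    library_sizes: np.ndarray  # shape (n_samples,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.region_ids), len(self.samples)):
            raise ValueError("count matrix dimensions inconsistent with labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def cpm(self) -> np.ndarray:
        return self.counts * 1e6 / self.library_sizes[None, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=self.region_ids,
            columns=[m.sample_id for m in self.samples],
        )

    def group_indices(self, group: str) -> list[int]:
        return [j for j, m in enumerate(self.samples) if m.group == group]


@dataclass(slots=True)
class NormFactors:
    """Per-sample TMM factors; geometric mean 1 by construction."""

    factors: np.ndarray
    library_sizes: np.ndarray

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors


@dataclass(slots=True)
class DispersionEstimate:
    common: float
    per_region: np.ndarray | None = None


@dataclass(slots=True)
class DifferentialResult:
    """Per-region two-group test results (group A vs group B)."""

    region_ids: list[str]
    regions: IntervalCollection
    log2_fold_change: np.ndarray  # A vs B
    mean_normalized: np.ndarray
    pvalues: np.ndarray
    fdr: np.ndarray
    status: list[str]  # increased / decreased / unchanged
    group_a: str = "A"
    group_b: str = "B"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_ids,
                "log2FC": self.log2_fold_change,
                "mean_norm": self.mean_normalized,
                "pvalue": self.pvalues,
                "fdr": self.fdr,
                "status": self.status,
            }
        )


def region_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def consensus_regions(
    group_peak_sets: Sequence[IntervalCollection], merge_gap_bp: int = 100
) -> IntervalCollection:
    """Distance-merged union of the compared groups' replicated peak sets.

    Output is disjoint and sorted; stable ids are derived from coordinates
    (``chrom:start-end``).
    """
    if not group_peak_sets:
        raise ValueError("need at least one peak set")
    merged = merge_within(union(group_peak_sets), merge_gap_bp)
    out = IntervalCollection(
        [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=region_id(iv))
            for iv in merged
        ],
        disjoint=True,
    )
    return out


def count_fragments(
    regions: IntervalCollection,
    fragment_sets: Sequence[FragmentSet],
    max_fragment_length: int = 2000,
) -> CountMatrix:
    """Count fragments per disjoint consensus region.

    A retained fragment (length <= ``max_fragment_length``) adds one count
    to *every* region it overlaps by >= 1 bp; longer fragments are ignored
    entirely and do not enter the library size.
    """
    _check_disjoint(regions)
    by_chrom = regions.by_chrom()
    # index regions: per chrom arrays of starts/ends and row indices
    row_of: dict[tuple[str, int, int], int] = {
        (iv.chrom, iv.start, iv.end): i for i, iv in enumerate(regions)
    }
    chrom_arrays = {}
    for chrom, ivs in by_chrom.items():
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        rows = np.array([row_of[(chrom, iv.start, iv.end)] for iv in ivs])
        chrom_arrays[chrom] = (starts, ends, rows)

    counts = np.zeros((len(regions), len(fragment_sets)), dtype=np.int64)
    lib_sizes = np.zeros(len(fragment_sets))
    for j, fset in enumerate(fragment_sets):
        frag_by_chrom: dict[str, list[GenomicInterval]] = {}
        retained = 0
        for frag in fset.fragments:
            if frag.length <= max_fragment_length:
                retained += 1
                frag_by_chrom.setdefault(frag.chrom, []).append(frag)
        lib_sizes[j] = retained
        for chrom, frags in frag_by_chrom.items():
            if chrom not in chrom_arrays:
                continue
            starts, ends, rows = chrom_arrays[chrom]
            fs = np.array([f.start for f in frags])
            fe = np.array([f.end for f in frags])
            # disjoint sorted regions: overlapped rows form a contiguous run
            lo = np.searchsorted(ends, fs, side="right")
            hi = np.searchsorted(starts, fe, side="left")
            for a, b in zip(lo, hi):
                if b > a:
                    np.add.at(counts[:, j], rows[a:b], 1)
        if retained == 0:
            lib_sizes[j] = 0
    return CountMatrix(
        region_ids=[region_id(iv) for iv in regions],
        regions=regions,
        samples=[f.meta for f in fragment_sets],
        counts=counts,
        library_sizes=lib_sizes,
    )


def _check_disjoint(regions: IntervalCollection) -> None:
    for ivs in regions.by_chrom().values():
        for prev, nxt in zip(ivs, ivs[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"regions not disjoint: {prev} overlaps {nxt}"
                )


def filter_low_counts(
    matrix: CountMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Keep regions with CPM >= ``min_cpm`` in >= ``min_samples`` samples
    (default n - 1); the CPM boundary is inclusive."""
    n = matrix.n_samples
    if min_samples is None:
        min_samples = n - 1
    if min_samples > n:
        raise ValueError("min_samples exceeds number of samples")
    if np.any(matrix.library_sizes <= 0):
        raise ValueError("all library sizes must be positive for CPM filtering")
    keep = (matrix.cpm() >= min_cpm).sum(axis=1) >= min_samples
    idx = np.flatnonzero(keep)
    return CountMatrix(
        region_ids=[matrix.region_ids[i] for i in idx],
        regions=IntervalCollection(
            [matrix.regions[i] for i in idx], disjoint=matrix.regions.disjoint
        ),
        samples=matrix.samples,
        counts=matrix.counts[idx],
        library_sizes=matrix.library_sizes,
    )


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_logratio: float,
    trim_abundance: float,
) -> float:
    """Two-sample TMM factor (observed vs reference), doubly trimmed
    weighted mean of M-values with inverse asymptotic-variance weights."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return 1.0
    o = obs[mask].astype(float)
    r = ref[mask].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = len(m)
    lo_m = np.floor(n * trim_logratio) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_abundance) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or v[keep].min() <= 0:
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    matrix: CountMatrix,
    trim_logratio: float = 0.30,
    trim_abundance: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean of those quantiles.  Per sample, the factor is 2 to the
    weighted trimmed mean of per-region log2 count-rate ratios against the
    reference (trimming the ``trim_logratio`` / ``trim_abundance`` fractions
    from each tail of the M and A distributions, weights = inverse binomial
    asymptotic variances, regions zero in either sample excluded).  Factors
    are rescaled to geometric mean 1 so effective library sizes preserve
    total scale.
    """
    if matrix.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    if np.any(matrix.counts.sum(axis=0) == 0):
        raise ValueError("a sample has no counts in regions; cannot normalize")
    lib = matrix.library_sizes
    q75 = np.array(
        [np.quantile(matrix.counts[:, j] / lib[j], 0.75) for j in range(matrix.n_samples)]
    )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(
                matrix.counts[:, j],
                matrix.counts[:, ref],
                lib[j],
                lib[ref],
                trim_logratio,
                trim_abundance,
            )
            for j in range(matrix.n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(factors=factors, library_sizes=lib.copy())


# ---------------------------------------------------------------------------
# dispersion


def _nb_loglik(counts: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Sum of NB2 log-pmf over an array; phi -> 0 handled as Poisson."""
    counts = counts.ravel()
    mu = np.clip(mu.ravel(), 1e-12, None)
    if phi < 1e-10:
        return float(np.sum(counts * np.log(mu) - mu - special.gammaln(counts + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(counts + r)
            - special.gammaln(r)
            - special.gammaln(counts + 1)
            + r * np.log(r / (r + mu))
            + counts * np.log(mu / (r + mu))
        )
    )


def _conditional_loglik(y: np.ndarray, phi: float) -> float:
    """Conditional NB log-likelihood of replicate counts given their sum.

    For n iid NB(mean, phi) replicates the distribution of the counts
    conditional on their total is free of the mean, so maximizing this
    removes the small-sample bias of plugging in fitted group means.
    Terms constant in phi are dropped.
    """
    r = 1.0 / phi
    n = y.shape[1]
    s = y.sum(axis=1)
    return float(
        np.sum(special.gammaln(y + r))
        - y.shape[0] * n * special.gammaln(r)
        + y.shape[0] * special.gammaln(n * r)
        - np.sum(special.gammaln(s + n * r))
    )


def estimate_common_dispersion(
    matrix: CountMatrix,
    factors: NormFactors,
    groups: Mapping[str, Sequence[int]] | None = None,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are scaled to a common effective library size (geometric mean)
    so replicates within a group are exchangeable, then phi maximizes the
    summed conditional log-likelihood of the within-group counts given the
    group totals — the classic qCML route, which avoids the downward bias
    of profile likelihood with fitted group means at 2-4 replicates.
    Groups with a single sample carry no information; at least one group
    must have >= 2 samples.  The search is bracketed on ``bounds``.
    """
    if groups is None:
        groups = {}
        for j, m in enumerate(matrix.samples):
            groups.setdefault(m.group, []).append(j)  # type: ignore[attr-defined]
    eff = factors.effective_library_sizes
    informative = {g: list(idx) for g, idx in groups.items() if len(idx) >= 2}
    if not informative:
        raise ValueError("no group has >= 2 samples; dispersion not estimable")

    blocks = []
    for idx in informative.values():
        common_lib = float(np.exp(np.mean(np.log(eff[idx]))))
        y = matrix.counts[:, idx].astype(float) * (common_lib / eff[idx][None, :])
        keep = y.sum(axis=1) > 0
        blocks.append(y[keep])

    def negloglik(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -sum(_conditional_loglik(y, phi) for y in blocks)

    res = optimize.minimize_scalar(
        negloglik,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi_hat = float(np.exp(res.x))
    # prefer the boundary when the likelihood is monotone toward it
    if negloglik(np.log(bounds[0])) <= res.fun:
        phi_hat = bounds[0]
    return DispersionEstimate(common=phi_hat)


# ---------------------------------------------------------------------------
# exact test


def _nb_logpmf_vec(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if phi < 1e-10:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def exact_test_pvalue(
    sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided conditional exact NB p-value for group sums.

    Under the null of equal per-sample means, the group sums are
    NB(n_a * m, phi / n_a) and NB(n_b * m, phi / n_b) with the common mean m
    estimated from the total.  Conditional on total t = sum_a + sum_b, the
    p-value sums P(split) over every split of t whose probability does not
    exceed the observed split's (tolerance 1e-12 for ties).
    """
    if phi < 0:
        raise ValueError("dispersion must be nonnegative")
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    m = t / (n_a + n_b)
    k = np.arange(t + 1)
    log_pa = _nb_logpmf_vec(k, n_a * m, phi / n_a)
    log_pb = _nb_logpmf_vec(t - k, n_b * m, phi / n_b)
    log_joint = log_pa + log_pb
    log_joint -= special.logsumexp(log_joint)
    probs = np.exp(log_joint)
    obs = probs[sum_a]
    p = float(probs[probs <= obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def exact_nb_test(
    matrix: CountMatrix,
    factors: NormFactors,
    dispersion: float | DispersionEstimate,
    group_a: str,
    group_b: str,
    fdr_threshold: float = 0.05,
    prior_count: float = 0.125,
) -> DifferentialResult:
    """Per-region conditional exact NB test of group A vs group B.

    Counts are first scaled to a common effective library size (the
    geometric mean), rounded to integer pseudo-counts; p-values come from
    :func:`exact_test_pvalue` on the pseudo-count group sums.  log2 fold
    changes use normalized group mean rates with a symmetric
    ``prior_count`` added to each side; status is set by BH FDR against
    ``fdr_threshold``.
    """
    phi = dispersion.common if isinstance(dispersion, DispersionEstimate) else float(dispersion)
    if phi < 0:
        raise ValueError("dispersion must be nonnegative")
    ia = matrix.group_indices(group_a)
    ib = matrix.group_indices(group_b)
    if not ia or not ib:
        raise ValueError("both groups must have at least one sample")
    eff = factors.effective_library_sizes
    common_lib = float(np.exp(np.mean(np.log(eff[ia + ib]))))
    pseudo = matrix.counts.astype(float) * (common_lib / eff[None, :])
    sum_a = np.rint(pseudo[:, ia].sum(axis=1)).astype(np.int64)
    sum_b = np.rint(pseudo[:, ib].sum(axis=1)).astype(np.int64)

    pvals = np.array(
        [
            exact_test_pvalue(int(sa), int(sb), len(ia), len(ib), phi)
            for sa, sb in zip(sum_a, sum_b)
        ]
    )
    mean_a = pseudo[:, ia].mean(axis=1)
    mean_b = pseudo[:, ib].mean(axis=1)
    log2fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))
    fdr = bh_adjust(pvals)
    status = [
        "unchanged"
        if q >= fdr_threshold
        else ("increased" if fc > 0 else "decreased")
        for q, fc in zip(fdr, log2fc)
    ]
    return DifferentialResult(
        region_ids=list(matrix.region_ids),
        regions=matrix.regions,
        log2_fold_change=log2fc,
        mean_normalized=(mean_a * len(ia) + mean_b * len(ib)) / (len(ia) + len(ib)),
        pvalues=pvals,
        fdr=fdr,
        status=status,
        group_a=group_a,
        group_b=group_b,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cumulative_gene_scores(
    results: DifferentialResult,
    annotations: Sequence[PeakAnnotation],
) -> pd.DataFrame:
    """Per-gene cumulative accessibility change.

    Each gene's score is the sum of log2 fold changes of all tested regions
    whose nearest TSS belongs to the gene; unassigned regions are excluded.
    ``annotations`` must be parallel to ``results`` regions (one annotation
    per tested region, same order).  Returns a frame indexed by gene with
    columns ``score`` and ``n_regions``, sorted by descending score.
    """
    if len(annotations) != len(results.region_ids):
        raise ValueError("one annotation per tested region is required")
    scores: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ann, fc in zip(annotations, results.log2_fold_change):
        if not ann.assigned:
            continue
        scores[ann.gene] = scores.get(ann.gene, 0.0) + float(fc)
        counts[ann.gene] = counts.get(ann.gene, 0) + 1
    frame = pd.DataFrame(
        {"score": pd.Series(scores, dtype=float), "n_regions": pd.Series(counts)}
    )
    frame.index.name = "gene"
    return frame.sort_values("score", ascending=False)
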