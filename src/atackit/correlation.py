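"""Reads-in-peaks sample correlation, Ward.D2 clustering, and FRiP QC.

Rank (Spearman) correlation of per-region counts is scale-free per sample,
so library-size differences do not distort it; samples from one cell
population should correlate highly and cluster together.  Clustering uses
Euclidean distance between correlation-matrix rows with Ward.D2
agglomeration (the squared-distance Lance-Williams variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffacc import CountMatrix, FragmentSet
from .intervals import IntervalCollection, _OverlapIndex

__all__ = [
    "CorrelationMatrix",
    "Dendrogram",
    "spearman_matrix",
    "ward_cluster",
    "fraction_reads_in_peaks",
]


@dataclass(slots=True)
class CorrelationMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, diagonal 1; NaN marks undefined pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass(slots=True)
class Dendrogram:
    """Agglomeration record in scipy linkage convention.

    ``merges[k] = (i, j, height, size)`` merges clusters i and j (indices
    < n are leaves, >= n earlier merges) at the given height into cluster
    n + k.  Heights are nondecreasing for Ward.D2.
    """

    sample_ids: list[str]
    merges: np.ndarray  # (n-1, 4) float

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the merge tree."""

        def walk(node: int) -> list[int]:
            if node < self.n:
                return [node]
            i, j = int(self.merges[node - self.n, 0]), int(self.merges[node - self.n, 1])
            return walk(i) + walk(j)

        return walk(2 * self.n - 2) if self.n > 1 else [0]

    def first_bipartition(self) -> tuple[set[int], set[int]]:
        """Leaf sets of the two children of the root merge."""

        def leaves(node: int) -> set[int]:
            if node < self.n:
                return {node}
            i, j = int(self.merges[node - self.n, 0]), int(self.merges[node - self.n, 1])
            return leaves(i) | leaves(j)

        root = self.merges[-1]
        return leaves(int(root[0])), leaves(int(root[1]))


def spearman_matrix(matrix: CountMatrix) -> CorrelationMatrix:
    """Pairwise Spearman correlation of per-region counts across samples.

    Constant columns have undefined rank correlation; those pairs are
    reported as NaN with a warning rather than raising.
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if len(matrix.region_ids) < 3:
        raise ValueError("need >= 3 regions for a meaningful rank correlation")
    counts = matrix.counts.astype(float)
    constant = np.ptp(counts, axis=0) == 0
    if constant.any():
        bad = [matrix.samples[j].sample_id for j in np.flatnonzero(constant)]
        warnings.warn(f"constant count columns (correlation undefined): {bad}")
    # Pearson on average-tied ranks (= Spearman); computed via rankdata +
    # corrcoef because scipy.spearmanr degenerates to a scalar on constant
    # columns
    ranks = np.apply_along_axis(stats.rankdata, 0, counts)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix([m.sample_id for m in matrix.samples], rho)


def ward_cluster(corr: CorrelationMatrix) -> Dendrogram:
    """Ward.D2 hierarchical clustering of correlation-matrix rows.

    Distance between samples = Euclidean distance between their rows of the
    correlation matrix.  Agglomeration follows the Ward.D2 Lance-Williams
    update on (non-squared) distances:

        d(k, i+j) = sqrt(((n_i + n_k) d_ik^2 + (n_j + n_k) d_jk^2
                          - n_k d_ij^2) / (n_i + n_j + n_k))

    Ties are broken deterministically by the smallest (i, j) pair index.
    """
    if corr.has_missing:
        raise ValueError(
            "correlation matrix has undefined entries; drop the affected "
            "samples or impute before clustering"
        )
    n = len(corr.sample_ids)
    if n < 2:
        raise ValueError("need >= 2 samples to cluster")
    d = np.sqrt(
        np.maximum(
            0.0,
            ((corr.values[:, None, :] - corr.values[None, :, :]) ** 2).sum(axis=2),
        )
    )
    active = list(range(n))  # cluster labels, leaves 0..n-1 then n, n+1, ...
    sizes = {i: 1 for i in range(n)}
    dist = {
        (min(i, j), max(i, j)): float(d[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    merges = np.zeros((n - 1, 4))
    next_label = n
    for step in range(n - 1):
        best = min(
            ((dist[(min(a, b), max(a, b))], (min(a, b), max(a, b)))
             for ai, a in enumerate(active) for b in active[ai + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        h, (i, j) = best
        ni, nj = sizes[i], sizes[j]
        merges[step] = (i, j, h, ni + nj)
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dij = h
            dnew = np.sqrt(
                max(
                    0.0,
                    ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                    / (ni + nj + nk),
                )
            )
            dist[(min(k, next_label), max(k, next_label))] = float(dnew)
        active = [a for a in active if a not in (i, j)] + [next_label]
        sizes[next_label] = ni + nj
        next_label += 1
    return Dendrogram(list(corr.sample_ids), merges)


def fraction_reads_in_peaks(
    fragments: FragmentSet, peaks: IntervalCollection
) -> float:
    """Percentage of fragments overlapping (>= 1 bp) at least one peak."""
    if len(fragments.fragments) == 0:
        raise ValueError("empty fragment set")
    index = _OverlapIndex(peaks)
    n_in = sum(1 for f in fragments.fragments if index.overlaps_any(f))
    return 100.0 * n_in / len(fragments.fragments)
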