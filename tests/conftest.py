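"""Shared fixtures and brute-force oracles for the test suite.

The oracles here deliberately use naive per-base representations (Python
sets of covered bases) so they stay independent of the interval algebra
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from atackit.intervals import GenomicInterval, IntervalCollection


# ---------------------------------------------------------------------------
# per-base brute-force oracles (toy genomes only)


def covered_bases(collection: IntervalCollection) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for iv in collection:
        out.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return out


def interval_bases(iv: GenomicInterval) -> set[int]:
    return set(range(iv.start, iv.end))


def max_single_overlap_oracle(iv: GenomicInterval, others: IntervalCollection) -> int:
    best = 0
    for other in others:
        if other.chrom == iv.chrom:
            best = max(best, len(interval_bases(iv) & interval_bases(other)))
    return best


def merge_oracle(collection: IntervalCollection, gap: int) -> list[GenomicInterval]:
    """Transitive closure over pairwise gap tests, per chromosome."""
    out = []
    for chrom in sorted(collection.chroms()):
        ivs = [iv for iv in collection if iv.chrom == chrom]
        parent = list(range(len(ivs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                a, b = ivs[i], ivs[j]
                separation = max(a.start, b.start) - min(a.end, b.end)
                if separation <= gap:
                    parent[find(i)] = find(j)
        groups: dict[int, list[GenomicInterval]] = {}
        for i, iv in enumerate(ivs):
            groups.setdefault(find(i), []).append(iv)
        for members in groups.values():
            out.append(
                GenomicInterval(
                    chrom,
                    min(m.start for m in members),
                    max(m.end for m in members),
                )
            )
    out.sort(key=GenomicInterval.key)
    return out


def random_collection(
    rng: np.random.Generator,
    n: int,
    chrom_length: int = 10_000,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    max_width: int = 300,
) -> IntervalCollection:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_length - max_width))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return IntervalCollection(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
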