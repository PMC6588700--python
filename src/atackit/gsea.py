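"""Preranked gene-set enrichment on cumulative accessibility scores.

Genes are ranked by their cumulative accessibility change (sum of log2
fold changes of their nearest peaks); a gene set's enrichment score (ES) is
the extremum of the classic weighted Kolmogorov-Smirnov running sum over
the ranked list — hits step up by |score|^exponent (normalized over set
members), misses step down by 1/(N - m).  Significance is assessed by a
gene-label permutation null: random same-size sets drawn from the ranked
genes, with p = (1 + #{null as extreme}) / (1 + nperm) and NES = ES divided
by the mean |null ES| of matching sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .diffacc import bh_adjust

__all__ = [
    "RankedGeneList",
    "GseaResult",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "permutation_pvalues",
]


class RankedGeneList:
    """Unique genes with finite scores, sorted by descending score."""

    def __init__(self, scores: Mapping[str, float] | pd.Series) -> None:
        series = pd.Series(dict(scores), dtype=float)
        if series.index.has_duplicates:
            raise ValueError("duplicate gene ids in ranked list")
        if not np.isfinite(series.to_numpy()).all():
            raise ValueError("scores must be finite")
        self.series = series.sort_values(ascending=False, kind="stable")

    @property
    def genes(self) -> list[str]:
        return list(self.series.index)

    @property
    def scores(self) -> np.ndarray:
        return self.series.to_numpy()

    def __len__(self) -> int:
        return len(self.series)


@dataclass(slots=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    pvalue: float
    fdr: float
    size: int
    leading_edge: list[str]


def read_gmt(source: TextIO) -> dict[str, list[str]]:
    """GMT format: one set per line, ``name<TAB>description<TAB>genes...``."""
    out: dict[str, list[str]] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected name, description, members")
        members = [g for g in fields[2:] if g]
        if not members:
            raise ValueError(f"GMT line {lineno}: empty gene set {fields[0]!r}")
        out[fields[0]] = members
    return out


def write_gmt(collection: Mapping[str, Sequence[str]], sink: TextIO) -> None:
    for name, members in collection.items():
        sink.write(name + "\tna\t" + "\t".join(members) + "\n")


def _es_from_mask(
    scores: np.ndarray, mask: np.ndarray, exponent: float
) -> tuple[float, int]:
    """ES and extremum position for a boolean membership mask over the
    ranked scores."""
    n = len(scores)
    m = int(mask.sum())
    weights = np.abs(scores) ** exponent
    hit_norm = weights[mask].sum()
    steps = np.where(
        mask,
        (weights / hit_norm) if hit_norm > 0 else (mask / max(m, 1)),
        -1.0 / max(n - m, 1),
    )
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def enrichment_score(
    ranked: RankedGeneList, members: Sequence[str], exponent: float = 1.0
) -> tuple[float, int, list[str]]:
    """Weighted KS enrichment score of a gene set in the ranked list.

    Returns (ES, extremum position, leading-edge genes).  The leading edge
    is the set members at or before the running-sum extremum for positive
    ES, or at or after it for negative ES.  Raises if no member appears in
    the ranked list.
    """
    member_set = set(members)
    mask = np.array([g in member_set for g in ranked.genes])
    if not mask.any():
        raise ValueError("gene set has no overlap with the ranked list")
    es, pos = _es_from_mask(ranked.scores, mask, exponent)
    genes = ranked.genes
    if es >= 0:
        leading = [g for i, g in enumerate(genes) if mask[i] and i <= pos]
    else:
        leading = [g for i, g in enumerate(genes) if mask[i] and i >= pos]
    return es, pos, leading


def permutation_pvalues(
    ranked: RankedGeneList,
    collection: Mapping[str, Sequence[str]],
    nperm: int = 10000,
    min_size: int = 25,
    max_size: int = 500,
    exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> list[GseaResult]:
    """Permutation GSEA over a gene-set collection.

    Sets are intersected with the ranked genes and kept when their
    effective size lies in [min_size, max_size].  The null for each
    retained size is the ES of ``nperm`` random same-size gene sets drawn
    from the ranked genes; p = (1 + #{null >= ES}) / (1 + nperm) for
    positive ES and mirrored for negative.  NES = ES / mean |null ES| of
    matching sign; BH adjustment across the retained sets.  Results are
    deterministic for a fixed seed.
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = ranked.genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    scores = ranked.scores

    retained: list[tuple[str, np.ndarray, int]] = []
    for name, members in collection.items():
        idx = sorted({gene_pos[g] for g in members if g in gene_pos})
        if min_size <= len(idx) <= max_size:
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            retained.append((name, mask, len(idx)))
    if not retained:
        raise ValueError(
            "no gene set within the size window after intersection with the "
            "ranked list"
        )

    null_cache: dict[int, np.ndarray] = {}
    for _, _, size in retained:
        if size not in null_cache:
            es_null = np.empty(nperm)
            for b in range(nperm):
                pick = rng.choice(n, size=size, replace=False)
                mask = np.zeros(n, dtype=bool)
                mask[pick] = True
                es_null[b] = _es_from_mask(scores, mask, exponent)[0]
            null_cache[size] = es_null

    results = []
    for name, mask, size in retained:
        es, pos = _es_from_mask(scores, mask, exponent)
        null = null_cache[size]
        # p is computed against the same-sign side of the null so that a
        # sign-symmetric null yields uniform p-values
        if es >= 0:
            p = (1 + int((null >= es).sum())) / (1 + int((null >= 0).sum()))
            same_sign = np.abs(null[null >= 0])
        else:
            p = (1 + int((null <= es).sum())) / (1 + int((null < 0).sum()))
            same_sign = np.abs(null[null < 0])
        p = min(1.0, p)
        denom = float(same_sign.mean()) if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        if es >= 0:
            leading = [g for i, g in enumerate(genes) if mask[i] and i <= pos]
        else:
            leading = [g for i, g in enumerate(genes) if mask[i] and i >= pos]
        results.append(GseaResult(name, es, nes, p, np.nan, size, leading))
    fdr = bh_adjust([r.pvalue for r in results])
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    results.sort(key=lambda r: r.pvalue)
    return results
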