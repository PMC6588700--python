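"""UCSC chain parsing, liftOver-style interval mapping, variant overlap.

A chain describes one gapped alignment between a source assembly (the
``tName`` side of the UCSC header, e.g. mm9) and a target assembly
(``qName``, e.g. hg19) as a list of aligned blocks separated by gaps.  An
interval lifts when at least ``min_match`` of its bases fall in aligned
blocks of the best-scoring overlapping chain; the mapped region is the
span from the first to the last mapped target base (internal deletions are
bridged), matching liftOver region semantics.  ``min_match`` compares the
mapped-base fraction, which is what liftOver's ``-minMatch`` measures.

Downstream, mapped regions are intersected with 1-based variant tables
(e.g. catalogs of deafness-associated SNVs) and variants can be projected
back through the chain to ask whether they fall inside a transcription
factor binding motif detected in the source peak.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .intervals import GenomicInterval, IntervalCollection
from .motifs import MotifHit, SequenceWindow

__all__ = [
    "Chain",
    "ChainBlock",
    "ChainFormatError",
    "LiftResult",
    "VariantRecord",
    "OverlapSummary",
    "parse_chain",
    "write_chain",
    "lift_interval",
    "lift_collection",
    "read_variant_table",
    "overlap_variants",
    "variants_in_motifs",
]


@dataclass(slots=True)
class ChainBlock:
    """One aligned block: ``size`` aligned bases, then ``dt`` unaligned
    source bases and ``dq`` unaligned target bases before the next block
    (both 0 on the final block)."""

    size: int
    dt: int = 0
    dq: int = 0


@dataclass(slots=True)
class Chain:
    """One source->target alignment chain (UCSC chain file semantics)."""

    score: float
    source_name: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    target_name: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: list[ChainBlock]
    chain_id: str = ""

    def validate(self) -> None:
        s_span = sum(b.size + b.dt for b in self.blocks)
        t_span = sum(b.size + b.dq for b in self.blocks)
        if self.blocks and (self.blocks[-1].dt or self.blocks[-1].dq):
            raise ChainFormatError(
                f"chain {self.chain_id}: final block must carry no gaps"
            )
        if s_span != self.source_end - self.source_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: block sum {s_span} != source span "
                f"{self.source_end - self.source_start}"
            )
        if t_span != self.target_end - self.target_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: block sum {t_span} != target span "
                f"{self.target_end - self.target_start}"
            )
        for b in self.blocks:
            if b.size <= 0 or b.dt < 0 or b.dq < 0:
                raise ChainFormatError(
                    f"chain {self.chain_id}: block sizes must be > 0, gaps >= 0"
                )

    def aligned_segments(self) -> list[tuple[int, int, int]]:
        """List of (source_start, size, target_start_on_strand).

        Target starts are in chain-strand coordinates; conversion to
        forward-strand coordinates happens in :meth:`map_base`.
        """
        segs = []
        s, t = self.source_start, self.target_start
        for b in self.blocks:
            segs.append((s, b.size, t))
            s += b.size + b.dt
            t += b.size + b.dq
        return segs

    def map_base(self, pos: int) -> int | None:
        """Map one source base to a forward-strand target coordinate, or
        None when the base lies in a gap / outside the chain."""
        for s0, size, t0 in self.aligned_segments():
            if s0 <= pos < s0 + size:
                q = t0 + (pos - s0)
                if self.target_strand == "-":
                    return self.target_size - 1 - q
                return q
        return None

    def map_back(self, target_pos: int) -> int | None:
        """Inverse of :meth:`map_base` for one forward-strand target base."""
        q = (
            self.target_size - 1 - target_pos
            if self.target_strand == "-"
            else target_pos
        )
        for s0, size, t0 in self.aligned_segments():
            if t0 <= q < t0 + size:
                return s0 + (q - t0)
        return None


class ChainFormatError(ValueError):
    pass


@dataclass(slots=True)
class LiftResult:
    """Outcome of lifting one interval.

    status: mapped / no_chain / below_min_match / split.
    """

    status: str
    source: GenomicInterval
    mapped: GenomicInterval | None = None
    matched_bases: int = 0
    matched_fraction: float = 0.0
    chain_id: str = ""


def parse_chain(source: TextIO) -> list[Chain]:
    """Parse UCSC chain-format text; header/block arithmetic validated."""
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []

    def flush() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, *rest) = header
        chain = Chain(
            score=float(score),
            source_name=t_name,
            source_size=int(t_size),
            source_strand=t_strand,
            source_start=int(t_start),
            source_end=int(t_end),
            target_name=q_name,
            target_size=int(q_size),
            target_strand=q_strand,
            target_start=int(q_start),
            target_end=int(q_end),
            blocks=list(blocks),
            chain_id=rest[0] if rest else "",
        )
        chain.validate()
        chains.append(chain)
        header, blocks = None, []

    for raw in source:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            flush()
            header = line.split()
            if len(header) < 12:
                raise ChainFormatError("chain header has too few fields")
        else:
            fields = line.split()
            if header is None:
                raise ChainFormatError("block line outside any chain")
            if len(fields) == 1:
                blocks.append(ChainBlock(int(fields[0])))
            elif len(fields) == 3:
                blocks.append(ChainBlock(int(fields[0]), int(fields[1]), int(fields[2])))
            else:
                raise ChainFormatError(f"bad block line: {line!r}")
    flush()
    return chains


def write_chain(chains: Iterable[Chain], sink: TextIO) -> None:
    for c in chains:
        sink.write(
            f"chain {c.score:g} {c.source_name} {c.source_size} {c.source_strand} "
            f"{c.source_start} {c.source_end} {c.target_name} {c.target_size} "
            f"{c.target_strand} {c.target_start} {c.target_end}"
            + (f" {c.chain_id}" if c.chain_id else "")
            + "\n"
        )
        for b in c.blocks[:-1]:
            sink.write(f"{b.size} {b.dt} {b.dq}\n")
        sink.write(f"{c.blocks[-1].size}\n\n")


def _index_chains(chains: Sequence[Chain]) -> dict[str, list[Chain]]:
    idx: dict[str, list[Chain]] = {}
    for c in chains:
        idx.setdefault(c.source_name, []).append(c)
    for lst in idx.values():
        lst.sort(key=lambda c: -c.score)
    return idx


def lift_interval(
    interval: GenomicInterval,
    chains: Sequence[Chain] | Mapping[str, Sequence[Chain]],
    min_match: float = 0.7,
) -> LiftResult:
    """Lift one interval through the best-scoring overlapping chain.

    Bases in aligned blocks map by block arithmetic (strand-aware); the
    matched fraction is mapped bases / interval length.  Status:

    * ``mapped`` — best chain maps >= ``min_match`` of the bases; result is
      the [min, max) span of the mapped target positions;
    * ``split`` — no single chain reaches ``min_match`` but several
      overlapping chains jointly do;
    * ``below_min_match`` — chains overlap but too few bases map;
    * ``no_chain`` — no chain overlaps the interval.
    """
    index = (
        chains if isinstance(chains, Mapping) else _index_chains(list(chains))
    )
    candidates = [
        c
        for c in index.get(interval.chrom, [])
        if c.source_start < interval.end and c.source_end > interval.start
    ]
    if not candidates:
        return LiftResult("no_chain", interval)
    length = interval.length
    best_chain = None
    best_bases = -1
    per_chain_bases = []
    for c in sorted(candidates, key=lambda c: -c.score):
        bases = 0
        for s0, size, _ in c.aligned_segments():
            lo = max(interval.start, s0)
            hi = min(interval.end, s0 + size)
            if hi > lo:
                bases += hi - lo
        per_chain_bases.append(bases)
        if bases > 0 and best_chain is None:
            best_chain, best_bases = c, bases
        elif best_chain is None:
            continue
    if best_chain is None or best_bases <= 0:
        return LiftResult("below_min_match", interval, matched_bases=0,
                          matched_fraction=0.0)
    fraction = best_bases / length
    if fraction >= min_match:
        positions = []
        for s0, size, t0 in best_chain.aligned_segments():
            lo = max(interval.start, s0)
            hi = min(interval.end, s0 + size)
            if hi > lo:
                q_lo = t0 + (lo - s0)
                q_hi = t0 + (hi - s0)  # exclusive
                if best_chain.target_strand == "-":
                    f_lo = best_chain.target_size - q_hi
                    f_hi = best_chain.target_size - q_lo
                else:
                    f_lo, f_hi = q_lo, q_hi
                positions.append((f_lo, f_hi))
        lo = min(p[0] for p in positions)
        hi = max(p[1] for p in positions)
        mapped = GenomicInterval(
            best_chain.target_name, lo, hi, name=interval.name
        )
        return LiftResult(
            "mapped", interval, mapped, best_bases, fraction, best_chain.chain_id
        )
    total = sum(per_chain_bases)
    contributing = sum(1 for b in per_chain_bases if b > 0)
    if total / length >= min_match and contributing > 1:
        return LiftResult("split", interval, None, best_bases, fraction,
                          best_chain.chain_id)
    return LiftResult("below_min_match", interval, None, best_bases, fraction,
                      best_chain.chain_id)


def lift_collection(
    peaks: IntervalCollection,
    chains: Sequence[Chain],
    min_match: float = 0.7,
) -> tuple[IntervalCollection, list[LiftResult], dict[str, int]]:
    """Lift every peak; returns (mapped collection, per-peak results,
    per-status tally).  Peak names are preserved on mapped output."""
    index = _index_chains(list(chains))
    results = [lift_interval(iv, index, min_match) for iv in peaks]
    mapped = IntervalCollection(
        [r.mapped for r in results if r.status == "mapped"]
    )
    tally: dict[str, int] = {}
    for r in results:
        tally[r.status] = tally.get(r.status, 0) + 1
    return mapped, results, tally


# ---------------------------------------------------------------------------
# variant overlap


DEFAULT_CLASS_LABELS = (
    "pathogenic",
    "likely_pathogenic",
    "benign",
    "likely_benign",
    "unknown_significance",
)
DEFAULT_FEATURE_LABELS = ("exonic", "intronic", "splice", "utr", "intergenic")


@dataclass(slots=True)
class VariantRecord:
    """One catalog variant; ``position`` is 1-based as in variant tables."""

    variant_id: str
    chrom: str
    position: int
    gene: str = ""
    pathogenicity: str = "unknown_significance"
    feature: str = "intergenic"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("variant position must be >= 1 (1-based)")

    @property
    def position0(self) -> int:
        """0-based coordinate."""
        return self.position - 1


@dataclass(slots=True)
class OverlapSummary:
    """Variant-in-region cross-tabulation (feature x pathogenicity)."""

    table: pd.DataFrame
    hits: list[tuple[VariantRecord, str]]  # (variant, region id)

    @property
    def total_overlapping(self) -> int:
        return int(self.table.to_numpy().sum())


def read_variant_table(source: TextIO) -> list[VariantRecord]:
    """Tab-separated variant table with a header naming at least
    ``id, chrom, position, gene, pathogenicity, feature``."""
    frame = pd.read_csv(source, sep="\t", dtype=str)
    required = {"id", "chrom", "position"}
    if not required.issubset(frame.columns):
        raise ValueError(f"variant table needs columns {sorted(required)}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            VariantRecord(
                variant_id=str(row.id),
                chrom=str(row.chrom),
                position=int(row.position),
                gene=str(getattr(row, "gene", "") or ""),
                pathogenicity=str(
                    getattr(row, "pathogenicity", "unknown_significance")
                ),
                feature=str(getattr(row, "feature", "intergenic")),
            )
        )
    return out


def overlap_variants(
    regions: IntervalCollection,
    variants: Sequence[VariantRecord],
    class_labels: Sequence[str] = DEFAULT_CLASS_LABELS,
    feature_labels: Sequence[str] = DEFAULT_FEATURE_LABELS,
) -> OverlapSummary:
    """Cross-tabulate variants falling inside mapped regions.

    A 1-based variant position p overlaps [start, end) iff p - 1 lies in
    the half-open interval.  Labels outside the declared vocabularies are
    tallied under "other" with a warning.
    """
    by_chrom: dict[str, tuple[list[int], list[GenomicInterval]]] = {}
    for chrom, ivs in regions.by_chrom().items():
        by_chrom[chrom] = ([iv.start for iv in ivs], ivs)
    classes = list(class_labels) + ["other"]
    features = list(feature_labels) + ["other"]
    table = pd.DataFrame(0, index=features, columns=classes)
    hits: list[tuple[VariantRecord, str]] = []
    warned: set[str] = set()
    for v in variants:
        group = by_chrom.get(v.chrom)
        if group is None:
            continue
        starts, ivs = group
        j = bisect_right(starts, v.position0) - 1
        hit_region = None
        while j >= 0:
            iv = ivs[j]
            if iv.start <= v.position0 < iv.end:
                hit_region = iv
                break
            if iv.end <= v.position0 and regions.disjoint:
                break
            j -= 1
        if hit_region is None:
            continue
        cls = v.pathogenicity if v.pathogenicity in class_labels else "other"
        feat = v.feature if v.feature in feature_labels else "other"
        if cls == "other" and v.pathogenicity not in warned:
            warnings.warn(f"unknown pathogenicity label {v.pathogenicity!r}")
            warned.add(v.pathogenicity)
        if feat == "other" and v.feature not in warned:
            warnings.warn(f"unknown feature label {v.feature!r}")
            warned.add(v.feature)
        table.loc[feat, cls] += 1
        rid = hit_region.name if hit_region.name else str(hit_region)
        hits.append((v, rid))
    return OverlapSummary(table=table, hits=hits)


def variants_in_motifs(
    window: SequenceWindow,
    hits: Sequence[MotifHit],
    motif_lengths: Mapping[str, int],
    chain: Chain,
    variants: Sequence[VariantRecord],
) -> list[tuple[VariantRecord, str | None, bool]]:
    """Flag variants (target-assembly coordinates) falling inside motif
    occurrences of a source peak window.

    Each variant's position is projected back to the source assembly with
    the chain's inverse block arithmetic; a variant is flagged with a motif
    name when its source position falls in [hit start, hit start + motif
    length) for some hit.  Returns (variant, motif name or None,
    projectable) — variants landing in unaligned gaps are reported as
    unprojectable (projectable=False).
    """
    out: list[tuple[VariantRecord, str | None, bool]] = []
    for v in variants:
        src = chain.map_back(v.position0)
        if src is None:
            out.append((v, None, False))
            continue
        flagged = None
        for h in hits:
            start = window.start + window.center_index + h.offset
            if start <= src < start + motif_lengths[h.motif]:
                flagged = h.motif
                break
        out.append((v, flagged, True))
    return out
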