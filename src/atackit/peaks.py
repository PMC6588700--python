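"""Reproducible-peak construction, cell-type-specific peaks and annotation.

The workflow mirrors the standard sorted-population ATAC-seq recipe: peaks
are called per biological replicate upstream; here a peak is *reproducible*
when it overlaps (>= 1 bp) a peak in at least one other replicate of the
same sample type, the union of reproducible peaks is distance-merged
(default gap 100 bp), ENCODE-blacklist regions are removed whole, and
population-specific peaks are obtained by subtracting a comparison panel
(the sorted-negative population plus external tissue peak sets).

Annotation assigns each peak to the gene with the nearest TSS (by peak
midpoint), classifies it against genomic feature catalogs by a precedence
order, and summarises observed vs. genome-coverage-expected counts per
feature class.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from math import log2
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalCollection,
    _OverlapIndex,
    merge_within,
    overlap_filter,
    subtract_nonoverlapping,
    total_coverage_bp,
    union,
)

__all__ = [
    "SampleMeta",
    "PeakCallSet",
    "TssRecord",
    "AnnotationCatalog",
    "PeakAnnotation",
    "FeatureEnrichment",
    "DEFAULT_PRECEDENCE",
    "reproducible_peaks",
    "remove_blacklist",
    "specific_peaks",
    "assign_nearest_tss",
    "classify_feature",
    "annotate_peaks",
    "feature_enrichment",
    "map_known_regions",
    "tss_distance_profile",
    "read_tss_table",
]


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """Identity of one sequenced sample: population group (e.g. sorted
    EGFP-high vs EGFP-negative), developmental stage, replicate index."""

    sample_id: str
    group: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")

    @property
    def sample_type(self) -> tuple[str, str]:
        return (self.group, self.stage)


@dataclass(slots=True)
class PeakCallSet:
    """Per-replicate peak calls (inputs; produced upstream by a caller)."""

    meta: SampleMeta
    peaks: IntervalCollection


@dataclass(frozen=True, slots=True)
class TssRecord:
    gene: str
    chrom: str
    position: int  # 0-based
    strand: str


class AnnotationCatalog:
    """Gene TSS table plus named feature-class interval catalogs.

    ``promoter_window`` generates a promoter class from the TSS table
    (default TSS -1000/+100 bp in gene orientation) when none is supplied.
    CpG islands are treated as an independent overlay, not a transcript
    part, so a peak can be e.g. promoter-class *and* CpG-overlapping.
    """

    def __init__(
        self,
        tss_table: Sequence[TssRecord],
        feature_classes: Mapping[str, IntervalCollection] | None = None,
        genome: GenomeLayout | None = None,
        cpg_islands: IntervalCollection | None = None,
        promoter_window: tuple[int, int] = (1000, 100),
    ) -> None:
        self.tss_table = list(tss_table)
        self.feature_classes = dict(feature_classes or {})
        self.genome = genome
        self.cpg_islands = cpg_islands
        if genome is not None:
            for rec in self.tss_table:
                if rec.chrom in genome and rec.position >= genome[rec.chrom]:
                    raise ValueError(
                        f"TSS of {rec.gene} at {rec.chrom}:{rec.position} "
                        "outside chromosome"
                    )
        if "promoter" not in self.feature_classes and self.tss_table:
            up, down = promoter_window
            proms = []
            for rec in self.tss_table:
                if rec.strand == "-":
                    start, end = rec.position - down, rec.position + up
                else:
                    start, end = rec.position - up, rec.position + down
                start = max(0, start)
                if genome is not None and rec.chrom in genome:
                    end = min(end, genome[rec.chrom])
                if start < end:
                    proms.append(GenomicInterval(rec.chrom, start, end, name=rec.gene))
            self.feature_classes["promoter"] = IntervalCollection(proms)
        # per-chromosome sorted TSS arrays for nearest lookup
        self._tss_by_chrom: dict[str, list[tuple[int, str, str]]] = {}
        for rec in self.tss_table:
            self._tss_by_chrom.setdefault(rec.chrom, []).append(
                (rec.position, rec.gene, rec.strand)
            )
        for entries in self._tss_by_chrom.values():
            entries.sort()

    def nearest_tss(self, chrom: str, point: int) -> tuple[int, str, str] | None:
        """Nearest (position, gene, strand) to ``point``; ties go to the
        lower-coordinate TSS (then lexicographic gene id)."""
        entries = self._tss_by_chrom.get(chrom)
        if not entries:
            return None
        positions = [e[0] for e in entries]
        i = bisect_left(positions, point)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(entries):
                cand = entries[j]
                if (
                    best is None
                    or abs(cand[0] - point) < abs(best[0] - point)
                    or (abs(cand[0] - point) == abs(best[0] - point) and cand < best)
                ):
                    best = cand
        return best


@dataclass(slots=True)
class PeakAnnotation:
    """Nearest-gene assignment and feature class for one peak.

    ``distance`` is peak-center minus TSS in gene orientation: positive
    means the peak center lies downstream of the TSS.
    """

    peak: GenomicInterval
    gene: str | None
    distance: int | None
    feature_class: str
    cpg_overlap: bool = False

    @property
    def assigned(self) -> bool:
        return self.gene is not None


@dataclass(slots=True)
class FeatureEnrichment:
    """Observed vs. expected peak counts per feature class.

    Expected counts assume uniform peak placement: total peaks times the
    class's fraction of genome coverage.  log2 ratios use a 0.5
    pseudo-count floor on both sides so empty classes stay finite.
    """

    observed: dict[str, int]
    expected: dict[str, float]
    log2_enrichment: dict[str, float]


DEFAULT_PRECEDENCE = ("promoter", "5utr", "exon", "3utr", "tts", "intron")


def reproducible_peaks(
    replicates: Sequence[PeakCallSet],
    merge_gap_bp: int = 100,
    mode: str = "union",
) -> IntervalCollection:
    """Peaks supported in >= 2 replicates of one sample type, merged.

    ``mode="union"`` keeps, over all replicates, every peak overlapping
    (>= 1 bp) a peak in at least one *other* replicate, then merges the
    union within ``merge_gap_bp``.  ``mode="pairwise"`` is the strict
    two-replicate reading: peaks of the first replicate supported by the
    second, then merged.
    """
    if len(replicates) < 2:
        raise ValueError("reproducibility is undefined with fewer than 2 replicates")
    sample_types = {r.meta.sample_type for r in replicates}
    if len(sample_types) != 1:
        raise ValueError(f"replicates span multiple sample types: {sample_types}")
    if mode == "pairwise":
        kept = [overlap_filter(replicates[0].peaks, replicates[1].peaks)]
    elif mode == "union":
        kept = []
        for i, rep in enumerate(replicates):
            others = union(r.peaks for j, r in enumerate(replicates) if j != i)
            kept.append(overlap_filter(rep.peaks, others))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return merge_within(union(kept), merge_gap_bp)


def remove_blacklist(
    peaks: IntervalCollection, blacklist: IntervalCollection
) -> IntervalCollection:
    """Drop peaks touching (>= 1 bp) any artefact-prone blacklist region;
    removal is whole-interval, never trimming."""
    return subtract_nonoverlapping(peaks, blacklist)


def specific_peaks(
    target: IntervalCollection, panel: Iterable[IntervalCollection]
) -> IntervalCollection:
    """Target peaks overlapping zero peaks in any panel collection."""
    return subtract_nonoverlapping(target, union(panel))


def assign_nearest_tss(
    peaks: IntervalCollection, catalog: AnnotationCatalog
) -> list[PeakAnnotation]:
    """Assign each peak to the gene minimizing |peak center - TSS|.

    Peaks on chromosomes with no TSS are flagged unassigned (gene None).
    Feature class is filled by :func:`classify_feature`; this function
    leaves it as "unclassified".
    """
    if not catalog.tss_table:
        raise ValueError("catalog has no TSS records")
    out = []
    for peak in peaks:
        hit = catalog.nearest_tss(peak.chrom, peak.center)
        if hit is None:
            out.append(PeakAnnotation(peak, None, None, "unclassified"))
        else:
            pos, gene, strand = hit
            signed = peak.center - pos if strand != "-" else pos - peak.center
            out.append(PeakAnnotation(peak, gene, signed, "unclassified"))
    return out


def classify_feature(
    peaks: IntervalCollection,
    catalog: AnnotationCatalog,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> list[str]:
    """Highest-precedence feature class overlapping (>= 1 bp) each peak,
    else "intergenic".  Classes in ``precedence`` must exist in the catalog
    when nonempty there; unknown names raise a configuration error."""
    for cls in precedence:
        if cls not in catalog.feature_classes:
            raise ValueError(f"precedence names unknown feature class {cls!r}")
    indexes = {
        cls: _OverlapIndex(catalog.feature_classes[cls]) for cls in precedence
    }
    out = []
    for peak in peaks:
        for cls in precedence:
            if indexes[cls].overlaps_any(peak):
                out.append(cls)
                break
        else:
            out.append("intergenic")
    return out


def annotate_peaks(
    peaks: IntervalCollection,
    catalog: AnnotationCatalog,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> list[PeakAnnotation]:
    """Nearest-TSS assignment plus feature classification plus CpG overlay.

    Precedence entries naming classes absent from the catalog are dropped
    here (a minimal catalog need not carry every class); pass an explicit
    precedence to :func:`classify_feature` for strict checking.
    """
    annotations = assign_nearest_tss(peaks, catalog)
    effective = [c for c in precedence if c in catalog.feature_classes]
    classes = classify_feature(peaks, catalog, effective)
    cpg_index = (
        _OverlapIndex(catalog.cpg_islands) if catalog.cpg_islands is not None else None
    )
    for ann, cls in zip(annotations, classes):
        ann.feature_class = cls
        if cpg_index is not None:
            ann.cpg_overlap = cpg_index.overlaps_any(ann.peak)
    return annotations


def feature_enrichment(
    annotations: Sequence[PeakAnnotation],
    catalog: AnnotationCatalog,
    pseudo: float = 0.5,
) -> FeatureEnrichment:
    """Observed vs. uniform-expectation peak counts per feature class.

    expected(c) = n_peaks * coverage_bp(c) / genome_bp;
    log2 enrichment = log2((obs + pseudo) / (exp + pseudo)).
    """
    if catalog.genome is None:
        raise ValueError("feature enrichment requires a genome layout")
    genome_bp = catalog.genome.total_bp
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    classes = list(catalog.feature_classes) + ["intergenic"]
    observed = {cls: 0 for cls in classes}
    for ann in annotations:
        observed[ann.feature_class] = observed.get(ann.feature_class, 0) + 1
    n = len(annotations)
    covered = {
        cls: total_coverage_bp(coll) for cls, coll in catalog.feature_classes.items()
    }
    # intergenic expectation: genome not covered by any class
    class_union_bp = total_coverage_bp(union(catalog.feature_classes.values()))
    covered["intergenic"] = genome_bp - class_union_bp
    expected = {cls: n * covered[cls] / genome_bp for cls in classes}
    enrich = {
        cls: log2((observed[cls] + pseudo) / (expected[cls] + pseudo))
        for cls in classes
    }
    return FeatureEnrichment(observed, expected, enrich)


def map_known_regions(
    peaks: IntervalCollection, curated: IntervalCollection
) -> tuple[list[tuple[str, bool, list[str]]], tuple[int, int]]:
    """Overlap report of peaks against a curated (named) region catalog.

    Returns per-region rows ``(region name, hit, overlapping peak ids)`` and
    a ``(n_hit, n_total)`` summary, e.g. how many literature-curated otic
    enhancers/promoters are detected as open chromatin.
    """
    index = _OverlapIndex(peaks)
    by_chrom = peaks.by_chrom()
    rows = []
    n_hit = 0
    for i, region in enumerate(curated):
        name = region.name if region.name is not None else f"region_{i + 1}"
        hits: list[str] = []
        if index.overlaps_any(region):
            for peak in by_chrom.get(region.chrom, ()):
                if peak.overlap_bp(region) >= 1:
                    pid = peak.name if peak.name is not None else str(peak)
                    hits.append(pid)
        rows.append((name, bool(hits), hits))
        n_hit += bool(hits)
    return rows, (n_hit, len(curated))


def tss_distance_profile(
    annotations: Sequence[PeakAnnotation], bin_edges: Sequence[float]
) -> np.ndarray:
    """Histogram of signed peak-center-to-TSS distances.

    ``bin_edges`` must be strictly increasing; the first and last bins are
    open-ended (distances below the first edge fall in bin 0, at or above
    the last edge in the final bin), so counts always sum to the number of
    assigned peaks.  Returns ``len(bin_edges) + 1`` counts.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    distances = np.array(
        [ann.distance for ann in annotations if ann.assigned], dtype=float
    )
    counts = np.zeros(len(edges) + 1, dtype=int)
    if len(distances):
        idx = np.searchsorted(edges, distances, side="right")
        np.add.at(counts, idx, 1)
    return counts


def read_tss_table(source: TextIO) -> list[TssRecord]:
    """Read a tab-separated (gene, chrom, position, strand) table with
    0-based positions; ``#`` comment lines skipped."""
    out = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"TSS table line {lineno}: expected 4 fields")
        gene, chrom, pos, strand = fields[0], fields[1], fields[2], fields[3]
        try:
            position = int(pos)
        except ValueError as exc:
            raise ValueError(f"TSS table line {lineno}: non-integer position") from exc
        out.append(TssRecord(gene, chrom, position, strand))
    return out
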