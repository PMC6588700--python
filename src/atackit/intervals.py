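"""Genomic interval data model and the set algebra the pipeline is built on.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; 1-based inputs (variant tables) are converted at their parser
boundary.  Chromosome names are compared by exact string equality — no
"chr" aliasing — so that input mismatches surface as empty overlaps rather
than silent coercion.

Semantics mirror the classic command-line tools:

* :func:`overlap_filter` / :func:`subtract_nonoverlapping` — element-wise
  ``bedops -e`` / ``bedops -n`` (an interval is kept or dropped whole).
* :func:`merge_within` — ``bedtools merge -d``; a gap of exactly ``d``
  bases still merges, ``d + 1`` does not.
* :func:`multiset_intersection_sizes` — Venn-style exclusive categories
  over 2–5 peak/region sets.
"""

from __future__ import annotations

import sys
import warnings
from bisect import bisect_left
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

__all__ = [
    "GenomicInterval",
    "IntervalCollection",
    "GenomeLayout",
    "BedParseError",
    "read_intervals",
    "write_intervals",
    "overlap_filter",
    "subtract_nonoverlapping",
    "merge_within",
    "union",
    "multiset_intersection_sizes",
    "total_coverage_bp",
]


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalCollection:
    """An ordered sequence of :class:`GenomicInterval`.

    The collection preserves insertion order (BED input order) unless it was
    produced by an operation that guarantees sorted output, in which case
    ``disjoint`` may additionally be set, promising that no two intervals on
    one chromosome share a base.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        disjoint: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.disjoint = disjoint

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalCollection):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:  # pragma: no cover - convenience
        return f"IntervalCollection({len(self)} intervals, disjoint={self.disjoint})"

    def sorted(self) -> "IntervalCollection":
        """Stable sort by (chrom, start, end); equal keys keep input order."""
        out = IntervalCollection(sorted(self.intervals, key=GenomicInterval.key))
        out.disjoint = self.disjoint
        return out

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        """Intervals grouped per chromosome, each group sorted."""
        groups: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            groups.setdefault(iv.chrom, []).append(iv)
        for ivs in groups.values():
            ivs.sort(key=GenomicInterval.key)
        return groups

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}


class GenomeLayout:
    """Chromosome name -> length (bases).  All lengths must be positive."""

    def __init__(self, lengths: Mapping[str, int]) -> None:
        for chrom, n in lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom!r} has nonpositive length {n}")
        self.lengths: dict[str, int] = dict(lengths)

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def validate(self, collection: IntervalCollection) -> None:
        """Raise if any interval exceeds its chromosome bounds."""
        for iv in collection:
            if iv.chrom not in self.lengths:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > self.lengths[iv.chrom]:
                raise ValueError(
                    f"interval {iv} exceeds {iv.chrom} length {self.lengths[iv.chrom]}"
                )


class BedParseError(ValueError):
    """A malformed BED record; message names the offending line number."""


def read_intervals(source: TextIO, dialect: str = "bed3") -> IntervalCollection:
    """Parse a BED3 or BED6 stream into an :class:`IntervalCollection`.

    Input order is preserved.  ``track``/``browser`` lines are skipped with
    a warning; blank lines and ``#`` comments are skipped silently.
    """
    if dialect not in ("bed3", "bed6"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith(("track", "browser")):
            warnings.warn(f"line {lineno}: skipping {line.split()[0]} line")
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedParseError(f"line {lineno}: expected >=3 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
        name = score = None
        strand = "."
        if dialect == "bed6":
            if len(fields) >= 4 and fields[3] not in ("", "."):
                name = fields[3]
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: non-numeric score") from exc
            if len(fields) >= 6:
                strand = fields[5]
                if strand == "−":  # unicode minus tolerated on input
                    strand = "-"
        try:
            out.append(
                GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
            )
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: {exc}") from exc
    return IntervalCollection(out)


def write_intervals(
    collection: IntervalCollection, sink: TextIO = sys.stdout, dialect: str = "bed3"
) -> None:
    """Write BED3 or BED6 (tab-separated, no header)."""
    for iv in collection:
        if dialect == "bed3":
            sink.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            sink.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# set algebra


def _max_single_overlap(
    iv: GenomicInterval, starts: Sequence[int], sorted_ivs: Sequence[GenomicInterval]
) -> int:
    """Largest base overlap between ``iv`` and any single interval of a
    sorted per-chromosome list (``starts`` = their start coordinates)."""
    best = 0
    # candidates: all with start < iv.end; scan left from there until ends
    # cannot reach iv.start any more.  Lists are sorted by start so we walk
    # back linearly; for peak-scale inputs this is fast enough.
    hi = bisect_left(starts, iv.end)
    for j in range(hi - 1, -1, -1):
        other = sorted_ivs[j]
        if other.end > iv.start:
            best = max(best, min(iv.end, other.end) - max(iv.start, other.start))
            if best >= iv.length:
                break
        # cannot early-exit on other.end <= iv.start alone (ends not sorted),
        # but once starts are far left of iv.start minus the max length seen,
        # further hits are impossible only if we track max end; keep simple.
    return best


class _OverlapIndex:
    """Per-chromosome sorted interval index answering max-single-overlap and
    any-overlap queries against a fixed collection."""

    def __init__(self, collection: IntervalCollection) -> None:
        self._groups: dict[str, tuple[list[int], list[GenomicInterval]]] = {}
        for chrom, ivs in collection.by_chrom().items():
            self._groups[chrom] = ([iv.start for iv in ivs], ivs)

    def max_overlap(self, iv: GenomicInterval) -> int:
        group = self._groups.get(iv.chrom)
        if group is None:
            return 0
        return _max_single_overlap(iv, group[0], group[1])

    def overlaps_any(self, iv: GenomicInterval, min_bp: int = 1) -> bool:
        return self.max_overlap(iv) >= min_bp


def overlap_filter(
    a: IntervalCollection, b: IntervalCollection, min_overlap_bp: int = 1
) -> IntervalCollection:
    """Intervals of ``a`` sharing >= ``min_overlap_bp`` bases with at least
    one single interval of ``b`` (``bedops -e`` element semantics).

    Output intervals are the originals from ``a``, unmodified, in ``a``'s
    order.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be a positive integer")
    index = _OverlapIndex(b)
    return IntervalCollection(
        iv for iv in a if index.overlaps_any(iv, min_overlap_bp)
    )


def subtract_nonoverlapping(
    a: IntervalCollection, b: IntervalCollection
) -> IntervalCollection:
    """Intervals of ``a`` sharing zero bases with every interval of ``b``
    (``bedops -n 1`` element semantics: any overlap removes the whole
    interval; adjacency does not)."""
    index = _OverlapIndex(b)
    return IntervalCollection(iv for iv in a if not index.overlaps_any(iv))


def merge_within(a: IntervalCollection, max_gap_bp: int = 0) -> IntervalCollection:
    """``bedtools merge -d`` semantics: intervals on one chromosome whose
    separation (start of next minus end of previous; overlap counts as 0)
    is <= ``max_gap_bp`` are covered by a single output interval.

    Output is sorted by (chrom, start, end) with the disjoint flag set and
    carries no names/scores.  Idempotent for any fixed ``max_gap_bp``.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be nonnegative")
    merged: list[GenomicInterval] = []
    groups = a.by_chrom()
    for chrom in sorted(groups):
        ivs = groups[chrom]
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap_bp:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalCollection(merged, disjoint=True)


def union(collections: Iterable[IntervalCollection]) -> IntervalCollection:
    """Concatenation of collections (not merged)."""
    out: list[GenomicInterval] = []
    for coll in collections:
        out.extend(coll.intervals)
    return IntervalCollection(out)


def multiset_intersection_sizes(
    collections: Mapping[str, IntervalCollection],
    semantics: str = "regions",
) -> dict[frozenset[str], int]:
    """Venn-style exclusive-category counts over 2-5 named collections.

    With ``semantics="regions"`` (default) the union of all inputs is merged
    into disjoint regions (gap 0) and each region is assigned to the exact
    set of collections overlapping it; the returned mapping gives, for every
    nonempty subset of names, the number of union regions overlapped by
    exactly that subset.  ``semantics="peaks"`` instead classifies each input
    interval of each collection by the exact set of collections it overlaps
    and counts intervals (an interval always belongs to its own collection's
    category at minimum); intervals occurring in several collections are
    counted once per occurrence.
    """
    names = list(collections)
    if not (2 <= len(names) <= 5):
        raise ValueError("multiset_intersection_sizes supports 2-5 collections")
    if semantics not in ("regions", "peaks"):
        raise ValueError(f"unknown semantics {semantics!r}")
    indexes = {name: _OverlapIndex(collections[name]) for name in names}
    counts: dict[frozenset[str], int] = {
        frozenset(s): 0
        for r in range(1, len(names) + 1)
        for s in combinations(names, r)
    }
    if semantics == "regions":
        regions = merge_within(union(collections.values()), 0)
        for region in regions:
            members = frozenset(
                name for name in names if indexes[name].overlaps_any(region)
            )
            counts[members] += 1
    else:
        for name in names:
            for iv in collections[name]:
                members = frozenset(
                    other for other in names if indexes[other].overlaps_any(iv)
                ) | {name}
                counts[members] += 1
    return counts


def total_coverage_bp(a: IntervalCollection) -> int:
    """Number of distinct bases covered by ``a`` (overlaps counted once)."""
    return sum(iv.length for iv in merge_within(a, 0)) if len(a) else 0
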