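"""PWM motif scanning, enrichment, centrality, similarity and co-occurrence.

Motifs are position weight matrices of per-position base probabilities,
scored by log2 odds against a background base composition.  Peaks are
represented by sequence windows centered on their midpoints; a window
matches a motif wherever the summed log-odds meets the motif's detection
threshold, on either strand.  Enrichment compares the fraction of target
peaks with >= 1 hit against a GC-matched background peak set with a
cumulative hypergeometric tail; centrality profiles bin hit offsets around
the peak center; co-occurrence compares the observed joint hit frequency of
motif pairs with a background or independence expectation.

Masked sequence (lowercase or N) never matches any PWM column.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalCollection

__all__ = [
    "PositionWeightMatrix",
    "SequenceWindow",
    "MotifHit",
    "MotifEnrichmentRecord",
    "CooccurrenceMatrix",
    "read_homer_motifs",
    "write_homer_motifs",
    "read_count_matrix_motifs",
    "extract_windows",
    "scan",
    "scan_library",
    "motif_enrichment",
    "positional_profile",
    "motif_similarity",
    "cooccurrence",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class PositionWeightMatrix:
    """L x 4 base-probability matrix (columns A, C, G, T) with a log-odds
    detection threshold in bits.

    When a motif file carries no threshold the default is 80% of the
    maximum achievable log-odds under a uniform background.
    """

    name: str
    probabilities: np.ndarray
    threshold: float | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValueError(f"motif {self.name}: matrix must be L x 4")
        sums = self.probabilities.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"motif {self.name}: rows must each sum to 1")
        if self.threshold is None:
            self.threshold = 0.8 * self.max_score()
        elif self.threshold > self.max_score() + 1e-9:
            raise ValueError(
                f"motif {self.name}: threshold exceeds maximal achievable score"
            )

    def __len__(self) -> int:
        return self.probabilities.shape[0]

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """L x 4 log2(p/bg) with floor -20 bits for zero probabilities."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probabilities / bg)
        return np.maximum(lo, -20.0)

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background).max(axis=1).sum())

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.name, self.probabilities[::-1, ::-1], self.threshold, self.family
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=1))


@dataclass(slots=True)
class SequenceWindow:
    """Sequence centered on a peak midpoint.

    ``center_index`` is the position within ``sequence`` corresponding to
    the peak center; for untruncated windows it equals ``half_width``.
    ``start`` is the genomic coordinate of the window's first base.
    """

    peak_id: str
    chrom: str
    start: int
    sequence: str
    half_width: int
    center_index: int
    truncated: bool = False

    @property
    def gc_fraction(self) -> float:
        seq = self.sequence
        acgt = sum(seq.count(b) for b in BASES)
        if acgt == 0:
            return 0.0
        return (seq.count("G") + seq.count("C")) / acgt


@dataclass(slots=True)
class MotifHit:
    """One PWM occurrence in a window; ``offset`` is hit start relative to
    the window center (signed bp)."""

    peak_id: str
    motif: str
    offset: int
    strand: str
    score: float


def read_homer_motifs(source: TextIO) -> list[PositionWeightMatrix]:
    """Read HOMER-style motif text: ``>consensus<TAB>name<TAB>threshold``
    header lines followed by per-position A C G T probability rows."""
    motifs: list[PositionWeightMatrix] = []
    name = None
    threshold: float | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        if name is not None:
            motifs.append(
                PositionWeightMatrix(name, np.array(rows), threshold=threshold)
            )

    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            fields = line[1:].split("\t")
            name = fields[1] if len(fields) > 1 else fields[0]
            threshold = None
            if len(fields) > 2:
                try:
                    threshold = float(fields[2])  # interpreted in bits
                except ValueError:
                    threshold = None
            rows = []
        else:
            rows.append([float(x) for x in line.split()])
    flush()
    return motifs


def write_homer_motifs(
    motifs: Iterable[PositionWeightMatrix], sink: TextIO
) -> None:
    for m in motifs:
        sink.write(f">{m.consensus()}\t{m.name}\t{m.threshold:.6g}\n")
        for row in m.probabilities:
            sink.write("\t".join(f"{p:.6f}" for p in row) + "\n")


def read_count_matrix_motifs(
    source: TextIO, pseudo_count: float = 0.5
) -> list[PositionWeightMatrix]:
    """Minimal JASPAR-like count-matrix reader.

    Format: ``>name`` then four lines ``A [counts...]`` .. ``T [counts...]``
    (brackets optional).  Counts are normalized to probabilities per
    position with ``pseudo_count`` added to each cell.
    """
    motifs = []
    name = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        if name is None:
            return
        if set(rows) != set(BASES):
            raise ValueError(f"motif {name}: need one row per base A/C/G/T")
        counts = np.array([rows[b] for b in BASES]).T + pseudo_count
        motifs.append(
            PositionWeightMatrix(name, counts / counts.sum(axis=1, keepdims=True))
        )

    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
            rows = {}
        else:
            base, rest = line[0].upper(), line[1:]
            rows[base] = [float(x) for x in re.sub(r"[\[\]]", " ", rest).split()]
    flush()
    return motifs


def extract_windows(
    peaks: IntervalCollection,
    sequences: Mapping[str, str],
    half_width: int = 200,
    mask_lowercase: bool = True,
) -> list[SequenceWindow]:
    """Extract sequence windows of ``2 * half_width`` bp centered on peak
    midpoints; windows running off a chromosome end are truncated and
    flagged.  Lowercase (repeat-masked) bases become N when
    ``mask_lowercase``; N never matches any PWM column."""
    missing = sorted(peaks.chroms() - set(sequences))
    if missing:
        raise ValueError(f"sequences missing for chromosomes: {missing}")
    out = []
    for i, peak in enumerate(peaks):
        seq = sequences[peak.chrom]
        center = peak.center
        lo, hi = center - half_width, center + half_width
        trunc = lo < 0 or hi > len(seq)
        lo_c, hi_c = max(0, lo), min(len(seq), hi)
        text = str(seq[lo_c:hi_c])
        if mask_lowercase:
            text = re.sub(r"[a-z]", "N", text)
        text = text.upper()
        text = re.sub(f"[^{BASES}N]", "N", text)
        pid = peak.name if peak.name is not None else f"peak_{i + 1}"
        out.append(
            SequenceWindow(
                peak_id=pid,
                chrom=peak.chrom,
                start=lo_c,
                sequence=text,
                half_width=half_width,
                center_index=center - lo_c,
                truncated=trunc,
            )
        )
    return out


def _encode(seq: str) -> np.ndarray:
    """Map sequence to base indices; non-ACGT -> 4 (sentinel)."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def scan(
    pwm: PositionWeightMatrix,
    windows: Sequence[SequenceWindow],
    background: np.ndarray | None = None,
) -> list[MotifHit]:
    """All occurrences of ``pwm`` in the windows, both strands.

    Score at position i = sum over motif columns of log2(p/bg) for the
    observed bases; any N in the footprint disqualifies the position.
    Overlapping hits are all reported.  A minus-strand hit at offset o
    means the reverse complement of the motif starts at o on the forward
    sequence.
    """
    L = len(pwm)
    lo_fwd = pwm.log_odds(background)
    lo_rev = pwm.reverse_complement().log_odds(background)
    hits: list[MotifHit] = []
    for window in windows:
        n = len(window.sequence)
        if n < L:
            continue
        enc = _encode(window.sequence)
        valid = enc < 4
        # pad invalid with -inf scores
        for strand, lo_mat in (("+", lo_fwd), ("-", lo_rev)):
            scores = np.zeros(n - L + 1)
            ok = np.ones(n - L + 1, dtype=bool)
            for col in range(L):
                sl = enc[col : col + n - L + 1]
                vmask = valid[col : col + n - L + 1]
                ok &= vmask
                scores += np.where(vmask, lo_mat[col, np.clip(sl, 0, 3)], 0.0)
            passing = np.flatnonzero(ok & (scores >= pwm.threshold - 1e-9))
            for pos in passing:
                hits.append(
                    MotifHit(
                        peak_id=window.peak_id,
                        motif=pwm.name,
                        offset=int(pos) - window.center_index,
                        strand=strand,
                        score=float(scores[pos]),
                    )
                )
    return hits


def scan_library(
    pwms: Sequence[PositionWeightMatrix],
    windows: Sequence[SequenceWindow],
    background: np.ndarray | None = None,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for pwm in pwms:
        hits.extend(scan(pwm, windows, background))
    return hits


@dataclass(slots=True)
class MotifEnrichmentRecord:
    motif: str
    target_hits: int
    target_total: int
    background_hits: int
    background_total: int
    neg_log10_p: float
    fold: float

    @property
    def pvalue(self) -> float:
        return 10.0 ** (-self.neg_log10_p)


def _gc_matched_sample(
    target: Sequence[SequenceWindow],
    background: Sequence[SequenceWindow],
    rng: np.random.Generator,
    bin_width: float = 0.05,
) -> list[int]:
    """Indices into ``background`` resampled so its GC distribution matches
    the target's within ``bin_width`` GC bins (proportional sampling;
    sampling is with replacement when a bin is underpopulated)."""
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    t_gc = np.array([w.gc_fraction for w in target])
    b_gc = np.array([w.gc_fraction for w in background])
    t_bins = np.clip(np.digitize(t_gc, edges) - 1, 0, len(edges) - 2)
    b_bins = np.clip(np.digitize(b_gc, edges) - 1, 0, len(edges) - 2)
    n_out = len(background)
    chosen: list[int] = []
    t_frac = np.bincount(t_bins, minlength=len(edges) - 1) / len(target)
    for b in np.flatnonzero(t_frac > 0):
        pool = np.flatnonzero(b_bins == b)
        want = int(round(t_frac[b] * n_out))
        if want == 0:
            continue
        if len(pool) == 0:
            # no background sequence in this GC bin; borrow nearest bins
            order = np.argsort(np.abs(b_bins - b), kind="stable")
            pool = order[: max(1, want)]
        replace = want > len(pool)
        chosen.extend(rng.choice(pool, size=want, replace=replace).tolist())
    if not chosen:
        chosen = list(range(n_out))
    return sorted(chosen)


def motif_enrichment(
    target_windows: Sequence[SequenceWindow],
    background_windows: Sequence[SequenceWindow],
    pwms: Sequence[PositionWeightMatrix],
    background_frequencies: np.ndarray | None = None,
    gc_match: bool = True,
    rng: np.random.Generator | None = None,
) -> list[MotifEnrichmentRecord]:
    """Known-motif enrichment of target vs background peak windows.

    Per motif, the number of peaks with >= 1 hit is counted in the target
    and in a GC-matched background, and the upper-tail cumulative
    hypergeometric p-value asks whether target peaks are over-represented
    among all hit-bearing peaks.  Fold = target hit rate / background hit
    rate (0.5-peak pseudo-count on the background side to stay finite).
    Records are returned sorted by descending -log10 p.
    """
    if not target_windows:
        raise ValueError("empty target window set")
    if not background_windows:
        raise ValueError("empty background window set")
    rng = rng if rng is not None else np.random.default_rng(0)
    if gc_match:
        idx = _gc_matched_sample(target_windows, background_windows, rng)
        bg = [background_windows[i] for i in idx]
    else:
        bg = list(background_windows)
    # re-id so duplicates from with-replacement GC sampling count separately
    bg = [replace(w, peak_id=f"bg{i}") for i, w in enumerate(bg)]
    n_t, n_b = len(target_windows), len(bg)
    records = []
    for pwm in pwms:
        t_hit = len({h.peak_id for h in scan(pwm, target_windows)})
        b_hit = len({h.peak_id for h in scan(pwm, bg)})
        total_hit = t_hit + b_hit
        # upper tail: P(X >= t_hit), X ~ Hypergeom(N=n_t+n_b, K=total_hit, n=n_t)
        p = float(stats.hypergeom.sf(t_hit - 1, n_t + n_b, total_hit, n_t))
        p = min(1.0, max(p, 1e-300))
        fold = (t_hit / n_t) / ((b_hit + 0.5) / (n_b + 0.5))
        records.append(
            MotifEnrichmentRecord(
                motif=pwm.name,
                target_hits=t_hit,
                target_total=n_t,
                background_hits=b_hit,
                background_total=n_b,
                neg_log10_p=-math.log10(p),
                fold=fold,
            )
        )
    records.sort(key=lambda r: -r.neg_log10_p)
    return records


def positional_profile(
    hits: Sequence[MotifHit],
    half_width: int,
    bin_bp: int = 10,
    n_peaks: int | None = None,
) -> pd.DataFrame:
    """Motif frequency (hits per bp per peak) vs. offset from peak center.

    Bins tile [-half_width, half_width); the value in each bin is
    hit count / (n_peaks * bin_bp), so summing value * bin_bp * n_peaks
    over bins recovers the total hit count.
    """
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    if n_peaks is None:
        n_peaks = len({h.peak_id for h in hits}) or 1
    edges = np.arange(-half_width, half_width + bin_bp, bin_bp)
    motifs = sorted({h.motif for h in hits})
    table = {}
    for motif in motifs:
        offsets = np.array([h.offset for h in hits if h.motif == motif])
        counts, _ = np.histogram(offsets, bins=edges)
        table[motif] = counts / (n_peaks * bin_bp)
    frame = pd.DataFrame(table, index=pd.IntervalIndex.from_breaks(edges, closed="left"))
    frame.index.name = "offset_bin"
    return frame


def motif_similarity(
    pwms: Sequence[PositionWeightMatrix], min_overlap: int = 4
) -> pd.DataFrame:
    """Pairwise motif-matrix similarity.

    For each pair, the maximum Pearson correlation of flattened aligned
    probability columns over all ungapped offsets with >= ``min_overlap``
    overlapping columns, in both the direct and reverse-complement
    orientation.  Motifs shorter than ``min_overlap`` are excluded with a
    warning.
    """
    usable = []
    for pwm in pwms:
        if len(pwm) < min_overlap:
            warnings.warn(f"motif {pwm.name} shorter than {min_overlap}; excluded")
        else:
            usable.append(pwm)
    if len(usable) < 2:
        raise ValueError("need >= 2 usable motifs")
    names = [p.name for p in usable]
    out = np.eye(len(usable))
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            r = _best_alignment_corr(usable[i], usable[j], min_overlap)
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=names, columns=names)


def _best_alignment_corr(
    a: PositionWeightMatrix, b: PositionWeightMatrix, min_overlap: int
) -> float:
    best = -1.0
    for bb in (b, b.reverse_complement()):
        ma, mb = a.probabilities, bb.probabilities
        for offset in range(-(len(bb) - min_overlap), len(a) - min_overlap + 1):
            lo_a, hi_a = max(0, offset), min(len(a), offset + len(bb))
            if hi_a - lo_a < min_overlap:
                continue
            seg_a = ma[lo_a:hi_a].ravel()
            seg_b = mb[lo_a - offset : hi_a - offset].ravel()
            if np.ptp(seg_a) == 0 or np.ptp(seg_b) == 0:
                continue
            r = float(np.corrcoef(seg_a, seg_b)[0, 1])
            best = max(best, r)
    return best


@dataclass(slots=True)
class CooccurrenceMatrix:
    motifs: list[str]
    observed: np.ndarray
    expected: np.ndarray
    ratio: np.ndarray

    def to_frame(self, which: str = "ratio") -> pd.DataFrame:
        values = getattr(self, which)
        return pd.DataFrame(values, index=self.motifs, columns=self.motifs)


def _joint_frequencies(
    hits: Sequence[MotifHit], peak_ids: Sequence[str], motifs: Sequence[str]
) -> np.ndarray:
    """Fraction of peaks with >= 1 hit of motif i AND >= 1 of motif j;
    diagonal = fraction of peaks with >= 2 hits of motif i."""
    motif_index = {m: k for k, m in enumerate(motifs)}
    per_peak: dict[str, np.ndarray] = {
        pid: np.zeros(len(motifs), dtype=int) for pid in peak_ids
    }
    for h in hits:
        if h.peak_id in per_peak and h.motif in motif_index:
            per_peak[h.peak_id][motif_index[h.motif]] += 1
    n = max(1, len(peak_ids))
    obs = np.zeros((len(motifs), len(motifs)))
    for vec in per_peak.values():
        present = vec > 0
        obs += np.outer(present, present)
        np.fill_diagonal(obs, obs.diagonal() - present + (vec >= 2))
    return obs / n


def cooccurrence(
    hits: Sequence[MotifHit],
    target_peak_ids: Sequence[str],
    motifs: Sequence[str],
    expected_mode: str = "background",
    background_hits: Sequence[MotifHit] | None = None,
    background_peak_ids: Sequence[str] | None = None,
    epsilon: float = 1e-4,
) -> CooccurrenceMatrix:
    """Observed vs expected motif co-occurrence in target peaks.

    observed(i, j) = fraction of target peaks containing >= 1 hit of motif
    i and >= 1 of motif j (diagonal: >= 2 hits of motif i).  Expected comes
    from the same statistic on a background peak set
    (``expected_mode="background"``, the genomic-baseline reading) or from
    the product of target marginal frequencies
    (``expected_mode="independence"``).  ratio = (obs + eps) / (exp + eps).
    """
    obs = _joint_frequencies(hits, target_peak_ids, motifs)
    if expected_mode == "background":
        if background_hits is None or background_peak_ids is None:
            raise ValueError("background mode requires background hits and peak ids")
        exp = _joint_frequencies(background_hits, background_peak_ids, motifs)
    elif expected_mode == "independence":
        motif_index = {m: k for k, m in enumerate(motifs)}
        marg = np.zeros(len(motifs))
        per_peak: dict[str, set[str]] = {pid: set() for pid in target_peak_ids}
        for h in hits:
            if h.peak_id in per_peak:
                per_peak[h.peak_id].add(h.motif)
        for present in per_peak.values():
            for m in present:
                if m in motif_index:
                    marg[motif_index[m]] += 1
        marg /= max(1, len(target_peak_ids))
        exp = np.outer(marg, marg)
    else:
        raise ValueError(f"unknown expected_mode {expected_mode!r}")
    ratio = (obs + epsilon) / (exp + epsilon)
    return CooccurrenceMatrix(list(motifs), obs, exp, ratio)
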