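"""Seedable synthetic-data generators for every input the pipeline consumes.

The generator emulates a sorted-population ATAC-seq study: two sorted cell
populations (reporter-high and reporter-negative) sampled at embryonic
stages with biological replicates.  It produces, with planted ground
truth:

* a small two-chromosome genome with controllable GC composition;
* a truth catalog of open-chromatin peaks, a subset specific to the
  high population;
* per-replicate peak calls with boundary jitter and per-peak dropout, plus
  private noise peaks that reproducibility filtering must remove;
* per-sample fragment sets whose per-region totals follow a negative
  binomial model with planted group effects and optional composition bias,
  plus uniform background fragments so FRiP is meaningful;
* PWM motif libraries and sequences with motifs planted at peak centers
  (Gaussian offsets, strand-random, optional pair coupling/multiplicity);
* a collinear-with-indels alignment chain to a second assembly with an
  exact base-level mapping oracle;
* a 1-based variant table with known peak and motif overlaps;
* gene sets (GMT) including one set loaded on high-scoring genes.

Everything is a pure function of (config, seed): one `numpy` Generator
drives all draws, so equal configs give byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .diffacc import FragmentSet
from .intervals import GenomeLayout, GenomicInterval, IntervalCollection
from .liftover import Chain, ChainBlock, VariantRecord
from .motifs import PositionWeightMatrix, reverse_complement
from .peaks import (
    AnnotationCatalog,
    PeakCallSet,
    SampleMeta,
    TssRecord,
    assign_nearest_tss,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "make_genome",
    "make_motif_library",
    "plant_motifs",
    "make_chain",
    "write_bundle",
]

BASES = np.array(list("ACGT"))


@dataclass(slots=True)
class GenomeModel:
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 120_000, "chr2": 120_000}
    )
    gc_fraction: float = 0.45
    gc_block_bp: int = 1_000  # GC varies between blocks for GC-matching tests
    gc_block_sd: float = 0.08


@dataclass(slots=True)
class PeakModel:
    n_peaks: int = 200
    width_range: tuple[int, int] = (250, 550)
    min_spacing_bp: int = 400  # clear space between truth peaks
    specific_fraction: float = 0.3  # open only in the high population
    jitter_sd_bp: float = 10.0
    dropout_prob: float = 0.1
    noise_peaks_per_replicate: int = 10


@dataclass(slots=True)
class CountModel:
    library_size: int = 25_000
    library_size_spread: float = 0.2  # lognormal sigma on per-sample depth
    mean_count: float = 60.0  # per-region expected fragments at depth 1.0
    mean_log_sd: float = 0.5  # region-to-region abundance spread (log2)
    dispersion: float = 0.1
    da_fraction: float = 0.1
    da_log2fc: float = 2.0
    background_fraction: float = 0.35  # fragments landing outside peaks
    fragment_length_mean: float = 180.0
    fragment_length_sd: float = 40.0
    composition_bias_fraction: float = 0.0
    composition_bias_factor: float = 1.0
    composition_bias_samples: tuple[str, ...] = ()


@dataclass(slots=True)
class MotifModel:
    n_motifs: int = 20
    length_range: tuple[int, int] = (8, 12)
    info: float = 0.97  # dominant-base probability per column
    planted_motifs: tuple[int, ...] = (0,)  # indices into the library
    planting_prob: float = 0.6
    offset_sd_bp: float = 20.0
    coupled_pair: tuple[int, int] | None = None
    coupling_prob: float = 0.0
    multiplicity_prob: float = 0.0  # chance of planting a second copy


@dataclass(slots=True)
class ChainModel:
    n_indels: int = 8
    indel_length_range: tuple[int, int] = (20, 200)
    insertion_prob: float = 0.5  # vs deletion


@dataclass(slots=True)
class VariantModel:
    n_variants: int = 200
    in_peak_fraction: float = 0.4
    in_motif_fraction: float = 0.05
    class_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            "pathogenic": 0.2,
            "likely_pathogenic": 0.1,
            "benign": 0.3,
            "likely_benign": 0.15,
            "unknown_significance": 0.25,
        }
    )
    feature_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            "exonic": 0.25,
            "intronic": 0.45,
            "splice": 0.05,
            "utr": 0.1,
            "intergenic": 0.15,
        }
    )


@dataclass(slots=True)
class SyntheticConfig:
    """Study-condition bundle for the generator; see the methods note for
    the rationale behind each default."""

    seed: int = 0
    genome: GenomeModel = field(default_factory=GenomeModel)
    n_genes: int = 120
    peaks: PeakModel = field(default_factory=PeakModel)
    counts: CountModel = field(default_factory=CountModel)
    motifs: MotifModel = field(default_factory=MotifModel)
    chain: ChainModel = field(default_factory=ChainModel)
    variants: VariantModel = field(default_factory=VariantModel)
    groups: tuple[str, ...] = ("high", "neg")
    stages: tuple[str, ...] = ("E12", "E14.5")
    replicates: int = 3
    compared_stage: str = "E14.5"
    n_gene_sets: int = 15
    gene_set_size_range: tuple[int, int] = (25, 40)

    def validate(self) -> None:
        c = self.counts
        for name, p in (
            ("dropout_prob", self.peaks.dropout_prob),
            ("specific_fraction", self.peaks.specific_fraction),
            ("da_fraction", c.da_fraction),
            ("background_fraction", c.background_fraction),
            ("planting_prob", self.motifs.planting_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if c.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if any(n <= 0 for n in self.genome.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per sample type")


@dataclass(slots=True)
class SyntheticTruth:
    """Planted ground truth every pipeline stage is scored against."""

    peaks: IntervalCollection  # truth catalog, names peak_i
    peak_groups: dict[str, list[str]]  # peak name -> groups where open
    specific_peaks: list[str]  # open only in the high group
    replicate_retained: dict[str, list[str]]  # sample id -> retained names
    da_log2fc: dict[str, float]  # region id (truth peak name) -> planted fc
    motif_placements: list[dict]  # peak, motif, offset, strand
    chain_oracle: dict[str, "ChainOracle"]
    variant_in_peak: list[str]  # variant ids planted inside mapped peaks
    variant_in_motif: dict[str, str]  # variant id -> motif name
    loaded_gene_set: str  # name of the set planted on high-scoring genes

    def expected_reproducible(self, group: str, stage: str) -> set[str]:
        """Truth peak names retained in >= 2 replicates of (group, stage)."""
        tallies: dict[str, int] = {}
        for sid, names in self.replicate_retained.items():
            g, s, _ = sid.split("_", 2)
            if (g, s) == (group, stage):
                for name in names:
                    tallies[name] = tallies.get(name, 0) + 1
        return {name for name, k in tallies.items() if k >= 2}

    def summary(self) -> dict:
        return {
            "n_truth_peaks": len(self.peaks),
            "n_specific": len(self.specific_peaks),
            "n_da": sum(1 for v in self.da_log2fc.values() if v != 0.0),
            "n_motif_placements": len(self.motif_placements),
            "n_variant_in_peak": len(self.variant_in_peak),
            "n_variant_in_motif": len(self.variant_in_motif),
        }


class ChainOracle:
    """Exact source->target base map for a collinear synthetic chain."""

    def __init__(self, segments: list[tuple[int, int, int]], target_size: int):
        # (source_start, size, target_start), strictly increasing
        self.segments = segments
        self.target_size = target_size

    def map_base(self, pos: int) -> int | None:
        for s0, size, t0 in self.segments:
            if s0 <= pos < s0 + size:
                return t0 + (pos - s0)
        return None

    def expected_status(
        self, interval: GenomicInterval, min_match: float = 0.7
    ) -> str:
        mapped = sum(
            1
            for p in range(interval.start, interval.end)
            if self.map_base(p) is not None
        )
        if mapped == 0:
            # a collinear chain always overlaps the whole chromosome span
            return "below_min_match"
        return "mapped" if mapped / interval.length >= min_match else "below_min_match"


@dataclass(slots=True)
class SyntheticDataset:
    """In-memory bundle of everything the generator produced."""

    config: SyntheticConfig
    genome: GenomeLayout
    sequences: dict[str, str]
    tss: list[TssRecord]
    feature_classes: dict[str, IntervalCollection]
    cpg_islands: IntervalCollection
    blacklist: IntervalCollection
    peak_calls: list[PeakCallSet]
    fragment_sets: list[FragmentSet]
    pwms: list[PositionWeightMatrix]
    chains: list[Chain]
    target_sizes: dict[str, int]
    variants: list[VariantRecord]
    gene_sets: dict[str, list[str]]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genome and annotation


def make_genome(model: GenomeModel, rng: np.random.Generator) -> dict[str, str]:
    """Random sequences with per-block GC control."""
    sequences = {}
    for chrom, length in model.chromosomes.items():
        parts = []
        pos = 0
        while pos < length:
            block = min(model.gc_block_bp, length - pos)
            gc = float(
                np.clip(rng.normal(model.gc_fraction, model.gc_block_sd), 0.1, 0.9)
            )
            probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            parts.append("".join(BASES[rng.choice(4, size=block, p=probs)]))
            pos += block
        sequences[chrom] = "".join(parts)
    return sequences


def _place_disjoint(
    rng: np.random.Generator,
    chromosomes: Mapping[str, int],
    n: int,
    width_range: tuple[int, int],
    min_spacing: int,
    avoid: Sequence[GenomicInterval] = (),
) -> list[GenomicInterval]:
    """Place n nonoverlapping intervals with clear spacing, rejection
    sampling with a retry budget."""
    placed: list[GenomicInterval] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosomes}
    for iv in avoid:
        taken.setdefault(iv.chrom, []).append((iv.start, iv.end))
    chroms = list(chromosomes)
    tries = 0
    while len(placed) < n and tries < 200 * n:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        limit = chromosomes[chrom] - width - 1
        if limit <= 1:
            continue
        start = int(rng.integers(1, limit))
        lo, hi = start - min_spacing, start + width + min_spacing
        if any(s < hi and e > lo for s, e in taken[chrom]):
            continue
        taken[chrom].append((start, start + width))
        placed.append(GenomicInterval(chrom, start, start + width))
    if len(placed) < n:
        raise ValueError(
            f"could not place {n} intervals; genome too small for the config"
        )
    placed.sort(key=GenomicInterval.key)
    return placed


def make_motif_library(
    model: MotifModel, rng: np.random.Generator
) -> list[PositionWeightMatrix]:
    """Sharp random PWMs (one dominant base per column)."""
    pwms = []
    for k in range(model.n_motifs):
        L = int(rng.integers(model.length_range[0], model.length_range[1] + 1))
        mat = np.full((L, 4), (1 - model.info) / 3)
        dominant = rng.integers(0, 4, size=L)
        mat[np.arange(L), dominant] = model.info
        pwms.append(PositionWeightMatrix(f"motif_{k + 1}", mat))
    return pwms


def plant_motifs(
    sequences: dict[str, str],
    peaks: IntervalCollection,
    pwms: Sequence[PositionWeightMatrix],
    model: MotifModel,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[dict]]:
    """Write motif consensus instances into peak centers.

    Instances are sampled from the PWM column distributions, placed at
    peak-center + Gaussian offset, random strand; coupled pairs are
    co-planted with the configured probability and extra copies with the
    multiplicity probability.  Placements that would leave the peak window
    or collide with an earlier placement are retried a few times, then
    skipped (and simply not recorded).
    """
    seqs = {c: list(s) for c, s in sequences.items()}
    placements: list[dict] = []

    def sample_instance(pwm: PositionWeightMatrix) -> str:
        # consensus instances: planted occurrences always clear the default
        # detection threshold, so recovery failures indicate scanner bugs,
        # not planting noise
        return pwm.consensus()

    def try_place(peak: GenomicInterval, pwm: PositionWeightMatrix,
                  occupied: list[tuple[int, int]]) -> None:
        for _ in range(8):
            offset = int(round(rng.normal(0.0, model.offset_sd_bp)))
            start = peak.center + offset
            end = start + len(pwm)
            if start < peak.start or end > peak.end:
                continue
            if any(s < end and e > start for s, e in occupied):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            inst = sample_instance(pwm)
            text = inst if strand == "+" else reverse_complement(inst)
            seqs[peak.chrom][start:end] = list(text)
            occupied.append((start, end))
            placements.append(
                {
                    "peak": peak.name,
                    "motif": pwm.name,
                    "offset": offset,
                    "strand": strand,
                    "start": start,
                }
            )
            return

    for peak in peaks:
        occupied: list[tuple[int, int]] = []
        for k in model.planted_motifs:
            if rng.random() < model.planting_prob:
                try_place(peak, pwms[k], occupied)
                if rng.random() < model.multiplicity_prob:
                    try_place(peak, pwms[k], occupied)
        if model.coupled_pair is not None and rng.random() < model.coupling_prob:
            a, b = model.coupled_pair
            try_place(peak, pwms[a], occupied)
            try_place(peak, pwms[b], occupied)
    return {c: "".join(s) for c, s in seqs.items()}, placements


def make_chain(
    chromosomes: Mapping[str, int],
    model: ChainModel,
    rng: np.random.Generator,
    target_prefix: str = "hchr",
) -> tuple[list[Chain], dict[str, ChainOracle], dict[str, int]]:
    """One collinear chain per chromosome with random indels.

    Deletions appear as source gaps (dt > 0), insertions as target gaps
    (dq > 0).  Returns chains, per-source-chromosome base-map oracles, and
    the target chromosome sizes.
    """
    chains: list[Chain] = []
    oracles: dict[str, ChainOracle] = {}
    target_sizes: dict[str, int] = {}
    for ci, (chrom, length) in enumerate(chromosomes.items()):
        tname = f"{target_prefix}{ci + 1}"
        n_ind = model.n_indels
        cuts = np.sort(rng.choice(np.arange(500, length - 500), size=n_ind,
                                  replace=False))
        blocks: list[ChainBlock] = []
        segments: list[tuple[int, int, int]] = []
        s_pos, t_pos = 0, 0
        prev = 0
        for cut in cuts:
            size = int(cut - prev)
            if size <= 0:
                continue
            ind_len = int(
                rng.integers(model.indel_length_range[0],
                             model.indel_length_range[1] + 1)
            )
            if rng.random() < model.insertion_prob:
                dt, dq = 0, ind_len  # insertion in target
            else:
                dt, dq = ind_len, 0  # deletion from target (source gap)
            blocks.append(ChainBlock(size, dt, dq))
            segments.append((s_pos, size, t_pos))
            s_pos += size + dt
            t_pos += size + dq
            prev = s_pos  # next block starts after the source gap
        tail = length - s_pos
        blocks.append(ChainBlock(tail))
        segments.append((s_pos, tail, t_pos))
        t_end = t_pos + tail
        chain = Chain(
            score=1000.0 * (ci + 1),
            source_name=chrom,
            source_size=length,
            source_strand="+",
            source_start=0,
            source_end=length,
            target_name=tname,
            target_size=t_end,
            target_strand="+",
            target_start=0,
            target_end=t_end,
            blocks=blocks,
            chain_id=str(ci + 1),
        )
        chain.validate()
        chains.append(chain)
        oracles[chrom] = ChainOracle(segments, t_end)
        target_sizes[tname] = t_end
    return chains, oracles, target_sizes


# ---------------------------------------------------------------------------
# top-level generator


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Produce the full synthetic study bundle with ground truth."""
    config = config if config is not None else SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    gm = config.genome
    chromosomes = dict(gm.chromosomes)
    layout = GenomeLayout(chromosomes)
    sequences = make_genome(gm, rng)

    # --- truth peaks and group assignment
    pk = config.peaks
    raw_peaks = _place_disjoint(
        rng, chromosomes, pk.n_peaks, pk.width_range, pk.min_spacing_bp
    )
    peaks = IntervalCollection(
        [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=f"peak_{i + 1}")
            for i, iv in enumerate(raw_peaks)
        ],
        disjoint=True,
    )
    n_specific = int(round(pk.specific_fraction * len(peaks)))
    specific_idx = set(
        rng.choice(len(peaks), size=n_specific, replace=False).tolist()
    )
    peak_groups = {
        iv.name: (["high"] if i in specific_idx else list(config.groups))
        for i, iv in enumerate(peaks)
    }
    specific_names = [peaks[i].name for i in sorted(specific_idx)]

    # --- genes, TSS, features
    gene_sites = _place_disjoint(
        rng, chromosomes, config.n_genes, (1, 2), 50, avoid=()
    )
    tss = [
        TssRecord(
            f"gene_{i + 1}",
            iv.chrom,
            iv.start,
            "+" if rng.random() < 0.5 else "-",
        )
        for i, iv in enumerate(gene_sites)
    ]
    feature_classes = _make_feature_catalog(rng, chromosomes, tss)
    cpg = IntervalCollection(
        _place_disjoint(rng, chromosomes, 30, (200, 600), 100)
    )
    blacklist = IntervalCollection(
        _place_disjoint(
            rng, chromosomes, 5, (500, 1500), 100, avoid=list(peaks)
        )
    )

    # --- replicate peak calls; noise peaks accumulate into a shared avoid
    # list so they stay private to one replicate (irreproducible by design)
    peak_calls: list[PeakCallSet] = []
    replicate_retained: dict[str, list[str]] = {}
    noise_avoid: list[GenomicInterval] = list(peaks) + list(blacklist)
    for group in config.groups:
        for stage in config.stages:
            for rep in range(1, config.replicates + 1):
                sid = f"{group}_{stage}_{rep}"
                meta = SampleMeta(sid, group, stage, rep)
                called = []
                retained = []
                for iv in peaks:
                    if group not in peak_groups[iv.name]:
                        continue
                    if rng.random() < pk.dropout_prob:
                        continue
                    if pk.jitter_sd_bp > 0:
                        j1 = int(round(rng.normal(0, pk.jitter_sd_bp)))
                        j2 = int(round(rng.normal(0, pk.jitter_sd_bp)))
                    else:
                        j1 = j2 = 0
                    start = max(0, iv.start + j1)
                    end = min(chromosomes[iv.chrom], iv.end + j2)
                    if end - start < 50:
                        start, end = iv.start, iv.end
                    called.append(
                        GenomicInterval(iv.chrom, start, end, name=iv.name)
                    )
                    retained.append(iv.name)
                noise = _place_disjoint(
                    rng,
                    chromosomes,
                    pk.noise_peaks_per_replicate,
                    (150, 300),
                    150,
                    avoid=noise_avoid,
                )
                noise_avoid.extend(noise)
                for k, iv in enumerate(noise):
                    called.append(
                        GenomicInterval(
                            iv.chrom, iv.start, iv.end, name=f"{sid}_noise{k}"
                        )
                    )
                called.sort(key=GenomicInterval.key)
                peak_calls.append(PeakCallSet(meta, IntervalCollection(called)))
                replicate_retained[sid] = retained

    # --- planted DA effects and fragments for the compared stage
    cm = config.counts
    da_log2fc: dict[str, float] = {iv.name: 0.0 for iv in peaks}
    shared = [iv.name for iv in peaks if set(peak_groups[iv.name]) == set(config.groups)]
    n_da = int(round(cm.da_fraction * len(shared)))
    da_names = rng.choice(shared, size=n_da, replace=False).tolist()
    for i, name in enumerate(da_names):
        fc = cm.da_log2fc if i % 2 == 0 else -cm.da_log2fc
        da_log2fc[name] = float(fc)

    fragment_sets = _make_fragments(
        config, rng, peaks, peak_groups, da_log2fc, chromosomes
    )

    # --- motifs: planted into the high-specific peaks so the shared peaks
    # provide a motif-free background for enrichment statistics
    mm = config.motifs
    pwms = make_motif_library(mm, rng)
    motif_target = IntervalCollection(
        [iv for iv in peaks if peak_groups[iv.name] == ["high"]], disjoint=True
    )
    sequences, placements = plant_motifs(sequences, motif_target, pwms, mm, rng)

    # --- chain and variants
    chains, oracles, target_sizes = make_chain(chromosomes, config.chain, rng)
    variants, v_in_peak, v_in_motif = _make_variants(
        config, rng, peaks, placements, oracles, target_sizes,
        {c.source_name: c.target_name for c in chains}, pwms
    )

    # --- gene sets
    gene_sets, loaded_name = _make_gene_sets(config, rng, tss, peaks, da_log2fc)

    truth = SyntheticTruth(
        peaks=peaks,
        peak_groups=peak_groups,
        specific_peaks=specific_names,
        replicate_retained=replicate_retained,
        da_log2fc=da_log2fc,
        motif_placements=placements,
        chain_oracle=oracles,
        variant_in_peak=v_in_peak,
        variant_in_motif=v_in_motif,
        loaded_gene_set=loaded_name,
    )
    return SyntheticDataset(
        config=config,
        genome=layout,
        sequences=sequences,
        tss=tss,
        feature_classes=feature_classes,
        cpg_islands=cpg,
        blacklist=blacklist,
        peak_calls=peak_calls,
        fragment_sets=fragment_sets,
        pwms=pwms,
        chains=chains,
        target_sizes=target_sizes,
        variants=variants,
        gene_sets=gene_sets,
        truth=truth,
    )


def _make_feature_catalog(
    rng: np.random.Generator,
    chromosomes: Mapping[str, int],
    tss: Sequence[TssRecord],
) -> dict[str, IntervalCollection]:
    """Simple gene-part catalogs downstream of each TSS (promoter is
    derived from the TSS table by the annotation catalog itself)."""
    utr5, exon, intron, utr3, tts = [], [], [], [], []
    for rec in tss:
        sign = 1 if rec.strand != "-" else -1
        length = chromosomes[rec.chrom]

        def seg(a: int, b: int) -> tuple[int, int] | None:
            lo, hi = sorted((rec.position + sign * a, rec.position + sign * b))
            lo, hi = max(0, lo), min(length, hi)
            return (lo, hi) if lo < hi else None

        for coll, (a, b) in (
            (utr5, (0, 120)),
            (exon, (120, 400)),
            (intron, (400, 1400)),
            (utr3, (1400, 1600)),
            (tts, (1600, 1700)),
        ):
            s = seg(a, b)
            if s:
                coll.append(GenomicInterval(rec.chrom, s[0], s[1], name=rec.gene))
    return {
        "5utr": IntervalCollection(utr5).sorted(),
        "exon": IntervalCollection(exon).sorted(),
        "intron": IntervalCollection(intron).sorted(),
        "3utr": IntervalCollection(utr3).sorted(),
        "tts": IntervalCollection(tts).sorted(),
    }


def _make_fragments(
    config: SyntheticConfig,
    rng: np.random.Generator,
    peaks: IntervalCollection,
    peak_groups: Mapping[str, Sequence[str]],
    da_log2fc: Mapping[str, float],
    chromosomes: Mapping[str, int],
) -> list[FragmentSet]:
    """NB per-region fragment totals with planted effects, plus uniform
    genome-wide background fragments."""
    cm = config.counts
    base_rate = 2.0 ** rng.normal(
        np.log2(cm.mean_count), cm.mean_log_sd, size=len(peaks)
    )
    fragment_sets = []
    bias_names = []
    if cm.composition_bias_fraction > 0:
        k = int(round(cm.composition_bias_fraction * len(peaks)))
        bias_names = rng.choice(
            [iv.name for iv in peaks], size=k, replace=False
        ).tolist()
    bias_set = set(bias_names)
    for group in config.groups:
        for rep in range(1, config.replicates + 1):
            sid = f"{group}_{config.compared_stage}_{rep}"
            meta = SampleMeta(sid, group, config.compared_stage, rep)
            depth = float(np.exp(rng.normal(0.0, cm.library_size_spread)))
            frags: list[GenomicInterval] = []
            for i, iv in enumerate(peaks):
                if group not in peak_groups[iv.name]:
                    continue
                mu = base_rate[i] * depth
                fc = da_log2fc.get(iv.name, 0.0)
                if fc != 0.0:
                    # planted effect realized on the high population side
                    mu *= 2.0 ** (fc if group == "high" else 0.0)
                if iv.name in bias_set and sid in cm.composition_bias_samples:
                    mu *= cm.composition_bias_factor
                total = _nb_draw(rng, mu, cm.dispersion)
                frags.extend(
                    _uniform_fragments(rng, iv, total, cm, chromosomes)
                )
            n_bg = int(
                round(
                    cm.background_fraction
                    / max(1e-9, 1 - cm.background_fraction)
                    * len(frags)
                )
            )
            chrom_names = list(chromosomes)
            lens = np.array([chromosomes[c] for c in chrom_names], dtype=float)
            probs = lens / lens.sum()
            for _ in range(n_bg):
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=probs))]
                flen = _frag_len(rng, cm)
                start = int(rng.integers(0, max(1, chromosomes[chrom] - flen)))
                frags.append(GenomicInterval(chrom, start, start + flen))
            frags.sort(key=GenomicInterval.key)
            fragment_sets.append(FragmentSet(meta, IntervalCollection(frags)))
    return fragment_sets


def _nb_draw(rng: np.random.Generator, mu: float, phi: float) -> int:
    if phi <= 0:
        return int(rng.poisson(mu))
    r = 1.0 / phi
    p = r / (r + mu)
    return int(rng.negative_binomial(r, p))


def _frag_len(rng: np.random.Generator, cm: CountModel) -> int:
    return int(
        np.clip(rng.normal(cm.fragment_length_mean, cm.fragment_length_sd), 50, 1000)
    )


def _uniform_fragments(
    rng: np.random.Generator,
    region: GenomicInterval,
    total: int,
    cm: CountModel,
    chromosomes: Mapping[str, int],
) -> list[GenomicInterval]:
    out = []
    for _ in range(total):
        flen = _frag_len(rng, cm)
        center = int(rng.integers(region.start, region.end))
        start = max(0, center - flen // 2)
        end = min(chromosomes[region.chrom], start + flen)
        if end > start:
            out.append(GenomicInterval(region.chrom, start, end))
    return out


def _make_variants(
    config: SyntheticConfig,
    rng: np.random.Generator,
    peaks: IntervalCollection,
    placements: Sequence[dict],
    oracles: Mapping[str, ChainOracle],
    target_sizes: Mapping[str, int],
    target_name_of: Mapping[str, str],
    pwms: Sequence[PositionWeightMatrix],
) -> tuple[list[VariantRecord], list[str], dict[str, str]]:
    vm = config.variants
    pwm_len = {p.name: len(p) for p in pwms}
    classes = list(vm.class_frequencies)
    class_p = np.array(list(vm.class_frequencies.values()))
    class_p = class_p / class_p.sum()
    features = list(vm.feature_frequencies)
    feature_p = np.array(list(vm.feature_frequencies.values()))
    feature_p = feature_p / feature_p.sum()

    variants: list[VariantRecord] = []
    in_peak: list[str] = []
    in_motif: dict[str, str] = {}
    n_motif = int(round(vm.in_motif_fraction * vm.n_variants))
    n_in_peak = int(round(vm.in_peak_fraction * vm.n_variants))
    peak_by_name = {iv.name: iv for iv in peaks}

    def labels() -> tuple[str, str]:
        return (
            classes[int(rng.choice(len(classes), p=class_p))],
            features[int(rng.choice(len(features), p=feature_p))],
        )

    # restrict planting to peaks that lift at the default threshold, so the
    # planted variant-overlap truth is recoverable downstream
    mappable = {
        iv.name
        for iv in peaks
        if oracles[iv.chrom].expected_status(iv, 0.7) == "mapped"
    }

    vid = 0
    # variants inside planted motif occurrences (also inside peaks)
    usable = [
        pl
        for pl in placements
        if pl["peak"] in peak_by_name and pl["peak"] in mappable
    ]
    rng.shuffle(usable)
    for pl in usable:
        if len(in_motif) >= n_motif:
            break
        peak = peak_by_name[pl["peak"]]
        src_positions = range(pl["start"], pl["start"] + pwm_len[pl["motif"]])
        oracle = oracles[peak.chrom]
        liftable_pos = [p for p in src_positions if oracle.map_base(p) is not None]
        if not liftable_pos:
            continue
        src = liftable_pos[int(rng.integers(len(liftable_pos)))]
        tgt = oracle.map_base(src)
        vid += 1
        cls, feat = labels()
        v = VariantRecord(
            f"var_{vid}", target_name_of[peak.chrom], tgt + 1, peak.name, cls, feat
        )
        variants.append(v)
        in_peak.append(v.variant_id)
        in_motif[v.variant_id] = pl["motif"]
    # variants inside mapped peaks (outside motifs not enforced)
    peak_list = [iv for iv in peaks if iv.name in mappable]
    while len(in_peak) < n_in_peak and peak_list:
        peak = peak_list[int(rng.integers(len(peak_list)))]
        oracle = oracles[peak.chrom]
        src = int(rng.integers(peak.start, peak.end))
        tgt = oracle.map_base(src)
        if tgt is None:
            continue
        vid += 1
        cls, feat = labels()
        v = VariantRecord(
            f"var_{vid}", target_name_of[peak.chrom], tgt + 1, peak.name, cls, feat
        )
        variants.append(v)
        in_peak.append(v.variant_id)
    # background variants away from peaks
    peak_spans = {c: [] for c in oracles}
    for iv in peaks:
        peak_spans[iv.chrom].append((iv.start, iv.end))
    chrom_names = list(oracles)
    while len(variants) < vm.n_variants:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        oracle = oracles[chrom]
        src = int(rng.integers(0, config.genome.chromosomes[chrom]))
        pad = 300  # stay clear of peaks so truth overlap is unambiguous
        if any(s - pad < src < e + pad for s, e in peak_spans[chrom]):
            continue
        tgt = oracle.map_base(src)
        if tgt is None:
            continue
        vid += 1
        cls, feat = labels()
        variants.append(
            VariantRecord(
                f"var_{vid}", target_name_of[chrom], tgt + 1, "", cls, feat
            )
        )
    rng.shuffle(variants)
    return variants, in_peak, in_motif


def _make_gene_sets(
    config: SyntheticConfig,
    rng: np.random.Generator,
    tss: Sequence[TssRecord],
    peaks: IntervalCollection,
    da_log2fc: Mapping[str, float],
) -> tuple[dict[str, list[str]], str]:
    """Random gene sets plus one set loaded on genes nearest the planted
    positively-changed peaks."""
    genes = [t.gene for t in tss]
    sets: dict[str, list[str]] = {}
    lo, hi = config.gene_set_size_range
    for k in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sets[f"random_set_{k + 1}"] = sorted(members.tolist())
    # loaded set: genes whose TSS is nearest an increased peak
    catalog = AnnotationCatalog(list(tss))
    up_peaks = IntervalCollection(
        [iv for iv in peaks if da_log2fc.get(iv.name, 0.0) > 0]
    )
    loaded_name = "loaded_set"
    if len(up_peaks):
        anns = assign_nearest_tss(up_peaks, catalog)
        loaded = sorted({a.gene for a in anns if a.assigned})
        if len(loaded) >= 2:
            sets[loaded_name] = loaded
    return sets, loaded_name


# ---------------------------------------------------------------------------
# serialization


def write_bundle(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the bundle as plain-text standard formats plus truth.json."""
    from .gsea import write_gmt
    from .intervals import write_intervals
    from .liftover import write_chain
    from .motifs import write_homer_motifs

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in dataset.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(out / "tss.tsv", "w") as fh:
        for rec in dataset.tss:
            fh.write(f"{rec.gene}\t{rec.chrom}\t{rec.position}\t{rec.strand}\n")
    (out / "features").mkdir(exist_ok=True)
    for name, coll in dataset.feature_classes.items():
        with open(out / "features" / f"{name}.bed", "w") as fh:
            write_intervals(coll, fh, dialect="bed6")
    with open(out / "cpg_islands.bed", "w") as fh:
        write_intervals(dataset.cpg_islands, fh)
    with open(out / "blacklist.bed", "w") as fh:
        write_intervals(dataset.blacklist, fh)
    (out / "peaks").mkdir(exist_ok=True)
    for pcs in dataset.peak_calls:
        with open(out / "peaks" / f"{pcs.meta.sample_id}.bed", "w") as fh:
            write_intervals(pcs.peaks, fh, dialect="bed6")
    (out / "fragments").mkdir(exist_ok=True)
    for fs in dataset.fragment_sets:
        with open(out / "fragments" / f"{fs.meta.sample_id}.bed", "w") as fh:
            write_intervals(fs.fragments, fh)
    with open(out / "motifs.txt", "w") as fh:
        write_homer_motifs(dataset.pwms, fh)
    with open(out / "alignment.chain", "w") as fh:
        write_chain(dataset.chains, fh)
    with open(out / "variants.tsv", "w") as fh:
        fh.write("id\tchrom\tposition\tgene\tpathogenicity\tfeature\n")
        for v in dataset.variants:
            fh.write(
                f"{v.variant_id}\t{v.chrom}\t{v.position}\t{v.gene}\t"
                f"{v.pathogenicity}\t{v.feature}\n"
            )
    with open(out / "gene_sets.gmt", "w") as fh:
        write_gmt(dataset.gene_sets, fh)
    truth = dataset.truth
    payload = {
        "summary": truth.summary(),
        "peak_groups": truth.peak_groups,
        "specific_peaks": truth.specific_peaks,
        "replicate_retained": truth.replicate_retained,
        "da_log2fc": truth.da_log2fc,
        "motif_placements": truth.motif_placements,
        "variant_in_peak": truth.variant_in_peak,
        "variant_in_motif": truth.variant_in_motif,
        "loaded_gene_set": truth.loaded_gene_set,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
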