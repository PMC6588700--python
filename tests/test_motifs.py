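"""PWM scanning, enrichment, centrality, similarity, co-occurrence."""

import io
import math

import numpy as np
import pytest
from scipy import special

from atackit.intervals import GenomicInterval, IntervalCollection
from atackit.motifs import (
    PositionWeightMatrix,
    SequenceWindow,
    cooccurrence,
    extract_windows,
    motif_enrichment,
    motif_similarity,
    positional_profile,
    read_count_matrix_motifs,
    read_homer_motifs,
    reverse_complement,
    scan,
    scan_library,
    write_homer_motifs,
)


def _pwm_from_consensus(name, consensus, info=1.0, threshold=None):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(consensus), 4), (1 - info) / 3 if info < 1 else 0.0)
    for i, b in enumerate(consensus):
        mat[i, idx[b]] = info
    return PositionWeightMatrix(name, mat, threshold=threshold)


def _window(seq, peak_id="p1"):
    hw = len(seq) // 2
    return SequenceWindow(peak_id, "chr1", 0, seq, hw, hw)


class TestPwmModel:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PositionWeightMatrix("bad", np.full((4, 4), 0.3))

    def test_default_threshold_is_80pct_of_max(self):
        pwm = _pwm_from_consensus("m", "ACGT")
        assert pwm.threshold == pytest.approx(0.8 * pwm.max_score())

    def test_threshold_cannot_exceed_max(self):
        with pytest.raises(ValueError, match="threshold"):
            _pwm_from_consensus("m", "ACGT", threshold=100.0)

    def test_homer_round_trip(self):
        pwm = _pwm_from_consensus("m1", "ACGTAC", info=0.9)
        buf = io.StringIO()
        write_homer_motifs([pwm], buf)
        buf.seek(0)
        again = read_homer_motifs(buf)[0]
        assert again.name == "m1"
        assert np.allclose(again.probabilities, pwm.probabilities, atol=1e-6)
        assert again.threshold == pytest.approx(pwm.threshold, abs=1e-4)

    def test_count_matrix_reader_normalizes(self):
        text = ">m1\nA [10 0]\nC [0 10]\nG [0 0]\nT [0 0]\n"
        pwm = read_count_matrix_motifs(io.StringIO(text), pseudo_count=0.5)[0]
        assert pwm.probabilities.shape == (2, 4)
        assert pwm.probabilities[0, 0] == pytest.approx(10.5 / 12.0)
        assert np.allclose(pwm.probabilities.sum(axis=1), 1.0)


class TestExtractWindows:
    def test_centered_window_coordinates(self):
        seqs = {"chr1": "A" * 1000}
        peaks = IntervalCollection([GenomicInterval("chr1", 100, 200, name="p")])
        w = extract_windows(peaks, seqs, half_width=100)[0]
        assert (w.start, len(w.sequence), w.center_index) == (50, 200, 100)
        assert not w.truncated

    def test_edge_truncation_flagged(self):
        seqs = {"chr1": "A" * 300}
        peaks = IntervalCollection([GenomicInterval("chr1", 0, 40)])
        w = extract_windows(peaks, seqs, half_width=100)[0]
        assert w.truncated
        assert w.start == 0
        assert w.center_index == 20

    def test_matches_substring_oracle_and_masking(self):
        seq = "ACGTacgtNNACGTACGT" * 30
        seqs = {"chr1": seq}
        peaks = IntervalCollection([GenomicInterval("chr1", 200, 260)])
        w = extract_windows(peaks, seqs, half_width=30)[0]
        center = (200 + 260) // 2
        expected = seq[center - 30 : center + 30]
        expected = "".join("N" if c.islower() else c for c in expected).upper()
        assert w.sequence == expected

    def test_missing_chromosome_listed(self):
        peaks = IntervalCollection([GenomicInterval("chrX", 0, 10)])
        with pytest.raises(ValueError, match="chrX"):
            extract_windows(peaks, {"chr1": "ACGT"}, 5)


class TestScan:
    def test_probability_one_columns_score_closed_form(self):
        pwm = _pwm_from_consensus("m", "ACGT", threshold=7.9)
        hits = scan(pwm, [_window("TTTTACGTTTTT")])
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].score == pytest.approx(4 * math.log2(4))

    def test_reverse_complement_found_on_minus_strand(self):
        pwm = _pwm_from_consensus("m", "AACGT", threshold=9.0)
        seq = "TTTT" + reverse_complement("AACGT") + "TTTT"
        hits = scan(pwm, [_window(seq)])
        assert len(hits) == 1
        assert hits[0].strand == "-"

    def test_n_bases_never_match(self):
        pwm = _pwm_from_consensus("m", "ACGT", threshold=7.9)
        hits = scan(pwm, [_window("TTTTACNTTTTT")])
        assert hits == []

    def test_offsets_relative_to_center(self):
        pwm = _pwm_from_consensus("m", "ACGT", threshold=7.9)
        seq = "T" * 10 + "ACGT" + "T" * 10
        w = _window(seq)  # center index 12
        hits = scan(pwm, [w])
        assert [h.offset for h in hits if h.strand == "+"] == [10 - 12]

    def test_matches_bruteforce_sliding_oracle(self, rng):
        pwm = _pwm_from_consensus("m", "ACGTA", info=0.9)
        lo = pwm.log_odds()
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for _ in range(5):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
            w = _window(seq)
            got = {(h.offset, h.strand) for h in scan(pwm, [w])}
            expected = set()
            for strand, mat in (("+", lo), ("-", pwm.reverse_complement().log_odds())):
                for pos in range(len(seq) - len(pwm) + 1):
                    score = sum(
                        mat[c, idx[seq[pos + c]]] for c in range(len(pwm))
                    )
                    if score >= pwm.threshold - 1e-9:
                        expected.add((pos - w.center_index, strand))
            assert got == expected

    def test_strand_symmetry(self, rng):
        """Reverse-complementing every window maps + hits to - hits with
        identical scores."""
        pwm = _pwm_from_consensus("m", "ACGTAC", info=0.9)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        fwd = scan(pwm, [_window(seq)])
        rev = scan(pwm, [_window(reverse_complement(seq))])
        fwd_scores = sorted(round(h.score, 9) for h in fwd)
        rev_scores = sorted(round(h.score, 9) for h in rev)
        assert fwd_scores == rev_scores
        assert sorted(h.strand == "+" for h in fwd) == sorted(
            h.strand == "-" for h in rev
        )


class TestEnrichment:
    def _windows_with_motif(self, n, with_motif, consensus="ACGTACGTAA", seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=100))
            if i < with_motif:
                mid = 45
                seq = seq[:mid] + consensus + seq[mid + len(consensus):]
            out.append(_window(seq, peak_id=f"p{i}"))
        return out

    def test_all_target_none_background_closed_form(self):
        pwm = _pwm_from_consensus("m", "ACGTACGTAA")
        target = self._windows_with_motif(50, 50, seed=1)
        background = self._windows_with_motif(50, 0, seed=2)
        rec = motif_enrichment(target, background, [pwm], gc_match=False)[0]
        assert rec.target_hits == 50
        assert rec.background_hits == 0
        expected_p = 1.0 / special.comb(100, 50)
        assert rec.pvalue == pytest.approx(expected_p, rel=1e-6)

    def test_identical_rates_not_significant(self):
        pwm = _pwm_from_consensus("m", "ACGTACGTAA")
        target = self._windows_with_motif(40, 20, seed=3)
        background = self._windows_with_motif(40, 20, seed=4)
        rec = motif_enrichment(target, background, [pwm], gc_match=False)[0]
        assert rec.pvalue > 0.4

    def test_planted_motif_ranks_first_in_library(self):
        """60% target vs ~5% background planting puts the planted motif
        first by -log10 p among 20 motifs, across 10 seeds."""
        from atackit.simulate import MotifModel, make_motif_library

        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            pwms = make_motif_library(MotifModel(), rng)
            planted = pwms[0]
            consensus = planted.consensus()
            target = []
            background = []
            for i in range(50):
                seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=120))
                if rng.random() < 0.6:
                    seq = seq[:50] + consensus + seq[50 + len(consensus):]
                target.append(_window(seq, peak_id=f"t{i}"))
            for i in range(80):
                seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=120))
                if rng.random() < 0.05:
                    seq = seq[:50] + consensus + seq[50 + len(consensus):]
                background.append(_window(seq, peak_id=f"b{i}"))
            records = motif_enrichment(
                target, background, pwms, rng=np.random.default_rng(seed)
            )
            assert records[0].motif == planted.name

    def test_null_pvalues_roughly_uniform(self):
        """Target and background drawn from one pool: p < 0.05 in roughly
        5% of motif x seed combinations."""
        from atackit.simulate import MotifModel, make_motif_library

        n_sig = 0
        n_tot = 0
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            pwms = make_motif_library(
                MotifModel(n_motifs=10, length_range=(7, 9)), rng
            )
            pool = []
            for i in range(80):
                seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=100))
                pool.append(_window(seq, peak_id=f"w{i}"))
            records = motif_enrichment(
                pool[:40], pool[40:], pwms, gc_match=False
            )
            n_sig += sum(r.pvalue < 0.05 for r in records)
            n_tot += len(records)
        assert 0.0 <= n_sig / n_tot <= 0.09

    def test_empty_inputs_rejected(self):
        pwm = _pwm_from_consensus("m", "ACGT")
        w = [_window("ACGTACGT")]
        with pytest.raises(ValueError):
            motif_enrichment([], w, [pwm])
        with pytest.raises(ValueError):
            motif_enrichment(w, [], [pwm])


class TestPositionalProfile:
    def _hits(self, offsets, motif="m"):
        from atackit.motifs import MotifHit

        return [
            MotifHit(f"p{i}", motif, int(o), "+", 5.0) for i, o in enumerate(offsets)
        ]

    def test_all_center_hits_in_center_bin(self):
        prof = positional_profile(self._hits([0] * 10), half_width=100, bin_bp=10,
                                  n_peaks=10)
        nonzero = prof["m"][prof["m"] > 0]
        assert len(nonzero) == 1
        assert nonzero.index[0].left == 0

    def test_normalization_identity(self, rng):
        offsets = rng.integers(-95, 95, size=200)
        prof = positional_profile(self._hits(offsets), half_width=100, bin_bp=10,
                                  n_peaks=77)
        total = float((prof["m"] * 10 * 77).sum())
        assert total == pytest.approx(200)

    def test_gaussian_planting_peaks_at_center(self):
        for seed in range(10):
            local = np.random.default_rng(seed)
            offsets = np.clip(local.normal(0, 20, size=300), -99, 99).astype(int)
            prof = positional_profile(
                self._hits(offsets), half_width=100, bin_bp=20, n_peaks=300
            )
            peak_bin = prof["m"].idxmax()
            assert abs(peak_bin.left + 10) <= 30  # within one bin of center

    def test_uniform_planting_is_flat(self, rng):
        n = 4000
        offsets = rng.integers(-100, 100, size=n)
        prof = positional_profile(self._hits(offsets), half_width=100, bin_bp=20,
                                  n_peaks=n)
        counts = prof["m"].to_numpy() * 20 * n
        expect = n / len(counts)
        se = np.sqrt(expect)
        assert np.all(np.abs(counts - expect) < 3.5 * se)


class TestSimilarity:
    def test_identical_motifs_correlate_perfectly(self):
        a = _pwm_from_consensus("a", "ACGTAC", info=0.9)
        b = _pwm_from_consensus("b", "ACGTAC", info=0.9)
        sim = motif_similarity([a, b])
        assert sim.loc["a", "b"] == pytest.approx(1.0)

    def test_reverse_complement_orientation_found(self):
        a = _pwm_from_consensus("a", "AACGTC", info=0.9)
        b = PositionWeightMatrix("b", a.reverse_complement().probabilities)
        sim = motif_similarity([a, b])
        assert sim.loc["a", "b"] == pytest.approx(1.0)

    def test_short_motif_excluded_with_warning(self):
        a = _pwm_from_consensus("a", "ACGTA", info=0.9)
        b = _pwm_from_consensus("b", "ACGTC", info=0.9)
        short = _pwm_from_consensus("s", "ACG", info=0.9)
        with pytest.warns(UserWarning, match="shorter"):
            sim = motif_similarity([a, b, short])
        assert "s" not in sim.index

    def test_matches_exhaustive_offset_oracle(self, rng):
        def rand_pwm(name, L):
            mat = rng.dirichlet(np.ones(4), size=L)
            return PositionWeightMatrix(name, mat)

        a, b = rand_pwm("a", 7), rand_pwm("b", 9)
        sim = motif_similarity([a, b])
        best = -1.0
        for bb in (b.probabilities, b.reverse_complement().probabilities):
            for off in range(-(len(bb) - 4), len(a.probabilities) - 4 + 1):
                lo, hi = max(0, off), min(7, off + len(bb))
                if hi - lo < 4:
                    continue
                x = a.probabilities[lo:hi].ravel()
                y = bb[lo - off : hi - off].ravel()
                best = max(best, float(np.corrcoef(x, y)[0, 1]))
        assert sim.loc["a", "b"] == pytest.approx(best)


class TestCooccurrence:
    def _hits_for(self, spec):
        """spec: peak_id -> dict of motif -> hit count."""
        from atackit.motifs import MotifHit

        hits = []
        for pid, motifs in spec.items():
            for m, k in motifs.items():
                for j in range(k):
                    hits.append(MotifHit(pid, m, j, "+", 5.0))
        return hits

    def test_joint_over_independent_ratio_two(self):
        # both motifs in 50% of peaks, jointly; marginals 0.5 each
        peaks = [f"p{i}" for i in range(40)]
        spec = {p: {"a": 1, "b": 1} for p in peaks[:20]}
        hits = self._hits_for(spec)
        mat = cooccurrence(hits, peaks, ["a", "b"], expected_mode="independence")
        assert mat.observed[0, 1] == pytest.approx(0.5)
        assert mat.expected[0, 1] == pytest.approx(0.25)
        assert mat.ratio[0, 1] == pytest.approx(2.0, rel=0.01)

    def test_independent_planting_ratio_near_one(self):
        for seed in range(10):
            local = np.random.default_rng(seed)
            peaks = [f"p{i}" for i in range(400)]
            spec = {}
            for p in peaks:
                d = {}
                if local.random() < 0.5:
                    d["a"] = 1
                if local.random() < 0.5:
                    d["b"] = 1
                if d:
                    spec[p] = d
            mat = cooccurrence(
                self._hits_for(spec), peaks, ["a", "b"],
                expected_mode="independence",
            )
            assert 0.8 <= mat.ratio[0, 1] <= 1.25

    def test_diagonal_counts_multiple_occurrences(self):
        peaks = [f"p{i}" for i in range(10)]
        spec = {p: {"a": 2} for p in peaks[:5]}
        spec.update({p: {"a": 1} for p in peaks[5:]})
        hits = self._hits_for(spec)
        bg_peaks = [f"b{i}" for i in range(10)]
        bg_hits = self._hits_for({p: {"a": 1} for p in bg_peaks})
        mat = cooccurrence(
            hits, peaks, ["a"], expected_mode="background",
            background_hits=bg_hits, background_peak_ids=bg_peaks,
        )
        assert mat.observed[0, 0] == pytest.approx(0.5)  # >= 2 hits in half
        assert mat.expected[0, 0] == pytest.approx(0.0)

    def test_symmetry_and_peak_order_invariance(self, rng):
        peaks = [f"p{i}" for i in range(50)]
        spec = {}
        for p in peaks:
            d = {m: int(rng.integers(0, 3)) for m in ("a", "b", "c")}
            spec[p] = {m: k for m, k in d.items() if k}
        hits = self._hits_for(spec)
        mat1 = cooccurrence(hits, peaks, ["a", "b", "c"],
                            expected_mode="independence")
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        mat2 = cooccurrence(hits, shuffled, ["a", "b", "c"],
                            expected_mode="independence")
        assert np.allclose(mat1.ratio, mat1.ratio.T)
        assert np.allclose(mat1.observed, mat2.observed)

    def test_background_mode_requires_background(self):
        with pytest.raises(ValueError):
            cooccurrence([], ["p1"], ["a"], expected_mode="background")
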