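"""Counting, filtering, TMM, dispersion, exact NB test, gene scores."""

import numpy as np
import pytest
from scipy import stats

from atackit.diffacc import (
    CountMatrix,
    DispersionEstimate,
    FragmentSet,
    bh_adjust,
    consensus_regions,
    count_fragments,
    cumulative_gene_scores,
    estimate_common_dispersion,
    exact_nb_test,
    exact_test_pvalue,
    filter_low_counts,
    tmm_factors,
)
from atackit.intervals import GenomicInterval, IntervalCollection, merge_within, union
from atackit.peaks import PeakAnnotation, SampleMeta
from conftest import random_collection


def _matrix(counts, libs=None, groups=None):
    counts = np.asarray(counts)
    n_regions, n_samples = counts.shape
    if libs is None:
        libs = counts.sum(axis=0) * 2.0
    groups = groups or ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)
    regions = IntervalCollection(
        [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(n_regions)],
        disjoint=True,
    )
    metas = [SampleMeta(f"s{j}", groups[j], "st", j + 1) for j in range(n_samples)]
    return CountMatrix(
        [f"r{i}" for i in range(n_regions)], regions, metas, counts, np.asarray(libs, float)
    )


def _simulate_matrix(seed, n=2000, phi=0.1, planted=(), fc=2.0, n_per_group=3):
    rng = np.random.default_rng(seed)
    base = rng.lognormal(4.0, 0.7, size=n)
    libs = rng.uniform(0.8e6, 1.2e6, size=2 * n_per_group)
    mu = base[:, None] * (libs[None, :] / 1e6)
    for k, i in enumerate(planted):
        mu[i, :n_per_group] *= 2.0 ** (fc if k % 2 == 0 else -fc)
    gen = np.random.default_rng(seed + 10_000)
    if phi > 0:
        r = 1.0 / phi
        counts = gen.negative_binomial(r, r / (r + mu))
    else:
        counts = gen.poisson(mu)
    return _matrix(counts, libs)


class TestConsensusRegions:
    def test_single_set_is_merged_self(self, rng):
        coll = random_collection(rng, 40)
        got = consensus_regions([coll], 100)
        expected = merge_within(coll, 100)
        assert [iv.key() for iv in got] == [iv.key() for iv in expected]
        assert all(iv.name == f"{iv.chrom}:{iv.start}-{iv.end}" for iv in got)

    def test_small_gap_merges_across_sets(self):
        a = IntervalCollection([GenomicInterval("chr1", 0, 100)])
        b = IntervalCollection([GenomicInterval("chr1", 190, 300)])
        got = consensus_regions([a, b], 100)
        assert [iv.key() for iv in got] == [("chr1", 0, 300)]

    def test_matches_merge_oracle_on_union(self, rng):
        sets = [random_collection(rng, 30) for _ in range(3)]
        got = consensus_regions(sets, 100)
        expected = merge_within(union(sets), 100)
        assert [iv.key() for iv in got] == [iv.key() for iv in expected]


class TestCountFragments:
    def _fragset(self, fragments, sid="s1", group="A"):
        return FragmentSet(
            SampleMeta(sid, group, "st", 1), IntervalCollection(fragments)
        )

    def test_overlap_rule_and_length_cutoff(self):
        regions = IntervalCollection(
            [GenomicInterval("chr1", 150, 400)], disjoint=True
        )
        fs = self._fragset(
            [
                GenomicInterval("chr1", 100, 300),  # overlaps -> 1
                GenomicInterval("chr1", 0, 2500),  # length 2500 -> dropped
            ]
        )
        m = count_fragments(regions, [fs], max_fragment_length=2000)
        assert m.counts[0, 0] == 1
        assert m.library_sizes[0] == 1  # the long fragment leaves the library

    def test_fragment_spanning_two_regions_counts_twice(self):
        regions = IntervalCollection(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 150, 250)],
            disjoint=True,
        )
        fs = self._fragset([GenomicInterval("chr1", 90, 160)])
        m = count_fragments(regions, [fs])
        assert m.counts[:, 0].tolist() == [1, 1]

    def test_non_disjoint_regions_rejected(self):
        regions = IntervalCollection(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)]
        )
        with pytest.raises(ValueError, match="disjoint"):
            count_fragments(regions, [self._fragset([])])

    def test_matches_bruteforce_overlap_counting(self, rng):
        regions = merge_within(random_collection(rng, 40), 0)
        frags = random_collection(rng, 300)
        m = count_fragments(regions, [self._fragset(list(frags))])
        for i, region in enumerate(regions):
            expected = sum(
                1
                for f in frags
                if f.length <= 2000 and f.overlap_bp(region) >= 1
            )
            assert m.counts[i, 0] == expected


class TestCpmFilter:
    def test_all_zero_region_removed(self):
        m = _matrix([[0, 0, 0, 0], [10, 10, 10, 10]], libs=[1e6] * 4)
        kept = filter_low_counts(m)
        assert kept.region_ids == ["r1"]

    def test_n_minus_one_rule(self):
        # >= 1 CPM in exactly 3 of 4 samples -> kept
        m = _matrix([[2, 2, 2, 0], [2, 0, 0, 0]], libs=[2e6] * 4)
        kept = filter_low_counts(m, min_cpm=1.0)
        assert kept.region_ids == ["r0"]

    def test_cpm_boundary_inclusive(self):
        # count 2 at library 2e6 is exactly 1.0 CPM
        m = _matrix([[2, 2, 2, 2]], libs=[2e6] * 4)
        assert len(filter_low_counts(m, min_cpm=1.0).region_ids) == 1

    def test_min_samples_validation(self):
        m = _matrix([[1, 1, 1, 1]])
        with pytest.raises(ValueError):
            filter_low_counts(m, min_samples=5)


def _literal_tmm_reference(counts, libs, ref_idx, obs_idx,
                           trim_m=0.30, trim_a=0.05):
    """Direct transcription of the TMM definition, kept independent of the
    implementation's vectorized path."""
    o, r = counts[:, obs_idx].astype(float), counts[:, ref_idx].astype(float)
    lo, lr = libs[obs_idx], libs[ref_idx]
    mask = (o > 0) & (r > 0)
    o, r = o[mask], r[mask]
    m = np.log2((o / lo) / (r / lr))
    a = 0.5 * np.log2((o / lo) * (r / lr))
    w = (lo - o) / (lo * o) + (lr - r) / (lr * r)
    n = len(m)
    keep = np.ones(n, dtype=bool)
    lo_m = np.floor(n * trim_m) + 1
    lo_a = np.floor(n * trim_a) + 1
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep &= (rank_m >= lo_m) & (rank_m <= n + 1 - lo_m)
    keep &= (rank_a >= lo_a) & (rank_a <= n + 1 - lo_a)
    return 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


class TestTmm:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 4))
        m = _matrix(counts, libs=[1e5] * 4)
        f = tmm_factors(m)
        assert np.allclose(f.factors, 1.0)

    def test_pure_depth_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=500)
        counts = np.column_stack([base, 2 * base, base, 2 * base])
        m = _matrix(counts, libs=[1e5, 2e5, 1e5, 2e5])
        f = tmm_factors(m)
        assert np.allclose(f.factors, 1.0, atol=1e-6)

    def test_composition_bias_detected_within_5pct_of_reference(self):
        rng = np.random.default_rng(7)
        n = 2000
        base = rng.lognormal(5, 1, size=n)
        a = rng.poisson(base)
        b = rng.poisson(base)
        idx = rng.choice(n, n // 10, replace=False)
        b = b.copy()
        b[idx] = rng.poisson(base[idx] * 8)  # 10% of regions 8-fold inflated
        libs = np.array([a.sum() * 2.0, b.sum() * 2.0], dtype=float)
        m = _matrix(np.column_stack([a, b]), libs=libs, groups=["A", "B"])
        f = tmm_factors(m)
        assert f.factors[1] < f.factors[0]
        # compare the unscaled pair factor against the literal reference
        q75 = [np.quantile(m.counts[:, j] / libs[j], 0.75) for j in range(2)]
        ref_idx = int(np.argmin(np.abs(np.array(q75) - np.mean(q75))))
        obs_idx = 1 - ref_idx
        expected = _literal_tmm_reference(m.counts, libs, ref_idx, obs_idx)
        got_ratio = f.factors[obs_idx] / f.factors[ref_idx]
        assert got_ratio == pytest.approx(expected, rel=0.05)

    def test_geometric_mean_one(self, rng):
        counts = rng.poisson(50, size=(300, 5))
        m = _matrix(counts, libs=[1e5] * 5, groups=list("AABBB"))
        f = tmm_factors(m)
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        m = _matrix([[0, 5], [0, 5]], libs=[1e5, 1e5], groups=["A", "B"])
        with pytest.raises(ValueError):
            tmm_factors(m)


class TestDispersion:
    def test_poisson_counts_give_near_zero_phi(self):
        m = _simulate_matrix(seed=0, phi=0.0)
        f = tmm_factors(m)
        est = estimate_common_dispersion(m, f)
        assert est.common <= 0.02

    def test_nb_phi_point_two_recovered(self):
        estimates = []
        for seed in range(10):
            m = _simulate_matrix(seed=100 + seed, phi=0.2)
            f = tmm_factors(m)
            estimates.append(estimate_common_dispersion(m, f).common)
        assert all(0.15 <= e <= 0.25 for e in estimates)

    def test_single_sample_groups_rejected(self):
        m = _matrix([[5, 6]], libs=[1e5, 1e5], groups=["A", "B"])
        f = tmm_factors(m)
        with pytest.raises(ValueError, match="2 samples"):
            estimate_common_dispersion(m, f)


def _enumeration_oracle(sum_a, sum_b, n_a, n_b, phi):
    """Direct enumeration with plain pmf products (no log-space path)."""
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    mean = t / (n_a + n_b)

    def pmf(k, n):
        mu = n * mean
        if phi == 0:
            return stats.poisson.pmf(k, mu)
        r = n / phi
        return stats.nbinom.pmf(k, r, r / (r + mu))

    probs = [pmf(k, n_a) * pmf(t - k, n_b) for k in range(t + 1)]
    total = sum(probs)
    obs = probs[sum_a]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-12)) / total)


class TestExactTest:
    def test_symmetric_split_p_one(self):
        assert exact_test_pvalue(10, 10, 2, 2, 0.1) == pytest.approx(1.0)

    def test_poisson_case_matches_conditional_binomial(self):
        # at phi = 0 the conditional law of the A-sum is Binomial(t, nA/n)
        for sum_a, sum_b, n_a, n_b in [(3, 12, 2, 2), (9, 2, 3, 3), (5, 5, 1, 3)]:
            t = sum_a + sum_b
            p_binom = stats.binom.pmf(np.arange(t + 1), t, n_a / (n_a + n_b))
            obs = p_binom[sum_a]
            expected = p_binom[p_binom <= obs * (1 + 1e-12)].sum()
            got = exact_test_pvalue(sum_a, sum_b, n_a, n_b, 0.0)
            assert got == pytest.approx(float(expected), abs=1e-10)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_for_all_small_totals(self, phi):
        for t in range(0, 31):
            for sum_a in range(t + 1):
                got = exact_test_pvalue(sum_a, t - sum_a, 3, 3, phi)
                expected = _enumeration_oracle(sum_a, t - sum_a, 3, 3, phi)
                assert got == pytest.approx(expected, abs=1e-10)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            exact_test_pvalue(1, 2, 2, 2, -0.1)
        m = _simulate_matrix(seed=0, n=10)
        f = tmm_factors(m)
        with pytest.raises(ValueError):
            exact_nb_test(m, f, -1.0, "A", "B")

    def test_planted_effects_rank_above_null(self):
        rng = np.random.default_rng(3)
        planted = rng.choice(2000, 100, replace=False)
        m = _simulate_matrix(seed=3, planted=planted)
        f = tmm_factors(m)
        d = estimate_common_dispersion(m, f)
        res = exact_nb_test(m, f, d, "A", "B")
        is_planted = np.zeros(2000, dtype=bool)
        is_planted[planted] = True
        score = -np.log10(res.pvalues + 1e-300)
        order = np.argsort(-score)
        ranks = np.empty(2000)
        ranks[order] = np.arange(2000)
        # AUROC via rank statistic
        auroc = 1 - (ranks[is_planted].mean() - (100 - 1) / 2) / (2000 - 100)
        assert auroc > 0.95

    def test_status_labels_follow_fdr_and_sign(self):
        planted = list(range(100))
        m = _simulate_matrix(seed=11, planted=planted)
        f = tmm_factors(m)
        d = estimate_common_dispersion(m, f)
        res = exact_nb_test(m, f, d, "A", "B", fdr_threshold=0.05)
        for i in range(2000):
            if res.fdr[i] >= 0.05:
                assert res.status[i] == "unchanged"
            elif res.log2_fold_change[i] > 0:
                assert res.status[i] == "increased"
            else:
                assert res.status[i] == "decreased"


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_matches_reference_step_up(self, rng):
        p = rng.uniform(0, 1, size=200)
        got = bh_adjust(p)
        # reference step-up implementation
        order = np.argsort(p)
        m = len(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(got, expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestGeneScores:
    def _result(self, log2fcs):
        n = len(log2fcs)
        regions = IntervalCollection(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(n)],
            disjoint=True,
        )
        from atackit.diffacc import DifferentialResult

        return DifferentialResult(
            region_ids=[f"r{i}" for i in range(n)],
            regions=regions,
            log2_fold_change=np.asarray(log2fcs, float),
            mean_normalized=np.zeros(n),
            pvalues=np.ones(n),
            fdr=np.ones(n),
            status=["unchanged"] * n,
        )

    def _annotations(self, genes):
        return [
            PeakAnnotation(GenomicInterval("chr1", i * 1000, i * 1000 + 100),
                           g, 0 if g else None, "x")
            for i, g in enumerate(genes)
        ]

    def test_stated_sum(self):
        res = self._result([1.0, 2.0, -0.5])
        frame = cumulative_gene_scores(res, self._annotations(["g1", "g1", "g1"]))
        assert frame.loc["g1", "score"] == pytest.approx(2.5)
        assert frame.loc["g1", "n_regions"] == 3

    def test_gene_without_regions_absent(self):
        res = self._result([1.0])
        frame = cumulative_gene_scores(res, self._annotations(["g1"]))
        assert "g2" not in frame.index

    def test_unassigned_regions_excluded(self):
        res = self._result([1.0, 5.0])
        frame = cumulative_gene_scores(res, self._annotations(["g1", None]))
        assert frame["score"].sum() == pytest.approx(1.0)

    def test_matches_groupby_oracle_and_order_invariance(self, rng):
        n = 200
        genes = [f"g{int(k)}" for k in rng.integers(0, 40, size=n)]
        fcs = rng.normal(0, 2, size=n)
        res = self._result(fcs)
        frame = cumulative_gene_scores(res, self._annotations(genes))
        expected: dict[str, float] = {}
        for g, fc in zip(genes, fcs):
            expected[g] = expected.get(g, 0.0) + fc
        for g, total in expected.items():
            assert frame.loc[g, "score"] == pytest.approx(total)
        # permutation invariance
        perm = rng.permutation(n)
        res2 = self._result(fcs[perm])
        frame2 = cumulative_gene_scores(
            res2, self._annotations([genes[i] for i in perm])
        )
        assert np.allclose(
            frame.sort_index()["score"], frame2.sort_index()["score"]
        )
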