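"""Coverage correlation and interval statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from nucfoot.genomic_stats import (CoverageTrack, bin_midpoints,
                                   categorize_overlap, circular_shift,
                                   compare_conservation, correlation_matrix,
                                   enrichment_empirical, enrichment_fisher,
                                   jaccard_matrix, make_promoters,
                                   make_tad_boundaries,
                                   sliding_regional_correlation)
from nucfoot.intervals import GenomicInterval
from nucfoot.io import MidpointSet, Track


def iv(s, e, chrom="chr1", **kw):
    return GenomicInterval(chrom, s, e, **kw)


def _mps(positions, chrom="chr1"):
    pos = np.asarray(positions, dtype=np.int64)
    return MidpointSet({chrom: pos}, {chrom: np.ones(len(pos), bool)})


class TestBinning:
    def test_bin_edges(self):
        t = bin_midpoints(_mps([0, 499, 500]), 500, {"chr1": 1000})
        assert t.counts["chr1"].tolist() == [2, 1]

    def test_empty_set_all_zero(self):
        t = bin_midpoints(MidpointSet(), 500, {"chr1": 2000})
        assert t.counts["chr1"].tolist() == [0, 0, 0, 0]

    def test_refinement_consistency_50_to_500(self, rng):
        pos = np.sort(rng.integers(0, 10_000, 400))
        fine = bin_midpoints(_mps(pos), 50, {"chr1": 10_000})
        coarse = bin_midpoints(_mps(pos), 500, {"chr1": 10_000})
        resummed = fine.counts["chr1"].reshape(-1, 10).sum(axis=1)
        np.testing.assert_array_equal(resummed, coarse.counts["chr1"])

    def test_out_of_bounds_midpoint_is_an_error(self):
        with pytest.raises(ValueError, match="bounds"):
            bin_midpoints(_mps([1500]), 500, {"chr1": 1000})


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, rng):
        c = rng.poisson(5.0, 1000)
        t1 = CoverageTrack({"chr1": c}, 500, "a")
        t2 = CoverageTrack({"chr1": c.copy()}, 500, "b")
        mat, order = correlation_matrix([t1, t2])
        assert mat.loc["a", "b"] == pytest.approx(1.0)
        assert sorted(order) == [0, 1]

    def test_independent_tracks_near_zero(self, rng):
        tracks = [CoverageTrack({"chr1": rng.poisson(5.0, 100_000)}, 500, f"t{i}")
                  for i in range(2)]
        mat, _ = correlation_matrix(tracks)
        assert abs(mat.iloc[0, 1]) < 0.02

    def test_constant_track_undefined(self, rng):
        t1 = CoverageTrack({"chr1": rng.poisson(5.0, 500)}, 500, "a")
        t2 = CoverageTrack({"chr1": np.zeros(500, dtype=int)}, 500, "b")
        mat, _ = correlation_matrix([t1, t2])
        assert np.isnan(mat.loc["a", "b"])


class TestSlidingCorrelation:
    def test_identical_tracks_rho_one_everywhere(self, rng):
        c = rng.poisson(8.0, 400)
        tracks = [CoverageTrack({"chr1": c}, 50, "a"),
                  CoverageTrack({"chr1": c.copy()}, 50, "b")]
        df = sliding_regional_correlation(tracks, iv(0, 20_000))
        defined = df["rho_a_b"].dropna()
        np.testing.assert_allclose(defined, 1.0)

    def test_20kb_region_gives_396_positions(self, rng):
        tracks = [CoverageTrack({"chr1": rng.poisson(8.0, 400)}, 50, f"t{i}")
                  for i in range(2)]
        df = sliding_regional_correlation(tracks, iv(0, 20_000))
        assert len(df) == 400 - 5 + 1 == 396

    def test_anticorrelated_toy_rho_minus_one(self):
        a = np.arange(400, dtype=np.int64)
        tracks = [CoverageTrack({"chr1": a}, 50, "a"),
                  CoverageTrack({"chr1": a.max() - a}, 50, "b")]
        df = sliding_regional_correlation(tracks, iv(0, 20_000))
        np.testing.assert_allclose(df["rho_a_b"].dropna(), -1.0)


class TestRegionBuilders:
    def test_promoter_plus_strand(self):
        prom = make_promoters([iv(10_000, 10_001, strand="+")])
        assert (prom[0].start, prom[0].end) == (5000, 10_250)

    def test_promoter_minus_strand_mirror(self):
        prom = make_promoters([iv(9_999, 10_000, strand="-")])
        assert (prom[0].start, prom[0].end) == (9_750, 15_000)

    def test_promoter_clipped_at_chromosome_start(self):
        prom = make_promoters([iv(100, 101, strand="+")])
        assert (prom[0].start, prom[0].end) == (0, 350)

    def test_promoter_requires_strand(self):
        with pytest.raises(ValueError, match="strand"):
            make_promoters([iv(100, 101)])

    def test_tad_boundaries_centered_on_edges(self):
        b = make_tad_boundaries([iv(100_000, 300_000)])
        assert [(x.start, x.end) for x in b] == [(98_000, 102_000),
                                                 (298_000, 302_000)]

    def test_shared_breakpoint_deduplicated_when_merged(self):
        doms = [iv(0, 100_000), iv(100_000, 200_000)]
        merged = make_tad_boundaries(doms, merge=True)
        assert len(merged) == 3  # 0, 100k (shared), 200k

    def test_short_domain_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            make_tad_boundaries([iv(1000, 3000)])


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric: sum the probabilities of all tables with
    the same margins that are no more probable than the observed one."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def p_table(x):
        return (comb(col1, x, exact=True)
                * comb(n - col1, row1 - x, exact=True)) / comb(n, row1,
                                                               exact=True)
    p_obs = p_table(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = p_table(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


class TestEnrichmentFisher:
    def _sites(self, n, hit, region_start=0):
        """n 10-bp sites; the first `hit` of them fall inside the region."""
        sites = [iv(region_start + 20 * i, region_start + 20 * i + 10)
                 for i in range(n)]
        return sites

    def test_toy_table_odds_ratio_and_oracle_p(self):
        # build an 8/2/10/80 table geometrically
        region = [iv(0, 400)]
        query = self._sites(8, 8) + [iv(10_000 + 20 * i, 10_000 + 20 * i + 10)
                                     for i in range(2)]
        rest = self._sites(10, 10, region_start=0)[:10]
        # shift "rest-in-region" sites to distinct coords inside the region
        rest = [iv(1 + 20 * i + 5, 1 + 20 * i + 15) for i in range(10)]
        rest += [iv(20_000 + 20 * i, 20_000 + 20 * i + 10) for i in range(80)]
        universe = query + rest
        res = enrichment_fisher(query, region, universe)
        assert res.table.ravel().tolist() == [8, 2, 10, 80]
        assert res.odds_ratio == pytest.approx(32.0)
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(8, 2, 10, 80),
                                            rel=1e-9)

    def test_zero_cell_reports_infinite_odds(self):
        region = [iv(0, 300)]
        query = [iv(20 * i, 20 * i + 10) for i in range(10)]
        rest = [iv(10_000 + 20 * i, 10_000 + 20 * i + 10) for i in range(90)]
        res = enrichment_fisher(query, region, query + rest)
        assert np.isinf(res.odds_ratio)
        assert res.p_value == pytest.approx(
            fisher_two_sided_oracle(10, 0, 0, 90), rel=1e-9)

    def test_disjoint_query_odds_at_most_one(self):
        region = [iv(50_000, 60_000)]
        query = [iv(20 * i, 20 * i + 10) for i in range(10)]
        rest = [iv(50_000 + 20 * i, 50_000 + 20 * i + 10) for i in range(20)]
        res = enrichment_fisher(query, region, query + rest)
        assert res.odds_ratio <= 1.0

    def test_fisher_equals_oracle_on_random_small_tables(self, rng):
        for _ in range(12):
            a, b, c, d = rng.integers(0, 25, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p_scipy = stats.fisher_exact([[a, b], [c, d]])[1]
            assert p_scipy == pytest.approx(
                fisher_two_sided_oracle(int(a), int(b), int(c), int(d)),
                rel=1e-9, abs=1e-12)

    def test_query_must_be_subset_of_universe(self):
        with pytest.raises(ValueError, match="subset"):
            enrichment_fisher([iv(0, 10)], [], [iv(100, 110)])


class TestEnrichmentEmpirical:
    def test_whole_chromosome_region_p_one(self):
        query = [iv(1000 * i, 1000 * i + 10) for i in range(5)]
        res = enrichment_empirical(query, [iv(0, 100_000)], {"chr1": 100_000},
                                   n_shuffles=200, seed=1)
        assert res.p_value == pytest.approx(1.0)

    def test_minimum_attainable_p(self):
        """Tight clustering inside the only region: no shuffle can beat it."""
        query = [iv(10 + i, 11 + i) for i in range(5)]
        region = [iv(0, 20)]
        res = enrichment_empirical(query, region, {"chr1": 1_000_000},
                                   n_shuffles=499, seed=3)
        assert res.p_value >= 1.0 / 500
        assert res.p_value < 0.05

    def test_circular_shift_preserves_size_and_cyclic_spacing(self, rng):
        starts = np.sort(rng.choice(50_000, size=20, replace=False))
        query = [iv(int(s), int(s) + 5) for s in starts]
        shifted = circular_shift(query, {"chr1": 60_000},
                                 np.random.default_rng(5))
        assert len(shifted) == len(query)
        s_new = np.sort([x.start for x in shifted])
        gaps = lambda v, n: np.sort(np.diff(np.concatenate(
            [v, [v[0] + n]])))
        np.testing.assert_array_equal(gaps(np.sort(starts), 60_000),
                                      gaps(s_new, 60_000))

    def test_small_shuffle_count_warns(self):
        with pytest.warns(UserWarning, match="shuffles"):
            enrichment_empirical([iv(0, 10)], [iv(0, 100)], {"chr1": 1000},
                                 n_shuffles=50, seed=0)


class TestJaccard:
    def test_self_jaccard_one_disjoint_zero(self):
        A = [iv(0, 100)]
        B = [iv(500, 600)]
        jm = jaccard_matrix({"a": A, "a2": list(A), "b": B})
        assert jm.matrix.loc["a", "a2"] == pytest.approx(1.0)
        assert jm.matrix.loc["a", "b"] == 0.0

    def test_matches_per_bp_oracle(self, rng):
        sets = {}
        for name in "abc":
            starts = rng.integers(0, 9000, 15)
            sets[name] = [iv(int(s), int(s) + int(rng.integers(20, 300)))
                          for s in starts]
        jm = jaccard_matrix(sets)
        for x, y in itertools.combinations("abc", 2):
            mx = np.zeros(12_000, bool)
            my = np.zeros(12_000, bool)
            for s in sets[x]:
                mx[s.start:s.end] = True
            for s in sets[y]:
                my[s.start:s.end] = True
            want = (mx & my).sum() / (mx | my).sum()
            assert jm.matrix.loc[x, y] == pytest.approx(want)

    def test_empty_set_flagged_with_zero_row(self):
        jm = jaccard_matrix({"a": [iv(0, 10)], "none": []})
        assert jm.empty_sets == ["none"]
        assert jm.matrix.loc["none", "a"] == 0.0
        assert jm.matrix.loc["none", "none"] == 0.0


class TestCategorizeOverlap:
    def test_hand_tallied_toy(self):
        query = [iv(100 * i, 100 * i + 10) for i in range(10)]
        peaks_a = [iv(0, 15), iv(100, 115), iv(200, 215), iv(300, 315)]
        peaks_b = [iv(300, 320), iv(400, 420)]
        t = categorize_overlap(query, peaks_a, peaks_b)
        counts = dict(zip(t["category"], t["count"]))
        assert counts == {"a_only": 3, "a_and_b": 1, "neither": 6}
        pct = dict(zip(t["category"], t["percent"]))
        assert pct == {"a_only": 30.0, "a_and_b": 10.0, "neither": 60.0}

    def test_empty_peak_sets_all_neither(self):
        query = [iv(0, 10), iv(50, 60)]
        t = categorize_overlap(query, [], [])
        counts = dict(zip(t["category"], t["count"]))
        assert counts == {"a_only": 0, "a_and_b": 0, "neither": 2}

    def test_counts_are_exhaustive_and_exclusive(self, rng):
        query = [iv(int(s), int(s) + 10) for s in rng.integers(0, 5000, 40)]
        A = [iv(int(s), int(s) + 50) for s in rng.integers(0, 5000, 10)]
        B = [iv(int(s), int(s) + 50) for s in rng.integers(0, 5000, 10)]
        t = categorize_overlap(query, A, B, include_b_only=True)
        assert t["count"].sum() == len(query)


class TestCompareConservation:
    def test_tie_heavy_groups_give_half_u(self):
        bound = [iv(10 * i, 10 * i + 5, score=0.5) for i in range(20)]
        unbound = [iv(1000 + 10 * i, 1000 + 10 * i + 5, score=0.5)
                   for i in range(30)]
        u, p, table = compare_conservation(bound, unbound)
        assert u == pytest.approx(20 * 30 / 2)
        assert p == pytest.approx(1.0)

    def test_shifted_group_strongly_significant(self, rng):
        vb = np.clip(rng.beta(2, 5, 500) + 0.2, 0, 1)
        vu = rng.beta(2, 5, 500)
        bound = [iv(10 * i, 10 * i + 5, score=float(v))
                 for i, v in enumerate(vb)]
        unbound = [iv(100_000 + 10 * i, 100_000 + 10 * i + 5, score=float(v))
                   for i, v in enumerate(vu)]
        u, p, table = compare_conservation(bound, unbound)
        assert p < 1e-10
        tb = table.set_index("group")
        assert tb.loc["bound", "median"] > tb.loc["unbound", "median"]

    def test_track_based_scores(self):
        cons = Track({"chr1": np.linspace(0, 1, 1000)})
        bound = [iv(900 + i, 901 + i) for i in range(5)]
        unbound = [iv(10 + i, 11 + i) for i in range(5)]
        u, p, _ = compare_conservation(bound, unbound, conservation=cons)
        assert p < 0.05

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="3"):
            compare_conservation([iv(0, 5, score=0.1)],
                                 [iv(10, 15, score=0.2)])
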