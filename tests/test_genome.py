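"""Binning, conditioned correlation, fragmentation, shuffles, enrichment."""

import numpy as np
import pandas as pd
import pytest

from dualmark import genome as gn
from dualmark.intervals import IntervalSet
from dualmark.tracks import CoverageTrack


class TestBinGenome:
    def test_exact_and_trailing_tiling(self):
        bins = gn.bin_genome({"c1": 1000}, 1000)
        assert list(bins.df.itertuples(index=False, name=None)) == [("c1", 0, 1000)]
        bins = gn.bin_genome({"c1": 1500}, 1000)
        assert list(bins.df.itertuples(index=False, name=None)) == [
            ("c1", 0, 1000),
            ("c1", 1000, 1500),
        ]

    def test_blacklisted_bins_dropped_not_clipped(self):
        bl = IntervalSet.from_records([("c1", 1200, 1300)], role="blacklist")
        bins = gn.bin_genome({"c1": 3000}, 1000, blacklist=bl)
        assert list(bins.df.itertuples(index=False, name=None)) == [
            ("c1", 0, 1000),
            ("c1", 2000, 3000),
        ]

    def test_blacklist_on_unknown_chromosome_warns(self):
        bl = IntervalSet.from_records([("cZ", 0, 10)])
        with pytest.warns(UserWarning, match="cZ"):
            gn.bin_genome({"c1": 3000}, 1000, blacklist=bl)


class TestCorrelation:
    def test_track_correlates_perfectly_with_itself(self, rng, small_sizes):
        vals = {c: rng.uniform(0, 4, size=L // 100) for c, L in small_sizes.items()}
        t = CoverageTrack.from_dense(vals, small_sizes, 100)
        assert gn.binned_correlation(t, t, 500) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self, rng, small_sizes):
        vals = {c: rng.uniform(0, 4, size=L // 100) for c, L in small_sizes.items()}
        t = CoverageTrack.from_dense(vals, small_sizes, 100)
        neg = t.map_values(lambda v: 10.0 - v)
        assert gn.binned_correlation(t, neg, 500) == pytest.approx(-1.0)

    def test_matches_textbook_pearson_on_bin_means(self, rng, small_sizes):
        latent = {c: rng.uniform(0, 2, size=L // 100) for c, L in small_sizes.items()}
        a = CoverageTrack.from_dense(
            {c: v + rng.normal(0, 0.3, len(v)) for c, v in latent.items()},
            small_sizes, 100,
        )
        b = CoverageTrack.from_dense(
            {c: v + rng.normal(0, 0.3, len(v)) for c, v in latent.items()},
            small_sizes, 100,
        )
        bins = gn.bin_genome(small_sizes, 500)
        x, y = gn.mean_signal(a, bins), gn.mean_signal(b, bins)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert gn.binned_correlation(a, b, 500) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_is_flagged_undefined(self, small_sizes):
        flat = CoverageTrack.constant(2.0, small_sizes)
        other = CoverageTrack.constant(1.0, small_sizes)
        assert np.isnan(gn.binned_correlation(flat, other, 500))


def _bins_with_values(values, bin_size=10):
    n = len(values)
    df = pd.DataFrame(
        {
            "chrom": "c1",
            "start": np.arange(n) * bin_size,
            "end": (np.arange(n) + 1) * bin_size,
            "sig": values,
        }
    )
    return gn.GenomeBins(df=df, bin_size=bin_size)


class TestQuantileSplit:
    def test_distinct_values_rank_into_equal_groups(self, rng):
        values = rng.permutation(100).astype(float)
        rep = gn.quantile_split(_bins_with_values(values), "sig", k=10)
        sizes = np.bincount(rep.group)[1:]
        assert (sizes == 10).all()
        top = values[rep.group == 1]
        assert sorted(top) == list(range(90, 100))

    def test_all_ties_fall_back_to_genomic_order(self):
        rep = gn.quantile_split(_bins_with_values(np.ones(40)), "sig", k=4)
        assert (rep.group == np.repeat([1, 2, 3, 4], 10)).all()

    def test_partition_property_with_uneven_sizes(self, rng):
        values = rng.uniform(size=103)
        rep = gn.quantile_split(_bins_with_values(values), "sig", k=10)
        sizes = np.bincount(rep.group)[1:]
        assert sizes.sum() == 103 and sizes.max() - sizes.min() <= 1

    def test_group_means_non_increasing(self, rng):
        values = rng.uniform(size=200)
        rep = gn.quantile_split(_bins_with_values(values), "sig", k=10)
        means = [values[rep.group == g].mean() for g in range(1, 11)]
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestConditionalCorrelation:
    def test_identical_tracks_r_one(self, rng):
        values = rng.uniform(size=60)
        bins = _bins_with_values(values)
        bins.df["x"] = values * 2 + 1
        bins.df["y"] = values * 2 + 1
        rep = gn.quantile_split(bins, "sig", k=3)
        out = gn.conditional_correlation(rep, "x", "y")
        np.testing.assert_allclose(out["r"], 1.0)

    def test_independent_noise_stays_near_zero(self):
        rs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            bins = _bins_with_values(r.uniform(size=300))
            bins.df["x"] = r.normal(size=300)
            bins.df["y"] = r.normal(size=300)
            rep = gn.quantile_split(bins, "sig", k=3)
            rs.extend(gn.conditional_correlation(rep, "x", "y")["r"])
        assert np.mean(np.abs(rs) < 3 / np.sqrt(100)) > 0.8


class TestFragmentPeaks:
    sizes = {"c1": 3000}

    def test_aligned_peak_fragments_exactly(self):
        peaks = IntervalSet.from_records([("c1", 0, 450)])
        frags = gn.fragment_peaks(peaks, self.sizes, 150, 0.5)
        assert list(frags) == [("c1", 0, 150), ("c1", 150, 300), ("c1", 300, 450)]

    def test_half_overlap_boundary_is_inclusive(self):
        # fragment [150, 300): 75 bp overlap kept, 74 bp dropped
        kept = gn.fragment_peaks(
            IntervalSet.from_records([("c1", 225, 400)]), self.sizes, 150, 0.5
        )
        assert ("c1", 150, 300) in list(kept)
        dropped = gn.fragment_peaks(
            IntervalSet.from_records([("c1", 226, 400)]), self.sizes, 150, 0.5
        )
        assert ("c1", 150, 300) not in list(dropped)

    def test_every_kept_fragment_verified_brute_force(self, rng):
        sizes = {"c1": 20_000}
        recs = [
            ("c1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 19_000, 30), rng.integers(50, 900, 30))
        ]
        peaks = IntervalSet.from_records(recs)
        base = np.zeros(20_000, dtype=bool)
        for _, s, e in peaks:
            base[s:e] = True
        frags = gn.fragment_peaks(peaks, sizes, 150, 0.5)
        for _, s, e in frags:
            assert base[s:e].sum() >= 0.5 * (e - s)
        # and no eligible fragment was missed
        kept = {(s, e) for _, s, e in frags}
        for s in range(0, 20_000, 150):
            e = min(s + 150, 20_000)
            if base[s:e].sum() >= 0.5 * (e - s):
                assert (s, e) in kept


class TestClusterFragments:
    def _frags(self, n):
        return IntervalSet.from_records(
            [("c1", i * 150, (i + 1) * 150) for i in range(n)]
        )

    def test_k_one_gives_single_cluster(self, rng):
        sig = pd.DataFrame({"a": rng.uniform(size=20), "b": rng.uniform(size=20)})
        rep = gn.cluster_fragments(self._frags(20), sig, k=1, ordering_track="a")
        assert (rep.labels == 0).all()

    def test_duplicate_rows_co_assigned(self, rng):
        base = rng.uniform(size=(10, 2))
        sig = pd.DataFrame(np.vstack([base, base]), columns=["a", "b"])
        rep = gn.cluster_fragments(self._frags(20), sig, k=3, ordering_track="a")
        assert (rep.labels[:10] == rep.labels[10:]).all()

    def test_clusters_ordered_by_ordering_track(self, rng):
        sig = pd.DataFrame(
            {
                "a": np.concatenate([rng.normal(10, 0.1, 15), rng.normal(0, 0.1, 15)]),
                "b": rng.normal(0, 0.1, 30),
            }
        )
        rep = gn.cluster_fragments(self._frags(30), sig, k=2, ordering_track="a")
        assert (rep.labels[:15] == 0).all() and (rep.labels[15:] == 1).all()

    def test_k_beyond_distinct_rows_rejected(self):
        sig = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="distinct"):
            gn.cluster_fragments(self._frags(3), sig, k=2, ordering_track="a")


class TestShuffle:
    sizes = {"c1": 50_000, "c2": 30_000}

    def test_length_multiset_conserved(self, rng):
        recs = [
            ("c1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 40_000, 25), rng.integers(10, 2_000, 25))
        ]
        template = IntervalSet.from_records(recs)
        shuffled = gn.shuffle_intervals(template, self.sizes, seed=3)
        assert sorted(shuffled.lengths) == sorted(template.lengths)

    def test_blacklist_respected(self):
        template = IntervalSet.from_records([("c1", 0, 1000)] * 5)
        bl = IntervalSet.from_records([("c1", 0, 45_000), ("c2", 0, 25_000)])
        shuffled = gn.shuffle_intervals(template, self.sizes, blacklist=bl, seed=0)
        assert (shuffled.df.apply(
            lambda r: bl.overlap_bp([r["chrom"]], np.array([r["start"]]),
                                    np.array([r["end"]]))[0], axis=1) == 0).all()

    def test_uniform_placement_hits_region_proportionally(self):
        # a region covering 30% of the genome should catch ~30% of bases
        region = IntervalSet.from_records([("c1", 0, 24_000)])  # 24k / 80k
        template = IntervalSet.from_records([("c1", 0, 100)] * 40)
        frac = []
        for seed in range(30):
            sh = gn.shuffle_intervals(template, self.sizes, seed=seed)
            ov = region.overlap_bp(
                sh.df["chrom"].to_numpy(),
                sh.df["start"].to_numpy(),
                sh.df["end"].to_numpy(),
            )
            frac.append(ov.sum() / sh.lengths.sum())
        assert abs(np.mean(frac) - 0.3) < 0.05

    def test_infeasible_length_raises(self):
        template = IntervalSet.from_records([("c1", 0, 49_999)])
        bl = IntervalSet.from_records([("c1", 20_000, 30_000), ("c2", 0, 30_000)])
        with pytest.raises(ValueError, match="length"):
            gn.shuffle_intervals(template, self.sizes, blacklist=bl, seed=0)


class TestStateEnrichment:
    sizes = {"c1": 100_000}

    def _states(self):
        # three states partitioning the chromosome in 10 kb alternating blocks
        recs = []
        labels = ["A", "B", "C"]
        for i in range(10):
            recs.append(("c1", i * 10_000, (i + 1) * 10_000, labels[i % 3]))
        return IntervalSet.from_records(recs, role="states")

    def test_self_enrichment_is_maximal(self):
        states = self._states()
        peaks = IntervalSet(states.df[states.df["name"] == "A"][["chrom", "start", "end"]])
        rep = gn.state_enrichment(peaks, states, self.sizes, n_shuffles=20, seed=1)
        df = rep.df.set_index("category")
        assert df.loc["A", "ratio"] == df["ratio"].max()
        assert df.loc["A", "overlap_pct"] == 100.0

    def test_disjoint_state_has_zero_ratio(self):
        states = self._states()
        peaks = IntervalSet.from_records([("c1", 5_000, 5_100)])  # inside state A only
        rep = gn.state_enrichment(peaks, states, self.sizes, n_shuffles=5, seed=1)
        df = rep.df.set_index("category")
        assert df.loc["B", "observed"] == 0 and df.loc["B", "ratio"] == 0.0

    def test_empirical_p_in_unit_interval(self):
        rep = gn.state_enrichment(
            IntervalSet.from_records([("c1", 0, 500)]),
            self._states(), self.sizes, n_shuffles=9, seed=0,
        )
        assert ((rep.df["p"] > 0) & (rep.df["p"] <= 1)).all()


class TestPeakOverlapEnrichment:
    sizes = {"c1": 50_000, "c2": 50_000}

    def test_subset_gives_full_overlap(self):
        b = IntervalSet.from_records([("c1", 0, 10_000), ("c1", 20_000, 30_000)])
        a = IntervalSet.from_records([("c1", 100, 200), ("c1", 25_000, 25_100)])
        rep = gn.peak_overlap_enrichment(a, b, self.sizes, n_permutations=5, seed=0)
        assert rep.df["overlap_pct"].iloc[0] == 100.0

    def test_disjoint_chromosomes_give_zero(self):
        a = IntervalSet.from_records([("c1", 0, 100)])
        b = IntervalSet.from_records([("c2", 0, 100)])
        rep = gn.peak_overlap_enrichment(a, b, self.sizes, n_permutations=5, seed=0)
        assert rep.df["overlap_pct"].iloc[0] == 0.0
        assert rep.df["ratio"].iloc[0] == 0.0


class TestRegionMatrix:
    def test_constant_track_fills_matrix(self, small_sizes):
        t = CoverageTrack.constant(3.0, small_sizes)
        regions = IntervalSet.from_records([("chrA", 4_000, 4_100), ("chrA", 6_000, 6_200)])
        mat, col_means = gn.region_matrix(t, regions, flank=500, n_columns=10)
        np.testing.assert_allclose(mat.iloc[:, 2:].to_numpy(dtype=float), 3.0)
        np.testing.assert_allclose(col_means, 3.0)

    def test_delta_peak_lands_in_central_column(self, small_sizes):
        recs = [("chrA", 4_990, 5_010, 100.0)]
        t = CoverageTrack.from_records(recs, small_sizes)
        regions = IntervalSet.from_records([("chrA", 4_900, 5_100)])
        mat, _ = gn.region_matrix(t, regions, flank=500, n_columns=11)
        vals = mat.iloc[0, 2:].to_numpy(dtype=float)
        assert np.nanargmax(vals) == 5  # middle of 11 columns

    def test_row_means_match_interval_means(self, rng, small_sizes):
        vals = {c: rng.uniform(0, 4, size=L // 10) for c, L in small_sizes.items()}
        t = CoverageTrack.from_dense(vals, small_sizes, 10)
        regions = IntervalSet.from_records([("chrA", 3_000, 3_100), ("chrA", 7_000, 7_400)])
        mat, _ = gn.region_matrix(t, regions, flank=500, n_columns=10)
        for _, row in mat.iterrows():
            mid = int(row["mid"])
            expected = t.mean_over(["chrA"], np.array([mid - 500]), np.array([mid + 500]))[0]
            assert np.nanmean(row.iloc[2:].to_numpy(dtype=float)) == pytest.approx(
                expected, abs=1e-10
            )

    def test_off_chromosome_midpoint_dropped(self, small_sizes):
        t = CoverageTrack.constant(1.0, small_sizes)
        regions = IntervalSet.from_records([("chrQ", 0, 10)])
        with pytest.warns(UserWarning):
            mat, _ = gn.region_matrix(t, regions, flank=100, n_columns=4)
        assert len(mat) == 0
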