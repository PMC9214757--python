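import itertools

import numpy as np
import pytest
from scipy.special import comb

from hicogeny import comparative, simdata
from hicogeny.core import BinTable, GenomicInterval, IntervalSet, ScalarTrack

from conftest import make_bins, symmetric_matrix


def banded_matrix(values_by_pixel, n, kind="balanced"):
    v = np.zeros((n, n))
    for (i, j), x in values_by_pixel.items():
        v[i, j] = v[j, i] = x
    return symmetric_matrix(v, bins=make_bins(n), kind=kind)


class TestDeconvolve:
    def test_identical_matrices_zero_difference(self):
        m = banded_matrix({(0, 1): 3.0, (1, 2): 5.0, (0, 2): 1.0}, 4)
        diff = comparative.deconvolve([m, m], (0, 1))
        assert diff.kind == "difference"
        np.testing.assert_allclose(diff.values, 0.0, atol=1e-12)

    def test_three_pixel_quantile_worked_example(self):
        """(1,2,3) and (10,20,30) both map to the average sorted
        distribution (5.5, 11, 16.5); the difference is identically 0."""
        a = banded_matrix({(0, 1): 1.0, (1, 2): 2.0, (2, 3): 3.0}, 4)
        b = banded_matrix({(0, 1): 10.0, (1, 2): 20.0, (2, 3): 30.0}, 4)
        na, nb = comparative.quantile_normalize_matrices([a, b])
        assert na.values[0, 1] == pytest.approx(5.5)
        assert na.values[1, 2] == pytest.approx(11.0)
        assert na.values[2, 3] == pytest.approx(16.5)
        np.testing.assert_allclose(na.values, nb.values, atol=1e-12)
        diff = comparative.deconvolve([a, b], (0, 1))
        np.testing.assert_allclose(diff.values, 0.0, atol=1e-12)

    def test_shared_distribution_is_fixed_point(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2.0, 2.0, size=6)
        pixels = [(0, 1), (0, 2), (1, 3), (2, 4), (3, 5), (4, 5)]
        a = banded_matrix(dict(zip(pixels, vals)), 6)
        perm = rng.permutation(vals)
        b = banded_matrix(dict(zip(pixels, perm)), 6)
        na, nb = comparative.quantile_normalize_matrices([a, b])
        np.testing.assert_allclose(np.sort(na.values[na.values > 0]),
                                   np.sort(a.values[a.values > 0]))

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        pixels = [(0, 1), (1, 2), (0, 3), (2, 3)]
        a = banded_matrix(dict(zip(pixels, rng.gamma(2, 2, 4))), 5)
        b = banded_matrix(dict(zip(pixels, rng.gamma(2, 2, 4))), 5)
        ab = comparative.deconvolve([a, b], (0, 1))
        ba = comparative.deconvolve([a, b], (1, 0))
        np.testing.assert_allclose(ab.values, -ba.values, atol=1e-12)

    def test_mismatched_bins_rejected(self):
        a = banded_matrix({(0, 1): 1.0}, 4)
        b = banded_matrix({(0, 1): 1.0}, 5)
        with pytest.raises(ValueError, match="bin tables"):
            comparative.deconvolve([a, b], (0, 1))


class TestConservedRegions:
    def test_identical_tracks_full_genome_region(self):
        rng = np.random.default_rng(2)
        bins = BinTable.from_chrom_lengths(
            [("chr1", 50 * 400_000), ("chr2", 50 * 400_000)], 400_000
        )
        x = rng.standard_normal(100)
        a = ScalarTrack(bins, x)
        regions = comparative.conserved_regions(a, ScalarTrack(bins, x.copy()))
        assert len(regions) == 2
        for r in regions:
            assert r.mean_r == pytest.approx(1.0)
            assert r.start == 0 and r.end == 50 * 400_000

    def test_negated_tracks_no_regions(self):
        rng = np.random.default_rng(3)
        bins = BinTable.from_chrom_lengths([("chr1", 50 * 400_000)], 400_000)
        x = rng.standard_normal(50)
        regions = comparative.conserved_regions(
            ScalarTrack(bins, x), ScalarTrack(bins, -x)
        )
        assert regions == []

    def test_planted_blocks_recovered(self):
        blocks = IntervalSet(
            [
                GenomicInterval("chr1", 40_000_000, 80_000_000),
                GenomicInterval("chr1", 120_000_000, 160_000_000),
            ]
        )
        a, b = simdata.simulate_pc1_pair(
            2000, blocks, r_in=0.95, r_out=0.0, seed=6, bin_size=100_000
        )
        regions = comparative.conserved_regions(a, b)
        from hicogeny.pipeline import region_jaccard

        assert region_jaccard(regions, blocks) >= 0.8

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        bins = BinTable.from_chrom_lengths([("chr1", 80 * 400_000)], 400_000)
        x, y = rng.standard_normal((2, 80))
        r1 = comparative.conserved_regions(ScalarTrack(bins, x), ScalarTrack(bins, y))
        r2 = comparative.conserved_regions(
            ScalarTrack(bins, 7.3 * x), ScalarTrack(bins, 0.2 * y)
        )
        assert [(r.chrom, r.start, r.end) for r in r1] == [
            (r.chrom, r.start, r.end) for r in r2
        ]


class TestClusterProfiles:
    @staticmethod
    def grouped_tracks(seed=0):
        rng = np.random.default_rng(seed)
        bins = BinTable.from_chrom_lengths([("chr1", 200 * 400_000)], 400_000)
        base1 = rng.standard_normal(200)
        base2 = rng.standard_normal(200)
        tracks = []
        for k in range(2):
            tracks.append((f"g1_{k}", ScalarTrack(bins, base1 + 0.1 * rng.standard_normal(200))))
            tracks.append((f"g2_{k}", ScalarTrack(bins, base2 + 0.1 * rng.standard_normal(200))))
        return tracks

    def test_two_groups_separate_at_top_split(self):
        from scipy.cluster.hierarchy import fcluster

        Z, names = comparative.cluster_profiles(self.grouped_tracks())
        flat = fcluster(Z, t=2, criterion="maxclust")
        groups = {}
        for name, c in zip(names, flat):
            groups.setdefault(name.split("_")[0], set()).add(c)
        assert groups["g1"] != groups["g2"]
        assert len(groups["g1"]) == 1 and len(groups["g2"]) == 1

    def test_duplicate_joins_first(self):
        tracks = self.grouped_tracks()
        dup = [("dupA", tracks[0][1]), ("dupB", tracks[0][1].copy())] + tracks[1:]
        Z, names = comparative.cluster_profiles(dup)
        first = Z[0]
        joined = {names[int(first[0])], names[int(first[1])]}
        assert joined == {"dupA", "dupB"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_input_order_invariance(self):
        tracks = self.grouped_tracks()
        Z1, n1 = comparative.cluster_profiles(tracks)
        Z2, n2 = comparative.cluster_profiles(tracks[::-1])
        assert n1 == n2
        np.testing.assert_allclose(Z1, Z2)

    def test_newick_serialization(self):
        Z, names = comparative.cluster_profiles(self.grouped_tracks())
        nwk = comparative.linkage_to_newick(Z, names)
        assert nwk.endswith(";") and all(n in nwk for n in names)

    def test_constant_track_rejected(self):
        bins = BinTable.from_chrom_lengths([("chr1", 10 * 400_000)], 400_000)
        tracks = [
            ("ok", ScalarTrack(bins, np.arange(10.0))),
            ("flat", ScalarTrack(bins, np.ones(10))),
        ]
        with pytest.raises(ValueError, match="flat"):
            comparative.cluster_profiles(tracks)


class TestRegionOverlap:
    @staticmethod
    def regions(triples):
        return [comparative.ConservedRegion(c, s, e, 1.0) for c, s, e in triples]

    def test_identity_and_disjoint(self):
        a = self.regions([("chr1", 0, 100), ("chr1", 200, 300)])
        assert comparative.region_overlap(a, a) == (0, 200, 0)
        b = self.regions([("chr1", 400, 500)])
        assert comparative.region_overlap(a, b)[1] == 0

    def test_interval_arithmetic_by_hand(self):
        a = self.regions([("chr1", 0, 100)])
        b = self.regions([("chr1", 50, 150)])
        assert comparative.region_overlap(a, b) == (50, 50, 50)

    def test_overlapping_within_one_list_rejected(self):
        a = self.regions([("chr1", 0, 100), ("chr1", 50, 150)])
        with pytest.raises(ValueError, match="within one list"):
            comparative.region_overlap(a, a)


def brute_force_fisher_two_sided(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def p_of(x):
        return (
            comb(row1, x, exact=True)
            * comb(row2, col1 - x, exact=True)
            / comb(n, col1, exact=True)
        )

    p_obs = p_of(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(col1, row1) + 1):
        px = p_of(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisherEnrichment:
    def test_five_five_diagonal_table(self):
        """Bins 0-4 in regions all carry features, bins 5-9 none:
        table [[5,0],[0,5]] has two-sided p = 2/252."""
        universe = make_bins(10)
        regions = [comparative.ConservedRegion("chr1", 0, 5 * 40_000, 1.0)]
        features = IntervalSet(
            GenomicInterval("chr1", i * 40_000 + 10, i * 40_000 + 100, f"f{i}")
            for i in range(5)
        )
        res = comparative.fisher_enrichment(regions, features, universe)
        np.testing.assert_array_equal(res.table, [[5, 0], [0, 5]])
        assert res.p == pytest.approx(2 / 252)

    def test_agreement_with_enumeration_small_margins(self):
        """Implementation matches brute-force hypergeometric enumeration
        across a grid of tables with margins <= 30."""
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 16, size=4)
            table = np.array([[a, b], [c, d]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            _, p = sps.fisher_exact(table, alternative="two-sided")
            assert p == pytest.approx(brute_force_fisher_two_sided(table), rel=1e-9)

    def test_degenerate_margin(self):
        universe = make_bins(6)
        regions = [comparative.ConservedRegion("chr1", 0, 6 * 40_000, 1.0)]
        res = comparative.fisher_enrichment(regions, IntervalSet(), universe)
        assert res.p == 1.0 and np.isnan(res.odds_ratio)

    def test_null_pvalues_roughly_uniform(self):
        """Random features vs random regions give non-enriched p-values."""
        rng = np.random.default_rng(5)
        universe = make_bins(200)
        ps = []
        for _ in range(40):
            start = int(rng.integers(0, 150)) * 40_000
            regions = [
                comparative.ConservedRegion("chr1", start, start + 50 * 40_000, 1.0)
            ]
            feat_bins = rng.choice(200, size=30, replace=False)
            features = IntervalSet(
                GenomicInterval("chr1", int(b) * 40_000 + 5, int(b) * 40_000 + 50)
                for b in feat_bins
            )
            ps.append(comparative.fisher_enrichment(regions, features, universe).p)
        # Fisher p under the null is stochastically >= uniform (conservative)
        assert np.mean(ps) > 0.3
        assert np.mean(np.array(ps) < 0.05) < 0.2
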