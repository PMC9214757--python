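import numpy as np
import pytest

from hicogeny import matrixio, simdata
from hicogeny.core import BinTable, ContactMatrix

from conftest import make_bins, symmetric_matrix


def write_text(path, text):
    path.write_text(text)
    return str(path)


class TestTripletIO:
    def test_fold_and_sum_duplicates(self, tmp_path):
        bins = make_bins(3)
        matrixio.write_bins(bins, tmp_path / "bins.bed")
        trip = write_text(tmp_path / "m.txt", "0 1 5\n1 0 3\n")
        m = matrixio.read_matrix(trip, tmp_path / "bins.bed")
        assert m.values[0, 1] == 8 and m.values[1, 0] == 8

    def test_empty_triplet_gives_zero_matrix(self, tmp_path):
        bins = make_bins(4)
        matrixio.write_bins(bins, tmp_path / "bins.bed")
        trip = write_text(tmp_path / "m.txt", "")
        m = matrixio.read_matrix(trip, tmp_path / "bins.bed")
        assert m.n_bins == 4 and m.values.sum() == 0

    def test_symmetry_of_read_entries(self, tmp_path):
        bins = make_bins(3)
        matrixio.write_bins(bins, tmp_path / "bins.bed")
        trip = write_text(tmp_path / "m.txt", "0 0 2\n0 2 1\n")
        m = matrixio.read_matrix(trip, tmp_path / "bins.bed")
        assert m.values[2, 0] == 1

    def test_errors_on_bad_rows(self, tmp_path):
        bins = make_bins(3)
        matrixio.write_bins(bins, tmp_path / "bins.bed")
        bad_id = write_text(tmp_path / "a.txt", "0 7 1\n")
        with pytest.raises(ValueError, match="out of range"):
            matrixio.read_matrix(bad_id, tmp_path / "bins.bed")
        neg = write_text(tmp_path / "b.txt", "0 1 -3\n")
        with pytest.raises(ValueError, match="negative"):
            matrixio.read_matrix(neg, tmp_path / "bins.bed")

    def test_write_read_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        v = rng.poisson(4.0, size=(6, 6))
        v = np.triu(v) + np.triu(v, 1).T
        m = symmetric_matrix(v, bins=make_bins(6))
        matrixio.write_bins(m.bins, tmp_path / "bins.bed")
        matrixio.write_matrix(m, tmp_path / "m.txt")
        back = matrixio.read_matrix(tmp_path / "m.txt", tmp_path / "bins.bed")
        np.testing.assert_array_equal(back.values, m.values)

    def test_bedgraph_roundtrip(self, tmp_path):
        from hicogeny.core import ScalarTrack

        bins = make_bins(5)
        track = ScalarTrack(bins, np.array([1.5, -2.0, np.nan, 0.25, 3.0]))
        matrixio.write_bedgraph(track, tmp_path / "t.bedgraph")
        back = matrixio.read_bedgraph(tmp_path / "t.bedgraph", bins)
        np.testing.assert_allclose(back.values, track.values)


class TestMergeReplicates:
    def test_doubling_and_identity(self):
        v = np.array([[0, 2, 1], [2, 4, 0], [1, 0, 2]])
        m = symmetric_matrix(v, bins=make_bins(3))
        zero = symmetric_matrix(np.zeros((3, 3), dtype=int), bins=m.bins)
        double = matrixio.merge_replicates([m, m])
        np.testing.assert_array_equal(double.values, 2 * v)
        same = matrixio.merge_replicates([m, zero])
        np.testing.assert_array_equal(same.values, v)

    def test_disjoint_support_union(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 3
        b = np.zeros((4, 4), dtype=int)
        b[2, 3] = b[3, 2] = 7
        bins = make_bins(4)
        merged = matrixio.merge_replicates(
            [symmetric_matrix(a, bins=bins), symmetric_matrix(b, bins=bins)]
        )
        assert merged.values[0, 1] == 3 and merged.values[2, 3] == 7

    def test_mismatched_bins_error(self):
        a = symmetric_matrix(np.zeros((3, 3), dtype=int), bins=make_bins(3))
        b = symmetric_matrix(np.zeros((4, 4), dtype=int), bins=make_bins(4))
        with pytest.raises(ValueError, match="mismatched"):
            matrixio.merge_replicates([a, b])


class TestReplicateCorrelation:
    def test_self_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.poisson(5.0, size=(20, 20))
        v = np.triu(v) + np.triu(v, 1).T
        a = symmetric_matrix(v, bins=make_bins(20))
        assert matrixio.replicate_correlation(a, a) == pytest.approx(1.0)
        b = symmetric_matrix((2 * v + 7).astype(int), bins=a.bins)
        assert matrixio.replicate_correlation(a, b) == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        """Banded Pearson equals a pixel-by-pixel hand enumeration."""
        rng = np.random.default_rng(2)
        bins = make_bins(8, chroms=("chr1", "chr2"))
        n = bins.n_bins

        def draw():
            v = rng.poisson(6.0, size=(n, n))
            return symmetric_matrix(np.triu(v) + np.triu(v, 1).T, bins=bins)

        a, b = draw(), draw()
        max_dist = 3 * 40_000
        xs, ys = [], []
        for chrom in ("chr1", "chr2"):
            sl = bins.chrom_slice(chrom)
            for i in range(sl.start, sl.stop):
                for j in range(i, sl.stop):
                    if (j - i) * 40_000 <= max_dist:
                        xs.append(a.values[i, j])
                        ys.append(b.values[i, j])
        expected = np.corrcoef(xs, ys)[0, 1]
        got = matrixio.replicate_correlation(a, b, max_dist=max_dist)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_error(self):
        a = symmetric_matrix(np.ones((5, 5), dtype=int), bins=make_bins(5))
        with pytest.raises(ValueError, match="zero-variance"):
            matrixio.replicate_correlation(a, a)


class TestIceNormalize:
    def test_equal_row_sums_is_fixed_point(self):
        """A matrix with equal row sums balances to itself (up to scale)."""
        n = 10
        v = np.full((n, n), 5.0)
        m = symmetric_matrix(v.astype(int), bins=make_bins(n))
        bal, bias = matrixio.ice_normalize(m, mask_low_frac=0.0)
        assert bal.converged
        np.testing.assert_allclose(bias, bias[0])
        ratio = bal.values / v
        np.testing.assert_allclose(ratio, ratio[0, 0])

    def test_plant_and_recover_biases(self, biased_sim):
        """Biases recovered up to the structural (coverage) component."""
        m, bins, truth = biased_sim
        bal, bias = matrixio.ice_normalize(m)
        # structural reference: ICE of the unbiased noise-free expectation
        E0 = truth.expected_matrix / np.outer(truth.bias_vector, truth.bias_vector)
        _, struct = matrixio.ice_normalize(
            ContactMatrix(bins, E0, kind="balanced"), mask_low_frac=0.02
        )
        ok = np.isfinite(bias) & np.isfinite(struct)
        r = np.corrcoef(bias[ok] / struct[ok], truth.bias_vector[ok])[0, 1]
        assert r > 0.99

    def test_row_sum_cv_below_tolerance(self, biased_sim):
        m, _, _ = biased_sim
        bal, bias = matrixio.ice_normalize(m, tol=1e-5)
        ok = ~bal.mask
        s = bal.values[ok][:, ok].sum(axis=1)
        assert s.std() / s.mean() < 1e-4

    def test_bias_factorization_identity(self, biased_sim):
        """raw == b_i * b_j * balanced holds exactly on unmasked pixels."""
        m, _, _ = biased_sim
        bal, bias = matrixio.ice_normalize(m)
        ok = ~bal.mask
        i, j = np.nonzero(np.triu(m.values) > 0)
        keep = ok[i] & ok[j]
        i, j = i[keep], j[keep]
        np.testing.assert_allclose(
            bal.values[i, j] * bias[i] * bias[j], m.values[i, j], rtol=1e-10
        )

    def test_all_masked_raises(self):
        m = symmetric_matrix(np.zeros((5, 5), dtype=int), bins=make_bins(5))
        with pytest.raises(ValueError, match="unmasked"):
            matrixio.ice_normalize(m)


class TestObservedExpected:
    def test_distance_function_gives_unity(self):
        n = 30
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        v = 1.0 / (1.0 + d)
        m = symmetric_matrix(v, bins=make_bins(n), kind="balanced")
        oe = matrixio.observed_expected(m)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(oe.values[off], 1.0)

    def test_doubled_pixel_oe_value(self):
        """Doubling one pixel at a distance with k pixels gives 2k/(k+1)."""
        n = 12
        v = np.ones((n, n))
        d = 3
        k = n - d  # pixels at that distance
        v[0, d] = v[d, 0] = 2.0
        m = symmetric_matrix(v, bins=make_bins(n), kind="balanced")
        oe = matrixio.observed_expected(m)
        assert oe.values[0, d] == pytest.approx(2 * k / (k + 1))

    def test_raw_input_rejected(self):
        m = symmetric_matrix(np.ones((5, 5), dtype=int), bins=make_bins(5))
        with pytest.raises(ValueError, match="balanced"):
            matrixio.observed_expected(m)


class TestCoarsen:
    def test_block_sum_by_hand(self):
        v = np.array(
            [
                [1, 2, 3, 4],
                [2, 5, 6, 7],
                [3, 6, 8, 9],
                [4, 7, 9, 10],
            ]
        )
        m = symmetric_matrix(v, bins=make_bins(4))
        c = matrixio.coarsen(m, 2)
        assert c.n_bins == 2
        # upper-left block, each unordered pair once: (0,0)+(0,1)+(1,1)
        assert c.values[0, 0] == 1 + 2 + 5
        assert c.values[0, 1] == 3 + 4 + 6 + 7
        assert c.values[1, 1] == 8 + 9 + 10
        assert c.bins.bin_size == 80_000

    def test_zero_preservation_and_conservation(self):
        zero = symmetric_matrix(np.zeros((6, 6), dtype=int), bins=make_bins(6))
        assert matrixio.coarsen(zero, 3).values.sum() == 0
        rng = np.random.default_rng(4)
        v = rng.poisson(3.0, size=(9, 9))
        v = np.triu(v) + np.triu(v, 1).T
        m = symmetric_matrix(v, bins=make_bins(3, chroms=("chr1", "chr2", "chr3")))
        c = matrixio.coarsen(m, 2)
        assert c.total() == m.total()

    def test_invalid_factor(self):
        m = symmetric_matrix(np.zeros((4, 4), dtype=int), bins=make_bins(4))
        with pytest.raises(ValueError, match="factor"):
            matrixio.coarsen(m, 1)
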