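import numpy as np
import pytest

from hicarch.matrix_core import (
    BinTable,
    ContactMatrix,
    apply_normalization,
    compute_normalization,
    expected_by_distance,
    observed_over_expected,
    read_bin_table,
    read_contact_matrix,
    write_bin_table,
    write_contact_matrix,
)

from conftest import make_matrix, random_symmetric


def expected_by_distance_oracle(dense):
    """Brute-force per-diagonal mean over the dense matrix."""
    n = dense.shape[0]
    out = np.zeros(n)
    for d in range(n):
        vals = [dense[i, i + d] for i in range(n - d)]
        out[d] = np.mean(vals)
    return out


class TestTripletIO:
    def test_symmetry_folding(self, bins20, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("0\t1\t5\n1\t0\t3\n")
        m = read_contact_matrix(p, bins20)
        trip = m.triplets()
        assert len(trip) == 1
        assert (trip.iloc[0]["i"], trip.iloc[0]["j"], trip.iloc[0]["value"]) == (0, 1, 8)

    def test_empty_file(self, bins20, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("")
        m = read_contact_matrix(p, bins20)
        assert m.nnz == 0

    def test_out_of_range_names_line(self, tmp_path):
        bins = BinTable("chrT", 5 * 10_000, 10_000)
        p = tmp_path / "m.tsv"
        p.write_text("0\t1\t2\n0\t10\t1\n")
        with pytest.raises(IndexError, match=":2:"):
            read_contact_matrix(p, bins)

    def test_negative_count_rejected(self, bins20, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("0\t1\t-4\n")
        with pytest.raises(ValueError, match="negative"):
            read_contact_matrix(p, bins20)

    def test_comment_lines_ignored(self, bins20, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("# header\n0\t0\t7\n")
        m = read_contact_matrix(p, bins20)
        assert m.total() == 7

    def test_round_trip_bit_identical(self, bins100, tmp_path, default_sim):
        _, matrix, _ = default_sim
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_contact_matrix(matrix, p1)
        again = read_contact_matrix(p1, matrix.bin_table)
        write_contact_matrix(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_bin_table_round_trip(self, bins100, tmp_path):
        p = tmp_path / "bins.tsv"
        write_bin_table(bins100, p)
        back = read_bin_table(p)
        assert back == bins100


class TestNormalization:
    def test_vc_2x2_hand_case(self):
        m = make_matrix([[0, 2], [2, 0]])
        vec = compute_normalization(m, "VC")
        assert np.allclose(vec.weights, [1.0, 1.0])
        normed = apply_normalization(m, vec)
        assert np.allclose(normed.to_dense(), m.to_dense())

    def test_balanced_fixed_point_on_equal_rowsums(self):
        # circulant matrix: every row sum already equal
        n = 6
        dense = np.ones((n, n)) + np.eye(n)
        m = make_matrix(dense)
        vec = compute_normalization(m, "balanced")
        w = vec.weights
        assert np.allclose(w, w[0])

    def test_balanced_rowsum_relative_sd(self):
        rng = np.random.default_rng(42)
        m = make_matrix(random_symmetric(80, rng) + 1.0)
        vec = compute_normalization(m, "balanced", tol=1e-7)
        normed = apply_normalization(m, vec)
        rs = normed.marginals()[normed.mask]
        assert rs.std() / rs.mean() < 1e-6
        assert vec.converged

    def test_empty_row_flagged_missing(self):
        dense = np.ones((10, 10))
        dense[3, :] = 0
        dense[:, 3] = 0
        m = make_matrix(dense)
        vec = compute_normalization(m, "balanced")
        assert vec.missing[3]
        assert not vec.missing[[0, 1, 2, 4]].any()

    def test_all_zero_matrix_warns(self, bins20):
        m = ContactMatrix.from_dense(bins20, np.zeros((20, 20)))
        with pytest.warns(UserWarning):
            vec = compute_normalization(m, "VC")
        assert vec.missing.all()

    def test_unknown_method(self, bins20):
        m = ContactMatrix.from_dense(bins20, np.ones((20, 20)))
        with pytest.raises(ValueError):
            compute_normalization(m, "KR")


class TestApplyNormalization:
    def test_identity_weights(self):
        m = make_matrix(np.ones((5, 5)))
        from hicarch.matrix_core import NormalizationVector

        vec = NormalizationVector(np.ones(5), "VC")
        out = apply_normalization(m, vec)
        assert np.allclose(out.to_dense(), m.to_dense())

    def test_double_weights_quadruple_values(self):
        m = make_matrix(np.ones((5, 5)))
        from hicarch.matrix_core import NormalizationVector

        vec = NormalizationVector(np.full(5, 2.0), "VC")
        out = apply_normalization(m, vec)
        assert np.allclose(out.to_dense(), 4 * m.to_dense())

    def test_missing_weight_drops_entries(self):
        m = make_matrix(np.ones((5, 5)))
        from hicarch.matrix_core import NormalizationVector

        w = np.ones(5)
        w[2] = np.nan
        out = apply_normalization(m, NormalizationVector(w, "VC"))
        dense = out.to_dense()
        assert dense[2].sum() == 0 and dense[:, 2].sum() == 0
        assert not out.mask[2]

    def test_bin_table_mismatch(self):
        from hicarch.matrix_core import NormalizationVector

        m = make_matrix(np.ones((5, 5)))
        with pytest.raises(ValueError):
            apply_normalization(m, NormalizationVector(np.ones(7), "VC"))


class TestExpectedProfile:
    def test_constant_per_diagonal(self):
        n = 30
        idx = np.arange(n)
        dense = 100.0 / (1 + np.abs(idx[:, None] - idx[None, :]))
        m = make_matrix(dense)
        prof = expected_by_distance(m)
        assert np.allclose(prof.expected_value, 100.0 / (1 + np.arange(n)))

    def test_single_entry(self, bins20):
        dense = np.zeros((20, 20))
        dense[2, 7] = dense[7, 2] = 4.0
        m = ContactMatrix.from_dense(bins20, dense)
        prof = expected_by_distance(m)
        nonzero = np.nonzero(prof.expected_value)[0]
        assert list(nonzero) == [5]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for n in (17, 60, 150):
            dense = random_symmetric(n, rng)
            m = make_matrix(dense)
            prof = expected_by_distance(m)
            oracle = expected_by_distance_oracle(dense)
            assert np.allclose(prof.expected_value, oracle, rtol=1e-12)

    def test_masked_bins_excluded(self):
        dense = np.ones((10, 10))
        m = make_matrix(dense)
        m.mask[4] = False
        prof = expected_by_distance(m)
        # still 1.0 everywhere defined: zero-pairs only among valid bins
        assert np.allclose(prof.expected_value[:6], 1.0)


class TestObservedOverExpected:
    def test_self_expected_gives_ones(self):
        n = 25
        idx = np.arange(n)
        dense = 50.0 / (1 + np.abs(idx[:, None] - idx[None, :]))
        m = make_matrix(dense)
        oe = observed_over_expected(m, expected_by_distance(m))
        assert np.allclose(oe.to_dense(), np.ones((n, n)))

    def test_simple_division(self, bins20):
        dense = np.zeros((20, 20))
        dense[1, 4] = dense[4, 1] = 6.0
        m = ContactMatrix.from_dense(bins20, dense)
        prof = expected_by_distance(m)
        oe = observed_over_expected(m, prof)
        expected_at_3 = 6.0 / 17  # one nonzero among 17 pairs at separation 3
        assert np.isclose(oe.to_dense()[1, 4], 6.0 / expected_at_3)

    def test_symmetry_and_nonnegativity_preserved(self):
        rng = np.random.default_rng(3)
        dense = random_symmetric(40, rng)
        m = make_matrix(dense)
        oe = observed_over_expected(m, expected_by_distance(m))
        d = oe.to_dense()
        assert np.allclose(d, d.T)
        assert (d >= 0).all()
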