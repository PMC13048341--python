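import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svdkit.errors import MetricError, RankError
from svdkit.metrics import (
    align_signs,
    ccc,
    compare_decompositions,
    frobenius_error,
    reconstruct,
    sse_ratio,
)
from svdkit.svd import SVDResult, exact_svd, randomized_svd, truncate_svd
from svdkit.synthetic import make_lowrank


class TestReconstruct:
    def test_full_svd_reconstructs_input(self, rng):
        m = rng.standard_normal((7, 4))
        r = exact_svd(m)
        assert np.linalg.norm(m - reconstruct(r)) < 1e-10 * np.linalg.norm(m)

    def test_rank_zero_request_errors(self, rng):
        r = exact_svd(rng.standard_normal((5, 3)))
        with pytest.raises(RankError):
            reconstruct(r, 0)

    def test_truncation_error_is_tail_energy(self, rng):
        """Eckart-Young identity: rank-k error equals sqrt of the tail
        singular-value energy."""
        m = rng.standard_normal((10, 6))
        full = exact_svd(m)
        for k in (1, 3, 5):
            err = np.linalg.norm(m - reconstruct(full, k))
            expected = np.sqrt(np.sum(full.S[k:] ** 2))
            np.testing.assert_allclose(err, expected, rtol=1e-8)


class TestSSERatio:
    def test_truncated_reference_gives_exactly_one(self, rng):
        m = rng.standard_normal((12, 8))
        ref = exact_svd(m)
        cand = truncate_svd(ref, 4)
        assert sse_ratio(cand, ref, m, 4) == 1.0

    def test_nonoptimal_basis_exceeds_one(self, rng):
        """Any rank-k approximation other than the exact truncation has
        strictly larger SSE (Eckart-Young optimality)."""
        truth = make_lowrank(30, 20, [5, 4, 3, 2, 1], noise_sd=0.2, seed=0)
        m = truth.matrix
        ref = exact_svd(m)
        k = 3
        q, _ = np.linalg.qr(rng.standard_normal((30, k)))
        b = q.T @ m
        ub, s, vt = np.linalg.svd(b, full_matrices=False)
        cand = SVDResult(U=q @ ub, S=s, Vt=vt, k=k, method="randomized")
        assert sse_ratio(cand, ref, m, k) > 1

    def test_randomized_candidate_is_near_optimal(self):
        truth = make_lowrank(60, 40, [10, 5, 2, 1], noise_sd=0.05, seed=3)
        ref = exact_svd(truth.matrix)
        cand = randomized_svd(truth.matrix, k=4, seed=3)
        ratio = sse_ratio(cand, ref, truth.matrix, 4)
        assert 1 - 1e-8 <= ratio < 1.05

    def test_rank_deficient_reference_errors(self):
        truth = make_lowrank(10, 6, [3.0, 2.0], noise_sd=0.0, seed=0)
        ref = exact_svd(truth.matrix)
        cand = truncate_svd(ref, 2)
        with pytest.raises(MetricError, match="reference SSE is zero"):
            sse_ratio(cand, ref, truth.matrix, 2)

    def test_shape_mismatch_errors(self, rng):
        m = rng.standard_normal((10, 5))
        ref = exact_svd(m)
        with pytest.raises(MetricError, match="shape mismatch"):
            sse_ratio(ref, ref, rng.standard_normal((8, 5)), 2)

    def test_non_exact_reference_rejected(self, rng):
        m = rng.standard_normal((10, 5))
        rand = randomized_svd(m, k=3, oversample=2, seed=0)
        with pytest.raises(MetricError, match="exact"):
            sse_ratio(rand, rand, m, 2)


class TestFrobeniusError:
    def test_full_exact_is_machine_precision(self, rng):
        m = rng.standard_normal((9, 6))
        absolute, relative = frobenius_error(m, exact_svd(m))
        assert absolute < 1e-10 * np.linalg.norm(m)
        assert relative < 1e-10

    def test_zero_matrix(self):
        m = np.zeros((4, 3))
        assert frobenius_error(m, exact_svd(m)) == (0.0, 0.0)

    def test_truncation_error_matches_known_spectrum(self):
        truth = make_lowrank(20, 10, [8, 4, 2, 1], noise_sd=0.0, seed=2)
        r = exact_svd(truth.matrix)
        absolute, _ = frobenius_error(truth.matrix, r, k=2)
        np.testing.assert_allclose(absolute, np.sqrt(2**2 + 1**2), rtol=1e-8)

    def test_centered_ss_divisor(self, rng):
        m = rng.standard_normal((15, 5)) + 3.0
        r = exact_svd(m, k=2)
        absolute, relative = frobenius_error(m, r, divisor="centered_ss")
        expected = absolute / np.sqrt(np.sum((m - m.mean(axis=0)) ** 2))
        np.testing.assert_allclose(relative, expected)


class TestCCC:
    def test_perfect_agreement(self):
        assert ccc([1, 2, 3], [1, 2, 3]) == 1.0

    def test_perfect_reversal(self):
        # equal means, s_xy = -s_x^2 -> exactly -1
        assert abs(ccc([1, 2, 3], [3, 2, 1]) - (-1.0)) < 1e-12

    def test_unit_shift(self):
        # s_xy = s_x^2 = s_y^2 = 2/3, mean shift 1 -> 2*(2/3)/(2/3+2/3+1)
        assert abs(ccc([1, 2, 3], [2, 3, 4]) - 4 / 7) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(MetricError, match="length mismatch"):
            ccc([1, 2], [1, 2, 3])

    def test_undefined_for_equal_constants(self):
        with pytest.raises(MetricError, match="CCC undefined"):
            ccc([2, 2, 2], [2, 2, 2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_by_pearson(self, seed):
        """|CCC| <= |Pearson r|: agreement is penalized by location/scale
        shift on top of decorrelation."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        rho_c = ccc(x, y)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(rho_c) <= abs(pearson) + 1e-12
        assert ccc(x.tolist(), x.tolist()) == 1.0
        if not np.isclose(np.mean(y - x), 0):
            assert ccc(x, x + np.mean(y - x)) < 1.0


class TestAlignSigns:
    def test_identity_when_already_aligned(self, rng):
        r = exact_svd(rng.standard_normal((10, 6)), k=4)
        aligned = align_signs(r, r)
        np.testing.assert_array_equal(aligned.U, r.U)
        np.testing.assert_array_equal(aligned.Vt, r.Vt)

    def test_undoes_full_negation(self, rng):
        from dataclasses import replace

        r = exact_svd(rng.standard_normal((10, 6)), k=4)
        flipped = replace(r, U=-r.U, Vt=-r.Vt)
        aligned = align_signs(flipped, r)
        np.testing.assert_array_equal(aligned.U, r.U)
        np.testing.assert_array_equal(aligned.Vt, r.Vt)

    def test_undoes_random_per_column_flips(self, rng):
        from dataclasses import replace

        r = exact_svd(rng.standard_normal((16, 9)), k=6)
        signs = rng.choice([-1.0, 1.0], size=6)
        flipped = replace(r, U=r.U * signs, Vt=r.Vt * signs[:, None])
        aligned = align_signs(flipped, r)
        assert (np.einsum("ij,ij->j", aligned.U, r.U) > 0).all()
        np.testing.assert_array_equal(aligned.U, r.U)

    def test_idempotent(self, rng):
        a = exact_svd(rng.standard_normal((12, 7)), k=5)
        b = randomized_svd(rng.standard_normal((12, 7)), k=5, oversample=2, seed=0)
        once = align_signs(b, a)
        twice = align_signs(once, a)
        np.testing.assert_array_equal(once.U, twice.U)
        np.testing.assert_array_equal(once.Vt, twice.Vt)

    def test_shape_mismatch(self, rng):
        a = exact_svd(rng.standard_normal((10, 6)), k=3)
        b = exact_svd(rng.standard_normal((10, 6)), k=4)
        with pytest.raises(MetricError, match="shape mismatch"):
            align_signs(a, b)


class TestCompareDecompositions:
    def test_truncated_reference_is_perfect(self, rng):
        m = rng.standard_normal((20, 12))
        ref = exact_svd(m)
        report = compare_decompositions(truncate_svd(ref, 5), ref, m, k=5)
        assert report.sse_ratio == 1.0
        assert report.ccc_singular_values == 1.0
        assert all(v == 1.0 for v in report.ccc_pc.values())

    def test_randomized_candidate_report(self):
        truth = make_lowrank(80, 40, [20, 10, 5, 2, 1], noise_sd=0.05, seed=6)
        m = truth.matrix
        ref = exact_svd(m)
        cand = randomized_svd(m, k=5, seed=6)
        report = compare_decompositions(cand, ref, m, k=5, n_pcs_to_compare=2)
        assert 1 - 1e-8 <= report.sse_ratio < 1.05
        assert report.ccc_singular_values > 0.999
        assert report.ccc_pc[1] > 0.999 and report.ccc_pc[2] > 0.999
        assert report.k == 5

    def test_report_serialization(self, tmp_path, rng):
        m = rng.standard_normal((15, 8))
        ref = exact_svd(m)
        report = compare_decompositions(truncate_svd(ref, 3), ref, m, k=3)
        report.save(tmp_path)
        tsv = (tmp_path / "metrics.tsv").read_text()
        assert "sse_ratio\t1.000000" in tsv
        assert "ccc_singular_values\t1.0000" in tsv
        assert (tmp_path / "metrics.json").exists()
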