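"""Gene alignment/variance filtering, TF-IDF, row MinMax and the Gaussian
perturbation model, each checked against direct brute-force computation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conformix import (BulkDataset, align_and_filter_genes, minmax_rows,
                       perturb, tfidf)


def _bulk(expr, genes=None, fractions=None):
    expr = np.asarray(expr, dtype=float)
    if genes is None:
        genes = [f"g{j}" for j in range(expr.shape[1])]
    return BulkDataset(expression=expr, fractions=fractions, subject_id="b",
                       gene_ids=np.asarray(genes, dtype=object))


class TestAlignAndFilter:
    def test_intersection_of_gene_sets(self):
        train = _bulk(np.random.default_rng(0).poisson(5, (6, 3)), ["A", "B", "C"])
        test = _bulk(np.random.default_rng(1).poisson(5, (4, 3)), ["B", "C", "D"])
        spec = align_and_filter_genes(train, test, variance_threshold=0.0)
        assert set(spec.retained_genes) <= {"B", "C"}

    def test_constant_gene_excluded(self):
        expr = np.column_stack([np.full(5, 7.0), np.arange(5, dtype=float)])
        spec = align_and_filter_genes(_bulk(expr), variance_threshold=0.1)
        assert list(spec.retained_genes) == ["g1"]

    def test_variance_is_population_variance_on_raw_matrix(self):
        col = np.array([0.0, 0.0, 0.0, 10.0])
        expr = np.column_stack([col, 100.0 * np.arange(4, dtype=float)])
        brute = sum((x - col.mean()) ** 2 for x in col) / len(col)
        spec = align_and_filter_genes(_bulk(expr), variance_threshold=brute + 1e-9)
        assert "g0" not in set(spec.retained_genes)
        spec = align_and_filter_genes(_bulk(expr), variance_threshold=brute - 1e-9)
        assert "g0" in set(spec.retained_genes)

    def test_training_order_kept(self):
        rng = np.random.default_rng(2)
        train = _bulk(rng.poisson(5, (6, 4)), ["D", "B", "A", "C"])
        test = _bulk(rng.poisson(5, (4, 4)), ["A", "B", "C", "D"])
        spec = align_and_filter_genes(train, test, variance_threshold=0.0)
        assert list(spec.retained_genes) == ["D", "B", "A", "C"]

    def test_empty_intersection_raises(self):
        train = _bulk(np.ones((3, 2)) + np.eye(3)[:, :2], ["A", "B"])
        test = _bulk(np.ones((3, 2)), ["C", "D"])
        with pytest.raises(ValueError):
            align_and_filter_genes(train, test)


class TestTfidf:
    def test_tf_is_row_normalization(self):
        X = np.array([[2.0, 3.0, 5.0]])
        out = tfidf(X)
        idf = np.log(1.0 / (X.sum(axis=0) + 1.0))
        np.testing.assert_allclose(out, np.array([[0.2, 0.3, 0.5]]) * idf)

    def test_column_with_total_t_minus_one_zeroes_out(self):
        # column sum T - 1 -> IDF = log(T/T) = 0
        X = np.array([[1.0, 5.0], [1.0, 5.0], [0.0, 5.0]])
        out = tfidf(X)
        np.testing.assert_allclose(out[:, 0], 0.0, atol=1e-15)

    def test_matches_per_entry_brute_force(self):
        X = np.array([[1.0, 1.0], [1.0, 3.0], [2.0, 0.5]])
        T = X.shape[0]
        expected = np.empty_like(X)
        for i in range(T):
            for j in range(X.shape[1]):
                tf = X[i, j] / X[i].sum()
                idf = math.log(T / (X[:, j].sum() + 1.0))
                expected[i, j] = tf * idf
        np.testing.assert_allclose(tfidf(X), expected, rtol=1e-12)

    def test_zero_sum_row_rejected(self):
        with pytest.raises(ValueError):
            tfidf(np.array([[1.0, 2.0], [0.0, 0.0]]))

    @given(st.integers(2, 8), st.integers(1, 6), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_tf_rows_sum_to_one_before_idf(self, n, g, seed):
        rng = np.random.default_rng(seed)
        X = rng.poisson(3.0, (n, g)) + 1.0  # +1 guarantees positive rows
        tf = X / X.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(tf.sum(axis=1), 1.0, rtol=1e-12)
        out = tfidf(X)
        idf = np.log(n / (X.sum(axis=0) + 1.0))
        np.testing.assert_allclose(out, tf * idf, rtol=1e-12)


class TestMinmaxRows:
    def test_simple_row(self):
        np.testing.assert_allclose(minmax_rows(np.array([[1.0, 2.0, 3.0]])),
                                   [[0.0, 0.5, 1.0]])

    def test_identity_when_already_unit_range(self):
        X = np.array([[0.0, 0.25, 1.0], [1.0, 0.0, 0.5]])
        np.testing.assert_allclose(minmax_rows(X), X)

    def test_constant_row_maps_to_zeros(self):
        out = minmax_rows(np.array([[5.0, 5.0, 5.0], [1.0, 3.0, 2.0]]))
        np.testing.assert_allclose(out[0], 0.0)

    @given(st.integers(1, 6), st.integers(2, 8), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_range_and_extremes(self, n, g, seed):
        X = np.random.default_rng(seed).normal(size=(n, g))
        out = minmax_rows(X)
        assert (out >= 0).all() and (out <= 1).all()
        for i in range(n):
            if X[i].max() > X[i].min():
                assert out[i].min() == 0.0 and out[i].max() == 1.0


class TestPerturb:
    def test_lambda_zero_is_identity(self, rng):
        X = np.abs(np.random.default_rng(0).normal(5, 2, (4, 6)))
        np.testing.assert_array_equal(perturb(X, 0.0, rng), X)

    def test_nonnegative_and_zeros_fixed(self, rng):
        X = np.random.default_rng(1).poisson(2.0, (20, 30)).astype(float)
        out = perturb(X, 0.5, rng)
        assert (out >= 0).all()
        np.testing.assert_array_equal(out[X == 0], 0.0)

    def test_noise_variance_is_lambda_times_expression(self):
        # var of noise on an entry of 100 at lam=0.01 is 1.0; clamping is
        # negligible at this signal level
        rng = np.random.default_rng(12345)
        X = np.full((100_000, 1), 100.0)
        out = perturb(X, 0.01, rng)
        assert abs(out.var() - 1.0) < 0.1
        assert abs(out.mean() - 100.0) < 0.05

    def test_deterministic_given_rng_state(self):
        X = np.random.default_rng(3).poisson(5.0, (5, 5)).astype(float)
        a = perturb(X, 0.1, np.random.default_rng(77))
        b = perturb(X, 0.1, np.random.default_rng(77))
        np.testing.assert_array_equal(a, b)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb(np.ones((2, 2)), -0.1, rng)
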