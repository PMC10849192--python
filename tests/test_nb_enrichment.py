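import numpy as np
import pytest
from scipy import optimize, stats

from doublechec.nb_enrichment import (
    CountMatrix,
    NbTestConfig,
    benjamini_hochberg,
    estimate_dispersion,
    size_factors,
    wald_test,
)


def matrix_from(rows, n_tf=None, conditions=None):
    rows = np.atleast_2d(np.asarray(rows))
    if conditions is None:
        conditions = ("tf",) * n_tf + ("control",) * (rows.shape[1] - n_tf)
    return CountMatrix([("chrI", i) for i in range(rows.shape[0])], rows, conditions)


def nb_rvs(rng, mu, alpha, size):
    if alpha <= 0:
        return rng.poisson(mu, size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size)


class TestCountMatrix:
    def test_requires_both_conditions(self):
        with pytest.raises(ValueError, match="control"):
            matrix_from([[1, 2]], conditions=("tf", "tf"))

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            matrix_from([[-1, 2]], n_tf=1)

    def test_rejects_duplicate_row_ids(self):
        with pytest.raises(ValueError):
            CountMatrix([("c", 1), ("c", 1)], [[1, 1], [2, 2]], ("tf", "control"))


class TestSizeFactors:
    def test_identical_columns_get_equal_factors(self):
        m = matrix_from([[10, 10], [3, 3], [7, 7]], n_tf=1)
        np.testing.assert_allclose(size_factors(m), [1.0, 1.0])

    def test_doubled_column(self):
        m = matrix_from([[10, 20], [3, 6], [7, 14]], n_tf=1)
        f = size_factors(m)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_hand_oracle_median_of_ratios(self):
        # rows [[10,20],[30,60],[5,10]]: geometric means sqrt(200), sqrt(1800),
        # sqrt(50); all ratios are (1/sqrt2, sqrt2) -> factors prop. (1, 2)
        m = matrix_from([[10, 20], [30, 60], [5, 10]], n_tf=1)
        f = size_factors(m)
        assert f[1] / f[0] == pytest.approx(2.0)
        np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            size_factors(matrix_from([[0, 0]], n_tf=1))

    def test_fallback_to_library_size_with_warning(self):
        m = matrix_from([[4, 0], [0, 8]], n_tf=1)
        with pytest.warns(UserWarning, match="library-size"):
            f = size_factors(m)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_integer_scaling_property(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, (200, 4)) + 1
        m = matrix_from(counts, n_tf=2)
        scaled = counts.copy()
        scaled[:, 0] *= 3
        m3 = matrix_from(scaled, n_tf=2)
        f, f3 = size_factors(m), size_factors(m3)
        assert f3[0] / f[0] == pytest.approx(3.0 * (f3[1] / f[1]))


class TestEstimateDispersion:
    def test_poisson_rows_near_floor(self):
        rng = np.random.default_rng(1)
        mus = np.exp(rng.normal(np.log(200), 0.5, 1000))
        counts = np.stack([rng.poisson(m, 6) for m in mus])
        m = matrix_from(counts, n_tf=3)
        d = estimate_dispersion(m, np.ones(6))
        assert d.mean() < 0.05

    def test_nb_rows_recover_dispersion(self):
        rng = np.random.default_rng(2)
        mus = np.exp(rng.normal(np.log(200), 0.5, 2000))
        counts = np.stack([nb_rvs(rng, m, 0.2, 6) for m in mus])
        m = matrix_from(counts, n_tf=3)
        d = estimate_dispersion(m, np.ones(6))
        assert 0.1 <= np.median(d) <= 0.4

    def test_zero_variance_row_hits_floor(self):
        counts = np.vstack([[[5, 5, 5, 2, 2, 2]], np.random.default_rng(3).poisson(50, (50, 6))])
        m = matrix_from(counts, n_tf=3)
        d = estimate_dispersion(m, np.ones(6))
        assert d[0] == pytest.approx(1e-8)

    def test_no_replication_errors(self):
        m = matrix_from([[5, 2]], n_tf=1)
        with pytest.raises(ValueError, match="replication"):
            estimate_dispersion(m, np.ones(2))


def exact_nb_lrt(tf_counts, control_counts, alpha):
    """Oracle: exact NB likelihood-ratio test at fixed dispersion alpha."""
    y = np.concatenate([tf_counts, control_counts])
    r = 1.0 / alpha

    def nll(mu, data):
        return -stats.nbinom.logpmf(data, r, r / (r + mu)).sum()

    def fit(data):
        res = optimize.minimize_scalar(
            lambda lm: nll(np.exp(lm), data),
            bounds=(np.log(1e-3), np.log(1e6)),
            method="bounded",
        )
        return -nll(np.exp(res.x), data)

    ll_alt = fit(np.asarray(tf_counts)) + fit(np.asarray(control_counts))
    ll_null = fit(y)
    stat = 2.0 * (ll_alt - ll_null)
    return stats.chi2.sf(stat, df=1)


class TestWaldTest:
    def test_null_row_not_retained(self):
        m = matrix_from([[20, 21, 19, 20, 21, 19]], n_tf=3)
        (res,) = wald_test(m, np.ones(6), np.array([0.01]))
        assert abs(res.log2_fold_change) < 0.1
        assert not res.retained

    def test_strong_enrichment_retained_and_matches_lrt_oracle(self):
        tf, ctrl = [400, 420, 390], [10, 12, 9]
        m = matrix_from([tf + ctrl], n_tf=3)
        d = estimate_dispersion(m, np.ones(6))
        (res,) = wald_test(m, np.ones(6), d)
        # log2(403.33 / 10.33) = 5.29
        assert res.log2_fold_change == pytest.approx(5.29, abs=0.05)
        assert res.retained
        assert res.p_value < 1e-4
        # independent exact-likelihood oracle at the same dispersion
        assert exact_nb_lrt(tf, ctrl, float(d[0])) < 1e-4

    def test_sub_threshold_fold_change_not_retained(self):
        # log2(30.33/10) = 1.60 < 1.7 regardless of p
        m = matrix_from([[30, 28, 33, 10, 11, 9]], n_tf=3)
        (res,) = wald_test(m, np.ones(6), np.array([1e-8]))
        assert res.log2_fold_change == pytest.approx(1.60, abs=0.05)
        assert not res.retained

    def test_zero_control_row_is_finite_and_retained(self):
        m = matrix_from([[300, 310, 305, 0, 0, 0], [5, 6, 5, 5, 6, 5]], n_tf=3)
        res = wald_test(m, np.ones(6), np.array([0.05, 0.05]))
        assert np.isfinite(res[0].log2_fold_change)
        assert res[0].retained
        assert not res[1].retained

    def test_label_swap_negates_lfc(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson([50, 55, 45, 20, 22, 18], (30, 6))
        m = matrix_from(counts, n_tf=3)
        m_swapped = CountMatrix(
            m.row_ids, counts, ("control",) * 3 + ("tf",) * 3
        )
        d = np.full(30, 0.05)
        res = wald_test(m, np.ones(6), d)
        res_sw = wald_test(m_swapped, np.ones(6), d)
        for a, b in zip(res, res_sw):
            assert a.log2_fold_change == pytest.approx(-b.log2_fold_change, abs=1e-6)

    def test_scaling_one_sample_scales_factor_and_keeps_lfc_stable(self):
        # size factors absorb an integer rescaling exactly; the GLM fold
        # change is invariant only up to the scale-dependent IRLS weights
        rng = np.random.default_rng(5)
        counts = rng.poisson(40, (50, 6)) + 1
        m = matrix_from(counts, n_tf=3)
        scaled = counts.copy()
        scaled[:, 0] *= 4
        m4 = matrix_from(scaled, n_tf=3)
        f, f4 = size_factors(m), size_factors(m4)
        assert f4[0] / f[0] == pytest.approx(4.0 * (f4[1] / f[1]), rel=1e-9)
        d = np.full(50, 0.05)
        res = wald_test(m, f, d)
        res4 = wald_test(m4, f4, d)
        for a, b in zip(res, res4):
            assert a.log2_fold_change == pytest.approx(b.log2_fold_change, abs=0.1)
        # scaling *all* samples together is tighter still (weights shift
        # uniformly); the NB weight function is never exactly scale-free
        m_all = matrix_from(counts * 3, n_tf=3)
        res_all = wald_test(m_all, size_factors(m_all), d)
        for a, b in zip(res, res_all):
            assert a.log2_fold_change == pytest.approx(b.log2_fold_change, abs=0.01)

    def test_adjusted_p_at_least_p(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(30, (100, 6))
        m = matrix_from(counts, n_tf=3)
        res = wald_test(m, np.ones(6), np.full(100, 0.1))
        assert all(r.adjusted_p >= r.p_value - 1e-15 for r in res)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_is_excluded(self):
        out = benjamini_hochberg([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        # ranking over the 2 non-NaN values only
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.02])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([1.5])
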