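import math

import numpy as np
import pytest
import scipy.optimize
import scipy.special
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from umires.count_model import (
    POISSON,
    CountMatrix,
    deviance_residuals,
    fit_null,
    nb_logpmf,
    nb_loglik,
    offset_intercepts,
    pearson_residuals,
    poisson_loglik,
    residual_variance,
    sequencing_depths,
)

count_matrices = arrays(
    np.int64, st.tuples(st.integers(2, 4), st.integers(2, 4)), elements=st.integers(0, 5)
).filter(lambda a: a.sum() > 0)


class TestCountMatrix:
    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="negative"):
            CountMatrix.from_dense([[1, -1], [0, 2]])

    def test_rejects_non_integral(self):
        with pytest.raises(ValueError, match="non-integral"):
            CountMatrix.from_dense([[1.5, 0], [0, 2]])

    def test_rejects_mismatched_ids(self):
        with pytest.raises(ValueError):
            CountMatrix.from_dense([[1, 2]], cell_ids=["a", "b"])


class TestSequencingDepths:
    def test_row_sums(self, toy):
        assert sequencing_depths(toy).tolist() == [3, 7]

    def test_all_zeros(self):
        X = CountMatrix.from_dense(np.zeros((2, 3), dtype=int))
        assert sequencing_depths(X).tolist() == [0, 0]

    def test_sparse_row(self):
        X = CountMatrix.from_dense([[0, 5], [0, 0]])
        assert sequencing_depths(X).tolist() == [5, 0]


class TestFitNull:
    def test_uniform_matrix(self):
        X = CountMatrix.from_dense([[1, 1], [1, 1]])
        assert np.allclose(fit_null(X).mu_dense(), 1.0)

    def test_derived_mu(self, toy):
        # row.col/total evaluated by hand: [[3*4,3*6],[7*4,7*6]]/10
        expected = np.array([[1.2, 1.8], [2.8, 4.2]])
        assert np.allclose(fit_null(toy).mu_dense(), expected)

    def test_rank_one_reproduced(self):
        a, b = np.array([2, 3, 5]), np.array([1, 4])
        X = CountMatrix.from_dense(np.outer(a, b))
        assert np.allclose(fit_null(X).mu_dense(), np.outer(a, b))

    def test_all_zero_error(self):
        X = CountMatrix.from_dense(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="all-zero"):
            fit_null(X)

    def test_bad_theta(self, toy):
        with pytest.raises(ValueError, match="theta"):
            fit_null(toy, theta=-1.0)

    def test_fractions_sum_to_one(self, toy):
        assert abs(fit_null(toy).fractions.sum() - 1.0) < 1e-12

    @given(count_matrices)
    @settings(max_examples=50, deadline=None)
    def test_margin_preservation(self, counts):
        X = CountMatrix.from_dense(counts)
        mu = fit_null(X).mu_dense()
        assert np.allclose(mu.sum(axis=1), counts.sum(axis=1), atol=1e-9)
        assert np.allclose(mu.sum(axis=0), counts.sum(axis=0), atol=1e-9)


class TestPearsonResiduals:
    def test_rank_one_is_zero(self):
        X = CountMatrix.from_dense(np.outer([1, 2, 3], [2, 5]))
        assert np.allclose(pearson_residuals(X, clip=None).values, 0.0)

    def test_derived_entry(self, toy):
        z = pearson_residuals(toy, theta=POISSON, clip=None).values
        assert z[0, 0] == pytest.approx((1 - 1.2) / math.sqrt(1.2), abs=1e-12)

    def test_null_variance_near_one(self, null_sim):
        res = pearson_residuals(null_sim, theta=POISSON, clip=None)
        variances = res.gene_variance()
        mean = np.asarray(null_sim.counts.mean(axis=0)).ravel()
        med = np.median(variances[mean >= 0.1])
        assert 0.9 < med < 1.1

    def test_clip_bound_exact(self, rng):
        counts = rng.poisson(1.0, (30, 10))
        counts[0, 0] = 500  # force a large residual
        X = CountMatrix.from_dense(counts)
        z = pearson_residuals(X, clip="sqrt_n").values
        assert np.max(np.abs(z)) <= math.sqrt(30)

    def test_zero_gene_residual_zero_and_flagged(self):
        X = CountMatrix.from_dense([[1, 0], [2, 0]])
        res = pearson_residuals(X)
        assert np.all(res.values[:, 1] == 0)
        assert res.zero_genes.tolist() == [False, True]

    def test_nb_magnitude_below_poisson_and_monotone(self, rng):
        X = CountMatrix.from_dense(rng.poisson(3.0, (10, 6)) + 1)
        zp = np.abs(pearson_residuals(X, theta=POISSON, clip=None).values)
        prev = np.abs(pearson_residuals(X, theta=1.0, clip=None).values)
        for theta in (10.0, 100.0, 1e4):
            cur = np.abs(pearson_residuals(X, theta=theta, clip=None).values)
            assert np.all(cur >= prev - 1e-12)
            assert np.all(cur <= zp + 1e-12)
            prev = cur

    def test_two_fold_change_coefficient(self):
        # gene at mu in half the cells and 2*mu in the other half, equal depths:
        # residual -> +/- 0.5*mu/sqrt(1.5*mu) = 0.408*sqrt(mu) in the Poisson limit
        mu = 400
        depth = 10000
        half = 50
        gene = np.r_[np.full(half, mu), np.full(half, 2 * mu)]
        counts = np.c_[depth - gene, gene]
        X = CountMatrix.from_dense(counts)
        z = pearson_residuals(X, theta=POISSON, clip=None).values[:, 1]
        coef = 0.5 / math.sqrt(1.5)
        assert z[0] == pytest.approx(-coef * math.sqrt(mu), rel=1e-2)
        assert z[-1] == pytest.approx(coef * math.sqrt(mu), rel=1e-2)


class TestDevianceResiduals:
    def test_rank_one_is_zero(self):
        X = CountMatrix.from_dense(np.outer([1, 2], [3, 4]))
        assert np.allclose(deviance_residuals(X).values, 0.0)

    def test_zero_count_convention(self):
        # x=0 against expectation m gives -sqrt(2m)
        X = CountMatrix.from_dense([[0, 4], [4, 4]])
        mu = fit_null(X).mu_dense()
        z = deviance_residuals(X, theta=POISSON).values
        assert z[0, 0] == pytest.approx(-math.sqrt(2 * mu[0, 0]), abs=1e-12)

    def test_nb_limit_matches_poisson(self, toy):
        zp = deviance_residuals(toy, theta=POISSON).values
        znb = deviance_residuals(toy, theta=1e8).values
        assert np.allclose(znb, zp, rtol=1e-3)

    def test_deviance_identity(self, rng):
        # sum of squared residuals equals 2*(saturated - model loglik)
        counts = rng.poisson(4.0, (12, 7)) + 1
        X = CountMatrix.from_dense(counts)
        mu = fit_null(X).mu_dense()
        z = deviance_residuals(X, theta=POISSON).values
        oracle = 2.0 * (
            scipy.stats.poisson.logpmf(counts, counts)
            - scipy.stats.poisson.logpmf(counts, mu)
        ).sum()
        assert np.sum(z**2) == pytest.approx(oracle, rel=1e-10)


class TestOffsetIntercepts:
    def test_uniform(self):
        X = CountMatrix.from_dense(np.ones((2, 4), dtype=int))
        assert np.allclose(offset_intercepts(X), math.log(0.25))

    def test_derived(self, toy):
        assert np.allclose(offset_intercepts(toy), np.log([0.4, 0.6]))

    def test_straight_line_in_log_mean(self, rng):
        X = CountMatrix.from_dense(rng.poisson(3.0, (20, 8)) + 1)
        beta0 = offset_intercepts(X)
        mean_expr = np.asarray(X.counts.mean(axis=0)).ravel()
        mean_depth = sequencing_depths(X).mean()
        assert np.allclose(beta0, np.log(mean_expr) - math.log(mean_depth))

    def test_zero_gene_flagged(self):
        X = CountMatrix.from_dense([[1, 0], [2, 0]])
        beta0 = offset_intercepts(X)
        assert np.isneginf(beta0[1])

    def test_zero_depth_error(self):
        X = CountMatrix.from_dense([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="cell0"):
            offset_intercepts(X)


def _numeric_poisson_mle(counts: np.ndarray) -> float:
    """Brute-force maximizer of the rank-one Poisson log-likelihood."""
    X = CountMatrix.from_dense(counts)
    n_cells, n_genes = counts.shape

    def neg(params):
        depths = np.exp(params[:n_cells])
        frac = scipy.special.softmax(params[n_cells:])
        return -poisson_loglik(X, depths, frac)

    x0 = np.r_[np.log(counts.sum(axis=1) + 0.5), np.zeros(n_genes)]
    best = math.inf
    for shift in (0.0, 0.3):
        res = scipy.optimize.minimize(
            neg, x0 + shift, method="BFGS", options={"gtol": 1e-12, "maxiter": 5000}
        )
        best = min(best, res.fun)
    return -best


class TestPoissonLoglik:
    def test_single_entry(self):
        X = CountMatrix.from_dense([[1]])
        assert poisson_loglik(X, [1.0], [1.0]) == pytest.approx(-1.0)

    def test_analytic_beats_perturbation(self, rng):
        counts = rng.poisson(3.0, (4, 4)) + 1
        X = CountMatrix.from_dense(counts)
        fit = fit_null(X)
        best = poisson_loglik(X, fit.depths, fit.fractions)
        for _ in range(20):
            d = fit.depths * np.exp(rng.normal(0, 0.1, 4))
            p = fit.fractions * np.exp(rng.normal(0, 0.1, 4))
            p = p / p.sum()
            assert poisson_loglik(X, d, p) <= best + 1e-9

    def test_matches_numeric_optimizer(self, rng):
        checked = 0
        while checked < 5:
            counts = rng.integers(0, 6, (3, 3))
            if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
                continue
            X = CountMatrix.from_dense(counts)
            fit = fit_null(X)
            analytic = poisson_loglik(X, fit.depths, fit.fractions)
            numeric = _numeric_poisson_mle(counts)
            assert abs(analytic - numeric) < 1e-6
            checked += 1


class TestNbLoglik:
    def test_large_theta_argmax_near_poisson(self, rng):
        counts = rng.poisson(5.0, (3, 3)) + 1
        X = CountMatrix.from_dense(counts)
        fit = fit_null(X)

        def neg(logits):
            frac = scipy.special.softmax(logits)
            return -nb_loglik(X, fit.depths, frac, theta=1e8)

        res = scipy.optimize.minimize(neg, np.zeros(3), method="Nelder-Mead",
                                      options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 10000})
        frac_hat = scipy.special.softmax(res.x)
        assert np.allclose(frac_hat, fit.fractions, atol=1e-4)

    def test_density_normalizes(self):
        x = np.arange(0, 500)
        total = np.exp(nb_logpmf(x, 2.0, 5.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        counts = rng.poisson(4.0, (3, 4)) + 1
        X = CountMatrix.from_dense(counts)
        depths = rng.uniform(5, 15, 3)
        fractions = rng.dirichlet(np.ones(4))
        theta = 7.0
        eps = 1e-6

        def f(d, p):
            return nb_loglik(X, d, p, theta)

        xarr = X.to_dense()
        mu = np.outer(depths, fractions)
        # analytic gradient of sum[x ln(np) - (x+theta) ln(np+theta)] w.r.t. depths
        grad_d = ((xarr / depths[:, None]) - (xarr + theta) * fractions[None, :] / (mu + theta)).sum(axis=1)
        for c in range(3):
            d2 = depths.copy()
            d2[c] += eps
            fd = (f(d2, fractions) - f(depths, fractions)) / eps
            assert fd == pytest.approx(grad_d[c], rel=1e-4)

    def test_theta_validation(self, toy):
        with pytest.raises(ValueError):
            nb_loglik(toy, [3, 7], [0.4, 0.6], theta=0.0)


class TestResidualVariance:
    def test_rank_one_zero(self):
        X = CountMatrix.from_dense(np.outer([1, 2, 3], [2, 4]))
        assert np.allclose(residual_variance(X), 0.0)

    @pytest.mark.parametrize("kind,theta,clip", [
        ("pearson", 100.0, "sqrt_n"),
        ("pearson", POISSON, None),
        ("deviance", POISSON, None),
        ("deviance", 50.0, None),
    ])
    def test_matches_dense_path(self, rng, kind, theta, clip):
        X = CountMatrix.from_dense(rng.poisson(2.0, (50, 20)))
        streamed = residual_variance(X, kind=kind, theta=theta, clip=clip)
        if kind == "pearson":
            dense = pearson_residuals(X, theta=theta, clip=clip)
        else:
            dense = deviance_residuals(X, theta=theta)
        assert np.allclose(streamed, dense.gene_variance(), atol=1e-12)

    def test_unknown_kind(self, toy):
        with pytest.raises(ValueError, match="kind"):
            residual_variance(toy, kind="anscombe")
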