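"""Unit and property tests for the conjugate NIG regression core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import modelspace as ms
from modelspace._exceptions import DataError

from oracles import nig_grid_moments


def worked_posterior() -> ms.NIGState:
    """Unit prior updated on the single observation x=[1], y=2."""
    prior = ms.NIGState([0.0], [[1.0]], 1.0, 1.0)
    return ms.nig_update(prior, ms.DesignBlock([[1.0]], [2.0]))


class TestMakeDesign:
    def test_row_length_is_L_plus_5(self, rng):
        X = ms.make_design(rng.standard_normal(14), rng.uniform(0, 3, (6, 4)))
        assert X.shape == (6, 19)

    def test_zero_inputs_leave_only_intercept(self):
        X = ms.make_design(np.zeros(3), np.zeros((2, 4)))
        assert np.array_equal(X, np.array([[0, 0, 0, 0, 0, 0, 0, 1.0]] * 2))

    def test_identical_dosage_rows_give_identical_design_rows(self, rng):
        b = rng.standard_normal(5)
        X = ms.make_design(b, np.tile([1.0, 0, 0, 0.5], (3, 1)))
        assert np.array_equal(X[0], X[1]) and np.array_equal(X[1], X[2])
        # baseline block constant within the subject by construction
        assert np.array_equal(X[:, :5], np.tile(b, (3, 1)))

    def test_nan_rejected(self):
        with pytest.raises(DataError):
            ms.make_design([np.nan], np.zeros((1, 4)))


class TestNigUpdate:
    def test_worked_example(self):
        post = worked_posterior()
        assert post.tau == pytest.approx([1.0])
        assert post.lambda_inv == pytest.approx(np.array([[0.5]]))
        assert post.alpha == pytest.approx(1.5)
        assert post.beta == pytest.approx(2.0)

    def test_empty_block_is_identity(self, default_prior):
        out = ms.nig_update(default_prior, ms.DesignBlock(np.empty((0, 19)), []))
        assert np.array_equal(out.tau, default_prior.tau)
        assert np.array_equal(out.lambda_inv, default_prior.lambda_inv)
        assert out.alpha == default_prior.alpha and out.beta == default_prior.beta

    @pytest.mark.parametrize("P", [2, 5])
    def test_sequential_equals_batch(self, rng, P):
        prior = ms.NIGState(rng.standard_normal(P), np.eye(P), 1.2, 0.8)
        X = rng.standard_normal((5, P))
        y = rng.standard_normal(5)
        batch = ms.nig_update(prior, ms.DesignBlock(X, y))
        seq = prior
        for i in range(5):
            seq = ms.nig_update(seq, ms.DesignBlock(X[i : i + 1], y[i : i + 1]))
        assert seq.tau == pytest.approx(batch.tau, abs=1e-10)
        assert seq.lambda_inv == pytest.approx(batch.lambda_inv, abs=1e-10)
        assert seq.alpha == pytest.approx(batch.alpha, abs=1e-12)
        assert seq.beta == pytest.approx(batch.beta, abs=1e-10)

    def test_row_order_invariance(self, rng):
        P = 4
        prior = ms.NIGState(np.zeros(P), np.eye(P), 1.0, 1.0)
        X = rng.standard_normal((7, P))
        y = rng.standard_normal(7)

        def run(order):
            state = prior
            for i in order:
                state = ms.nig_update(state, ms.DesignBlock(X[i : i + 1], y[i : i + 1]))
            return state

        a = run(range(7))
        b = run(rng.permutation(7))
        assert a.tau == pytest.approx(b.tau, abs=1e-9)
        assert a.lambda_inv == pytest.approx(b.lambda_inv, abs=1e-9)
        assert a.beta == pytest.approx(b.beta, abs=1e-9)

    @pytest.mark.parametrize("P", [1, 2])
    def test_posterior_matches_grid_integration(self, rng, P):
        """Closed-form posterior moments agree with dense numerical
        integration of prior x likelihood (independent oracle)."""
        tau0 = rng.normal(0, 0.5, P)
        A = rng.standard_normal((P, P))
        lam0_inv = A @ A.T + np.eye(P)
        alpha0, beta0 = 2.0, 1.5
        X = rng.standard_normal((6, P))
        y = X @ rng.normal(0, 1, P) + rng.normal(0, 0.5, 6)

        post = ms.nig_update(
            ms.NIGState(tau0, lam0_inv, alpha0, beta0), ms.DesignBlock(X, y)
        )
        ref = nig_grid_moments(tau0, lam0_inv, alpha0, beta0, X, y)
        # analytic moments: E[w] = tau_n, Cov[w] = beta/(alpha-1) Lambda^-1
        assert post.tau == pytest.approx(ref["mean"], rel=1e-4, abs=1e-6)
        cov = post.beta / (post.alpha - 1.0) * post.lambda_inv
        assert cov == pytest.approx(ref["cov"], rel=1e-4, abs=1e-6)
        assert post.beta / (post.alpha - 1.0) == pytest.approx(
            ref["e_sigma2"], rel=1e-4
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 6), st.integers(1, 8))
    def test_update_preserves_state_validity(self, seed, P, n):
        rng = np.random.default_rng(seed)
        prior = ms.NIGState(rng.normal(0, 1, P), np.eye(P) * rng.uniform(0.1, 3), 1.0, 1.0)
        block = ms.DesignBlock(rng.standard_normal((n, P)), rng.standard_normal(n))
        post = ms.nig_update(prior, block)
        post.validate()
        assert post.alpha == prior.alpha + n / 2


class TestPredictive:
    def test_worked_example_distribution(self):
        dist = ms.posterior_predictive(worked_posterior(), [1.0])
        assert dist.location == pytest.approx(1.0)
        assert dist.scale_sq == pytest.approx(2.0)  # (2/1.5) * (1 + 0.5)
        assert dist.nu == pytest.approx(3.0)

    def test_nu_is_twice_alpha(self, rng):
        state = ms.NIGState(np.zeros(2), np.eye(2), 5.5, 1.7)
        assert ms.posterior_predictive(state, rng.standard_normal(2)).nu == 11.0

    def test_zero_mean_gives_zero_location(self, rng):
        state = ms.NIGState(np.zeros(4), np.eye(4), 2.0, 1.0)
        for _ in range(3):
            assert ms.posterior_predictive(state, rng.standard_normal(4)).location == 0.0

    def test_predictive_matches_monte_carlo(self, rng):
        """Sampling (w, sigma2) from the posterior and then y reproduces the
        Student-t predictive's mean and spread."""
        post = worked_posterior()
        n = 200_000
        sigma2 = stats.invgamma.rvs(post.alpha, scale=post.beta, size=n, random_state=rng)
        w = post.tau[0] + np.sqrt(sigma2 * post.lambda_inv[0, 0]) * rng.standard_normal(n)
        y = w * 1.0 + np.sqrt(sigma2) * rng.standard_normal(n)
        dist = ms.posterior_predictive(post, [1.0])
        assert np.mean(y) == pytest.approx(dist.location, abs=0.02)
        # compare central quantiles (variance of t_3 is infinite-ish noisy)
        lo, hi = ms.predictive_interval(dist, 0.8)
        assert np.quantile(y, 0.1) == pytest.approx(lo, abs=0.03)
        assert np.quantile(y, 0.9) == pytest.approx(hi, abs=0.03)


class TestPredictiveInterval:
    def test_zero_level_degenerates_to_location(self):
        dist = ms.PredictiveDistribution(1.5, 2.0, 3.0)
        assert ms.predictive_interval(dist, 0.0) == (1.5, 1.5)

    def test_normal_limit(self):
        dist = ms.PredictiveDistribution(0.0, 1.0, 1e7)
        lo, hi = ms.predictive_interval(dist, 0.95)
        assert hi == pytest.approx(1.959964, abs=1e-4)
        assert lo == pytest.approx(-hi)

    def test_worked_example_halfwidth_vs_cdf_inversion(self):
        dist = ms.PredictiveDistribution(1.0, 2.0, 3.0)
        lo, hi = ms.predictive_interval(dist, 0.95)
        # independent oracle: invert the t CDF numerically
        q = optimize.brentq(lambda t: stats.t.cdf(t, 3) - 0.975, 0, 100)
        assert hi - dist.location == pytest.approx(np.sqrt(2.0) * q, rel=1e-9)
        assert dist.location - lo == pytest.approx(np.sqrt(2.0) * q, rel=1e-9)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            ms.predictive_interval(ms.PredictiveDistribution(0, 1, 2), 1.0)


class TestSerialization:
    def test_json_round_trip(self, default_prior):
        restored = ms.NIGState.from_json(default_prior.to_json())
        assert np.array_equal(restored.tau, default_prior.tau)
        assert np.array_equal(restored.lambda_inv, default_prior.lambda_inv)
        assert restored.alpha == default_prior.alpha
        assert restored.beta == default_prior.beta
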