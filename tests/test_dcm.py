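"""Model core: forward integration, variational-Laplace inversion, BMA."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import multivariate_normal

from conftest import make_posterior
from scaledcm.dcm import (
    DCMModel,
    PriorSpec,
    bayesian_model_average,
    integrate_model,
    invert_model,
)
from scaledcm.laplace import variational_laplace
from scaledcm.timeseries import Timeseries


class TestIntegration:
    def test_zero_generator_is_identity_flow(self):
        ts = integrate_model(DCMModel([[0.0]]), [1.0], None, 50, 0.1)
        assert np.allclose(ts.values, 1.0)

    def test_scalar_closed_form(self):
        ts = integrate_model(DCMModel([[-1.0]]), [1.0], None, 101, 0.01)
        assert abs(ts.values[0, 100] - np.exp(-1.0)) < 1e-10

    def test_matches_adaptive_ode_oracle(self):
        A = np.array([[-1.0, 0.5], [0.2, -1.0]])
        x0 = np.array([1.0, 0.0])
        ts = integrate_model(DCMModel(A), x0, None, 501, 0.01)
        sol = solve_ivp(
            lambda t, x: A @ x,
            (0, 5.0),
            x0,
            t_eval=ts.times,
            rtol=1e-11,
            atol=1e-13,
        )
        assert np.abs(ts.values - sol.y).max() < 1e-6

    def test_one_step_equals_matrix_exponential(self):
        from scipy.linalg import expm

        A = np.array([[-0.7, 0.3], [-0.1, -1.2]])
        x0 = np.array([0.5, -1.0])
        ts = integrate_model(DCMModel(A), x0, None, 2, 0.37)
        assert np.abs(ts.values[:, 1] - expm(A * 0.37) @ x0).max() < 1e-10

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            integrate_model(DCMModel(np.eye(2) * -1), [1.0], None, 10, 0.1)

    def test_seeded_noise_is_reproducible(self):
        m = DCMModel([[-1.0]], noise_sd=0.3)
        a = integrate_model(m, [0.0], None, 50, 0.1, seed=9)
        b = integrate_model(m, [0.0], None, 50, 0.1, seed=9)
        c = integrate_model(m, [0.0], None, 50, 0.1, seed=10)
        assert (a.values == b.values).all()
        assert not (a.values == c.values).all()

    def test_smoothed_noise_keeps_amplitude(self):
        # unit-power kernel normalisation: smoothing must not quench the noise
        m = DCMModel([[0.0]], noise_sd=1.0, noise_smoothness=0.2)
        ts = integrate_model(m, [0.0], None, 2000, 0.1, seed=1)
        increments = np.diff(ts.values[0])
        assert 0.02 < increments.std() < 0.6


class TestVariationalLaplace:
    def _linear_problem(self, d, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, d))
        theta_true = rng.standard_normal(d)
        sigma = 0.4
        y = X @ theta_true + sigma * rng.standard_normal(n)
        theta0 = np.zeros(d)
        S0 = np.diag(np.linspace(0.5, 2.0, d))
        return X, y, theta0, S0, sigma

    @pytest.mark.parametrize("d", [1, 2])
    def test_conjugate_gaussian_oracle(self, d):
        """Linear model, known precision: VL must equal the exact posterior."""
        X, y, theta0, S0, sigma = self._linear_problem(d)
        lam = -2 * np.log(sigma)
        fit = variational_laplace(
            lambda th: X @ th, y, theta0, S0, lam=lam, fix_lam=True
        )
        P = np.linalg.inv(S0) + np.exp(lam) * X.T @ X
        S = np.linalg.inv(P)
        m = S @ (np.linalg.inv(S0) @ theta0 + np.exp(lam) * X.T @ y)
        log_ev = multivariate_normal.logpdf(
            y, mean=X @ theta0, cov=sigma**2 * np.eye(y.size) + X @ S0 @ X.T
        )
        assert np.abs(fit.theta - m).max() < 1e-6
        assert np.abs(fit.cov - S).max() < 1e-6
        assert abs(fit.free_energy - log_ev) < 1e-3

    def test_free_energy_monotone_nonlinear(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 4, 80)
        y = np.exp(-1.3 * t) + 0.05 * rng.standard_normal(t.size)
        fit = variational_laplace(
            lambda th: np.exp(-np.abs(th[0]) * t), y, [0.5], [[4.0]]
        )
        assert np.all(np.diff(fit.free_energy_trace) >= -1e-9)
        assert fit.converged


class TestInversion:
    def test_noiseless_recovery_scalar(self):
        data = integrate_model(DCMModel([[-1.0]]), [1.0], None, 500, 0.05)
        priors = PriorSpec([[-0.5]], [[1.0]])  # prior away from truth
        post = invert_model(data, priors=priors)
        assert abs(post.mean_A[0, 0] - (-1.0)) < 0.05

    def test_delta_prior_returns_prior_mean(self):
        rng = np.random.default_rng(0)
        data = Timeseries(rng.standard_normal((2, 50)), dt=0.1)
        priors = PriorSpec.default(2)
        priors = PriorSpec(priors.mean_A, np.zeros((2, 2)))
        post = invert_model(data, priors=priors)
        assert (post.mean_A == priors.mean_A).all()
        assert post.n_free == 0

    def test_recovery_rmse_over_replicates(self):
        """Random stable 2x2, sigma 0.05, T=1000: RMSE below 0.1."""
        rng = np.random.default_rng(7)
        errs = []
        for rep in range(20):
            A = -np.eye(2)
            A[0, 1] = rng.uniform(-0.5, 0.5)
            A[1, 0] = rng.uniform(-0.5, 0.5)
            data = integrate_model(
                DCMModel(A, noise_sd=0.05),
                rng.standard_normal(2),
                None,
                1000,
                0.25,
                seed=1000 + rep,
            )
            post = invert_model(data, priors=PriorSpec.default(2))
            errs.append(post.mean_A - A)
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse < 0.1

    def test_free_energy_monotone_and_finite(self):
        data = integrate_model(
            DCMModel(np.array([[-1.0, 0.4], [-0.2, -0.9]]), noise_sd=0.1),
            [1.0, 0.0],
            None,
            400,
            0.2,
            seed=5,
        )
        post = invert_model(data, priors=PriorSpec.default(2))
        assert np.isfinite(post.free_energy)
        assert np.all(np.diff(post.free_energy_trace) >= -1e-9)
        assert post.converged

    def test_too_few_samples_raises(self):
        data = Timeseries(np.random.default_rng(0).standard_normal((2, 2)), dt=0.1)
        with pytest.raises(ValueError):
            invert_model(data, priors=PriorSpec.default(2))

    def test_posterior_json_round_trip(self, tmp_path):
        data = integrate_model(
            DCMModel([[-1.0]], noise_sd=0.1), [1.0], None, 100, 0.2, seed=2
        )
        post = invert_model(data)
        p = tmp_path / "post.json"
        post.to_json(p)
        back = post.from_json(p)
        assert np.allclose(back.mean_A, post.mean_A)
        assert np.allclose(back.cov, post.cov)
        assert back.free_energy == post.free_energy
        # deterministic serialisation for diffing
        assert post.to_json() == back.to_json()

    def test_summary_mentions_parameters(self):
        data = integrate_model(
            DCMModel([[-1.0]], noise_sd=0.1), [1.0], None, 100, 0.2, seed=2
        )
        s = invert_model(data).summary()
        assert "a[0,0]" in s and "free energy" in s


class TestBMA:
    def test_idempotent_on_identical(self):
        P = make_posterior([[-1.0]])
        avg = bayesian_model_average([P, P, P])
        assert np.allclose(avg.mean_A, P.mean_A)
        assert np.allclose(avg.cov, P.cov)

    def test_equal_evidence_averages_means(self):
        a = make_posterior([[-1.0]], F=3.0)
        b = make_posterior([[-3.0]], F=3.0)
        avg = bayesian_model_average([a, b])
        assert abs(avg.mean_A[0, 0] - (-2.0)) < 1e-12

    def test_twenty_nat_gap_dominates(self):
        a = make_posterior([[-1.0]], F=20.0)
        b = make_posterior([[-3.0]], F=0.0)
        avg = bayesian_model_average([a, b])
        assert abs(avg.mean_A[0, 0] - (-1.0)) < 1e-6

    def test_equal_weights_option(self):
        a = make_posterior([[-1.0]], F=50.0)
        b = make_posterior([[-3.0]], F=0.0)
        avg = bayesian_model_average([a, b], weights="equal")
        assert abs(avg.mean_A[0, 0] - (-2.0)) < 1e-12

    def test_between_model_spread_inflates_covariance(self):
        a = make_posterior([[-1.0]], F=0.0)
        b = make_posterior([[-3.0]], F=0.0)
        avg = bayesian_model_average([a, b])
        assert avg.cov[0, 0] > a.cov[0, 0]

    def test_empty_and_inconsistent_raise(self):
        with pytest.raises(ValueError):
            bayesian_model_average([])
        with pytest.raises(ValueError):
            bayesian_model_average(
                [make_posterior([[-1.0]]), make_posterior(-np.eye(2))]
            )
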