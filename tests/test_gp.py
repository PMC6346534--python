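"""GP regression: kernel, likelihood, posterior, derivatives, coregionalisation."""

import numpy as np
import pytest

from grnmatch.gp import (
    CoregionalisedGPFit,
    GPHyperparameters,
    SmoothedTrajectories,
    fit_gp,
    fit_multioutput_gp,
    log_marginal_likelihood,
    multioutput_posterior_mean,
    numeric_derivative,
    posterior_derivative,
    posterior_mean_and_cov,
    se_kernel,
    smooth_dataset,
)

HYP = GPHyperparameters(signal_sd=1.0, noise_sd=0.1, lengthscale=2.0)


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        h = GPHyperparameters(1.7, 0.1, 3.0)
        assert se_kernel(np.array([4.0]), np.array([4.0]), h)[0, 0] == pytest.approx(1.7**2)

    def test_known_value_at_sqrt2_lengthscales(self):
        h = GPHyperparameters(1.0, 0.1, 2.0)
        k = se_kernel(np.array([0.0]), np.array([2.0 * np.sqrt(2.0)]), h)[0, 0]
        assert k == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_symmetry(self):
        t = np.array([0.0, 1.0, 3.5])
        k = se_kernel(t, t, HYP)
        assert np.allclose(k, k.T)


class TestLogMarginalLikelihood:
    def test_single_zero_observation(self):
        h = GPHyperparameters(np.sqrt(0.5), np.sqrt(0.5), 1.0)
        lml = log_marginal_likelihood(np.array([0.0]), np.array([0.0]), h)
        assert lml == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-7)

    def test_single_observation_normal_logpdf(self):
        h = GPHyperparameters(1.0, 0.5, 1.0)
        a = 1.3
        var = 1.0 + 0.25
        expect = -a**2 / (2 * var) - 0.5 * np.log(var) - 0.5 * np.log(2 * np.pi)
        lml = log_marginal_likelihood(np.array([a]), np.array([0.0]), h)
        assert lml == pytest.approx(expect, abs=1e-7)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            d = rng.integers(2, 10)
            t = np.sort(rng.uniform(0, 10, d))
            x = rng.standard_normal(d)
            h = GPHyperparameters(*np.exp(rng.uniform(-1, 1, 3)))
            k = se_kernel(t, t, h) + (h.noise_sd**2 + 1e-8 * h.signal_sd**2) * np.eye(d)
            expect = (
                -0.5 * x @ np.linalg.inv(k) @ x
                - 0.5 * np.log(np.linalg.det(k))
                - d / 2 * np.log(2 * np.pi)
            )
            assert log_marginal_likelihood(x, t, h) == pytest.approx(expect, abs=1e-8)

    def test_matches_sklearn_gpr(self):
        """Independent cross-check against scikit-learn's GP implementation."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 10, 9))
        x = rng.standard_normal(9)
        h = GPHyperparameters(1.3, 0.4, 2.2)
        kernel = ConstantKernel(h.signal_sd**2, "fixed") * RBF(h.lengthscale, "fixed") \
            + WhiteKernel(h.noise_sd**2, "fixed")
        gpr = GaussianProcessRegressor(kernel=kernel, alpha=0.0, optimizer=None)
        gpr.fit(t[:, None], x)
        ours = log_marginal_likelihood(x, t, h)
        # small discrepancy expected from the PSD safety jitter
        assert ours == pytest.approx(gpr.log_marginal_likelihood(), abs=1e-4)
        ts = np.linspace(0, 10, 7)
        from grnmatch.gp import GPFitResult

        fit = GPFitResult(h, t, x, 0.0, ours)
        mean, _ = posterior_mean_and_cov(fit, ts)
        assert np.allclose(mean, gpr.predict(ts[:, None]), atol=1e-6)

    def test_invariant_under_pair_permutation(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10, 8))
        x = rng.standard_normal(8)
        perm = rng.permutation(8)
        a = log_marginal_likelihood(x, t, HYP)
        b = log_marginal_likelihood(x[perm], t[perm], HYP)
        assert a == pytest.approx(b, abs=1e-9)


class TestPosterior:
    def test_near_noiseless_gp_interpolates(self):
        t = np.linspace(0, 10, 8)
        x = np.sin(t)
        h = GPHyperparameters(1.0, 1e-6, 2.0)
        from grnmatch.gp import GPFitResult

        fit = GPFitResult(h, t, x - x.mean(), float(x.mean()), 0.0)
        mean, _ = posterior_mean_and_cov(fit, t)
        assert np.allclose(mean, x, atol=1e-5)

    def test_prior_reversion_far_from_data(self):
        t = np.array([0.0, 1.0])
        x = np.array([2.0, 4.0])
        h = GPHyperparameters(1.5, 0.1, 1.0)
        from grnmatch.gp import GPFitResult

        fit = GPFitResult(h, t, x - x.mean(), float(x.mean()), 0.0)
        mean, cov = posterior_mean_and_cov(fit, np.array([200.0]))
        assert mean[0] == pytest.approx(3.0, abs=1e-8)
        assert cov[0, 0] == pytest.approx(1.5**2, rel=1e-6)

    def test_matches_dense_oracle_small_instance(self):
        rng = np.random.default_rng(2)
        t = np.array([0.0, 1.3])
        x = rng.standard_normal(2)
        ts = np.array([0.5, 2.0, 7.0])
        h = GPHyperparameters(0.8, 0.3, 1.1)
        from grnmatch.gp import GPFitResult

        fit = GPFitResult(h, t, x, 0.0, 0.0)
        mean, cov = posterior_mean_and_cov(fit, ts)
        kn = se_kernel(t, t, h) + (h.noise_sd**2 + 1e-8 * h.signal_sd**2) * np.eye(2)
        ks = se_kernel(t, ts, h)
        kin = np.linalg.inv(kn)
        assert np.allclose(mean, ks.T @ kin @ x, atol=1e-10)
        assert np.allclose(cov, se_kernel(ts, ts, h) - ks.T @ kin @ ks, atol=1e-10)

    def test_posterior_variance_nonnegative(self):
        t = np.linspace(0, 20, 15)
        rng = np.random.default_rng(8)
        fit = fit_gp(np.sin(t) + 0.05 * rng.standard_normal(15), t, restarts=3, seed=0)
        _, cov = posterior_mean_and_cov(fit, np.linspace(-5, 25, 40))
        assert np.all(np.diag(cov) >= -1e-10)


class TestDerivative:
    def test_vanishes_at_coincident_single_point(self):
        from grnmatch.gp import GPFitResult

        fit = GPFitResult(HYP, np.array([3.0]), np.array([1.0]), 0.0, 0.0)
        assert posterior_derivative(fit, np.array([3.0]))[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_central_finite_difference(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(5, 12)
        t = np.sort(rng.uniform(0, 20, d))
        x = np.sin(t / 2) + 0.02 * rng.standard_normal(d)
        fit = fit_gp(x, t, restarts=3, seed=seed)
        ts = np.linspace(t[0], t[-1], 9)
        h = 1e-6 * fit.hyper.lengthscale
        fd = (
            posterior_mean_and_cov(fit, ts + h)[0] - posterior_mean_and_cov(fit, ts - h)[0]
        ) / (2 * h)
        an = posterior_derivative(fit, ts)
        assert np.allclose(an, fd, rtol=1e-4, atol=1e-7 * max(1.0, np.abs(fd).max()))

    def test_linear_data_slope_recovered(self):
        t = np.linspace(0, 10, 21)
        x = 0.7 * t + 1.0
        fit = fit_gp(x, t, restarts=4, seed=3)
        d = posterior_derivative(fit, np.linspace(2, 8, 5))
        assert np.allclose(d, 0.7, rtol=0.01)


class TestFitGP:
    def test_seed_determinism(self):
        t = np.linspace(0, 10, 15)
        rng = np.random.default_rng(1)
        x = np.sin(t) + 0.1 * rng.standard_normal(15)
        a = fit_gp(x, t, restarts=4, seed=9)
        b = fit_gp(x, t, restarts=4, seed=9)
        assert a.hyper == b.hyper
        assert a.log_marginal_likelihood == b.log_marginal_likelihood

    def test_result_beats_every_start(self):
        t = np.linspace(0, 10, 15)
        rng = np.random.default_rng(4)
        x = np.cos(t) + 0.05 * rng.standard_normal(15)
        fit = fit_gp(x, t, restarts=5, seed=2)
        xc = x - x.mean()
        for l0 in (0.5, 2.0, 8.0):
            h = GPHyperparameters(np.std(xc), 0.1 * np.std(xc), l0)
            assert fit.log_marginal_likelihood >= log_marginal_likelihood(xc, t, h) - 1e-6

    def test_fixed_lengthscale_is_respected(self):
        t = np.linspace(0, 10, 15)
        fit = fit_gp(np.sin(t), t, restarts=3, seed=0, fixed_lengthscale=3.3)
        assert fit.hyper.lengthscale == 3.3

    def test_hyperparameter_recovery_from_gp_samples(self):
        true = GPHyperparameters(1.0, 0.05, 3.0)
        t = np.linspace(0, 40, 41)
        k = se_kernel(t, t, true) + true.noise_sd**2 * np.eye(41)
        L = np.linalg.cholesky(k)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = L @ rng.standard_normal(41)
            fit = fit_gp(x, t, restarts=4, seed=seed)
            errs.append(abs(np.log(fit.hyper.lengthscale) - np.log(true.lengthscale)))
        assert np.median(errs) < np.log(1.3)


class TestMultiOutput:
    def test_identity_coregionalisation_decouples(self):
        t = np.linspace(0, 10, 9)
        Y = np.vstack([np.sin(t), np.cos(t)])
        means = Y.mean(axis=1)
        fit = CoregionalisedGPFit(
            coreg_matrix=np.eye(2),
            lengthscale=2.0,
            noise_sd=0.1,
            train_times=t,
            train_values=Y - means[:, None],
            train_means=means,
            log_marginal_likelihood=0.0,
        )
        joint = multioutput_posterior_mean(fit, t)
        from grnmatch.gp import GPFitResult

        h = GPHyperparameters(1.0, 0.1, 2.0)
        for g in range(2):
            single = GPFitResult(h, t, Y[g] - means[g], means[g], 0.0)
            mean, _ = posterior_mean_and_cov(single, t)
            assert np.allclose(joint[g], mean, atol=1e-6)

    def test_duplicated_gene_yields_high_correlation(self):
        t = np.linspace(0, 10, 15)
        rng = np.random.default_rng(3)
        base = np.sin(t) + 0.01 * rng.standard_normal(15)
        Y = np.vstack([base, base])
        fit = fit_multioutput_gp(Y, t, restarts=4, seed=1)
        B = fit.coreg_matrix
        corr = B[0, 1] / np.sqrt(B[0, 0] * B[1, 1])
        assert corr >= 0.95

    def test_joint_likelihood_matches_dense_kronecker_oracle(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 10, 4))
        Y = rng.standard_normal((2, 4))
        L = np.array([[1.0, 0.0], [0.4, 0.8]])
        B = L @ L.T
        l, sn = 1.7, 0.3
        from grnmatch.gp import _icm_lml

        got = _icm_lml(Y, t, B, l, sn)
        kt = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * l**2)) + 1e-8 * np.eye(4)
        kfull = np.kron(B, kt) + sn**2 * np.eye(8)
        y = Y.reshape(-1)
        expect = (
            -0.5 * y @ np.linalg.inv(kfull) @ y
            - 0.5 * np.log(np.linalg.det(kfull))
            - 4 * np.log(2 * np.pi)
        )
        assert got == pytest.approx(expect, abs=1e-7)

    def test_seed_determinism(self):
        t = np.linspace(0, 10, 9)
        Y = np.vstack([np.sin(t), np.cos(t), np.sin(t / 2)])
        a = fit_multioutput_gp(Y, t, restarts=3, seed=5)
        b = fit_multioutput_gp(Y, t, restarts=3, seed=5)
        assert np.array_equal(a.coreg_matrix, b.coreg_matrix)
        assert a.lengthscale == b.lengthscale


class TestNumericDerivative:
    def test_quadratic_forward_difference(self):
        d = numeric_derivative(lambda t: np.asarray(t) ** 2, np.array([1.0]), delta=1e-4)
        assert d[0] == pytest.approx(2.0001, rel=1e-9)

    def test_constant_function(self):
        d = numeric_derivative(lambda t: np.full_like(np.asarray(t, float), 3.3), np.linspace(0, 1, 5))
        assert np.allclose(d, 0.0)

    def test_agrees_with_analytic_gp_derivative(self):
        t = np.linspace(0, 10, 15)
        x = np.sin(t)
        fit = fit_gp(x, t, restarts=4, seed=2)
        ts = np.linspace(1, 9, 7)
        num = numeric_derivative(lambda q: posterior_mean_and_cov(fit, q)[0], ts)
        an = posterior_derivative(fit, ts)
        assert np.allclose(num, an, rtol=1e-3, atol=1e-6)

    def test_rejects_nonpositive_delta(self):
        with pytest.raises(ValueError):
            numeric_derivative(lambda t: t, np.array([0.0]), delta=0.0)


class TestSmoothDataset:
    def test_shapes_and_pred_grid(self, oscillatory_dataset):
        sm = smooth_dataset(oscillatory_dataset, "single_output", n_pred=21, restarts=3, seed=0)
        assert sm.values.shape == (5, 21)
        assert sm.pred_times[0] == oscillatory_dataset.times[0]
        assert sm.pred_times[-1] == oscillatory_dataset.times[-1]

    def test_decay_gene_derivative_consistent_with_kinetics(self):
        import numpy as np
        from grnmatch.simulate import GeneKinetics, ODEModelSpec, simulate_deterministic

        gamma = 0.25
        spec = ODEModelSpec(
            kinetics=(GeneKinetics(0.0, 0.0, gamma), GeneKinetics(0.1, 0.0, 0.5)),
            initial_state=np.array([2.0, 0.5]),
        )
        data = simulate_deterministic(spec, np.linspace(0, 12, 25))
        sm = smooth_dataset(data, "single_output", n_pred=21, restarts=4, seed=1)
        interior = slice(4, -4)
        ratio = sm.derivatives[0][interior] / sm.values[0][interior]
        assert np.allclose(ratio, -gamma, rtol=0.05)

    def test_csv_roundtrip(self, tmp_path, oscillatory_dataset):
        sm = smooth_dataset(oscillatory_dataset, "single_output", n_pred=21, restarts=3, seed=0)
        p = tmp_path / "sm.csv"
        sm.to_csv(p)
        back = SmoothedTrajectories.from_csv(p)
        assert np.allclose(back.values, sm.values, rtol=1e-11)
        assert np.allclose(back.derivatives, sm.derivatives, rtol=1e-11)
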