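import numpy as np
import pytest
from scipy.stats import kstest, multivariate_normal, norm

from geobma import (
    ChainState,
    CovarianceParams,
    ModelIndicator,
    SamplerConfig,
    SpatialDataset,
    latent_log_gradient,
    log_joint,
    mala_update_latent,
    run_parj,
)
from geobma.covariance import build_covariance_matrix
from geobma.gaussian_core import CoefficientPrior
from geobma.sampler import _Engine
from geobma.synthetic import (
    SimulationScenario,
    recovery_scenario,
    simulate_gaussian_data,
    simulate_poisson_data,
)

from conftest import make_indicator


def poisson_dataset(n=20, seed=3):
    scn = SimulationScenario(
        n_sites=n,
        true_theta=CovarianceParams(
            log_sill=np.log(0.5), log_ranges=(np.log(2.0),) * 2, log_nugget=None
        ),
        true_gamma=make_indicator(3, [1]),
        true_beta=np.array([1.0, 0.5, 0.0]),
        family="poisson",
        seed=seed,
    )
    return simulate_poisson_data(scn), scn


def poisson_config(**kw):
    defaults = dict(
        n_iter=400, burn_in=100, seed=2, include_nugget=False, include_anisotropy=False
    )
    defaults.update(kw)
    return SamplerConfig(**defaults)


class TestSpatialDataset:
    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="3 sites"):
            SpatialDataset(np.zeros((2, 2)), np.ones((2, 1)), np.zeros(2), ["a"])

    def test_missing_values_rejected(self):
        X = np.ones((4, 1))
        y = np.array([0.0, np.nan, 1.0, 2.0])
        with pytest.raises(ValueError, match="missing"):
            SpatialDataset(np.zeros((4, 2)), X, y, ["a"])

    def test_poisson_requires_integer_counts(self):
        with pytest.raises(ValueError, match="integer"):
            SpatialDataset(
                np.random.default_rng(0).uniform(size=(4, 2)),
                np.ones((4, 1)),
                np.array([1.0, 2.5, 0.0, 3.0]),
                ["a"],
                family="poisson",
            )


class TestSamplerConfig:
    def test_all_violations_reported_at_once(self):
        cfg = SamplerConfig(n_iter=10, burn_in=20, sd_log_range=-1.0, thin_z=0)
        problems = cfg.validate()
        assert len(problems) >= 3

    def test_unknown_forced_covariate_detected(self, tiny_gaussian_dataset):
        data, _ = tiny_gaussian_dataset
        cfg = SamplerConfig(forced=("not_a_column",))
        assert any("not_a_column" in p for p in cfg.validate(data))

    def test_run_refuses_bad_config_before_iterating(self, tiny_gaussian_dataset):
        data, _ = tiny_gaussian_dataset
        with pytest.raises(ValueError, match="invalid sampler configuration"):
            run_parj(data, SamplerConfig(n_iter=5, burn_in=10))


class TestLogJoint:
    def test_gaussian_log_joint_matches_manual_computation(self, tiny_gaussian_dataset):
        """Full manual recomputation of every term with scipy densities."""
        data, scn = tiny_gaussian_dataset
        cfg = SamplerConfig(
            intercept_prior_mean=0.5,
            log_variance_prior_mean=-0.7,
            log_range_prior_mean=0.4,
            include_anisotropy=True,
        )
        theta = CovarianceParams(
            log_sill=0.1,
            log_ranges=(0.3, 0.6),
            psi=0.25,
            log_nugget=-1.0,
        )
        model = make_indicator(4, [1, 2])
        beta = np.array([0.4, 1.2, -0.3, 0.0])
        state = ChainState(theta, model, beta)
        impl = log_joint(state, data, cfg)

        sigma = build_covariance_matrix(data.coords, theta)
        expected = multivariate_normal(mean=data.X @ beta, cov=sigma).logpdf(data.y)
        idx = model.included
        prior_mean = np.array([0.5, 0.0, 0.0, 0.0])[idx]
        expected += multivariate_normal(
            mean=prior_mean, cov=100.0 * np.eye(3)
        ).logpdf(beta[idx])
        expected += 3 * np.log(0.5)  # Bernoulli(1/2) over 3 selectable covariates
        expected += norm.logpdf(0.1, -0.7, np.sqrt(10))
        expected += norm.logpdf(-1.0, -0.7, np.sqrt(10))
        expected += norm.logpdf(0.3, 0.4, 1.0) + norm.logpdf(0.6, 0.4, 1.0)
        expected += np.log(1 - abs(0.25))
        assert impl == pytest.approx(expected, rel=1e-10)

    def test_poisson_log_joint_matches_manual_computation(self):
        data, scn = poisson_dataset()
        cfg = poisson_config(
            intercept_prior_mean=1.0, log_variance_prior_mean=0.0, log_range_prior_mean=0.5
        )
        theta = CovarianceParams(log_sill=-0.5, log_ranges=(0.7, 0.7))
        model = make_indicator(3, [1])
        beta = np.array([1.0, 0.4, 0.0])
        rng = np.random.default_rng(8)
        z = np.log(data.y + 0.5) + 0.1 * rng.standard_normal(data.n)
        state = ChainState(theta, model, beta, z=z)
        impl = log_joint(state, data, cfg)

        from scipy.special import gammaln

        sigma = build_covariance_matrix(data.coords, theta)
        expected = float(
            np.sum(data.y * z - np.exp(z) - gammaln(data.y + 1.0))
        )
        expected += multivariate_normal(mean=data.X @ beta, cov=sigma).logpdf(z)
        idx = model.included
        expected += multivariate_normal(
            mean=np.array([1.0, 0.0]), cov=100.0 * np.eye(2)
        ).logpdf(beta[idx])
        expected += 2 * np.log(0.5)
        expected += norm.logpdf(-0.5, 0.0, np.sqrt(10))
        expected += norm.logpdf(0.7, 0.5, 1.0)
        assert impl == pytest.approx(expected, rel=1e-10)

    def test_zero_count_zero_latent_contributes_minus_one(self):
        """A Poisson site with y=0, z=0 contributes exactly -exp(0) = -1."""
        data, _ = poisson_dataset()
        y0 = data.y.copy()
        y0[:] = 0
        data0 = SpatialDataset(data.coords, data.X, y0, data.covariate_names, "poisson")
        cfg = poisson_config(forced=())
        theta = CovarianceParams(log_sill=-0.5, log_ranges=(0.7, 0.7))
        state = ChainState(
            theta, make_indicator(3, [], n_forced=0), np.zeros(3), z=np.zeros(data.n)
        )
        impl = log_joint(state, data0, cfg)
        sigma = build_covariance_matrix(data.coords, theta)
        gauss_and_priors = (
            multivariate_normal(mean=np.zeros(data.n), cov=sigma).logpdf(np.zeros(data.n))
            + 3 * np.log(0.5)
            + norm.logpdf(-0.5, *_lv_prior(data0))
            + norm.logpdf(0.7, *_lr_prior(data0))
        )
        assert impl - gauss_and_priors == pytest.approx(-data.n, rel=1e-10)

    def test_log_joint_is_deterministic(self, tiny_gaussian_dataset):
        data, scn = tiny_gaussian_dataset
        cfg = SamplerConfig(include_anisotropy=False)
        state = ChainState(
            CovarianceParams(0.0, (0.0, 0.0), log_nugget=-1.0),
            make_indicator(4, [1]),
            np.array([0.2, 0.9, 0.0, 0.0]),
        )
        assert log_joint(state, data, cfg) == log_joint(state, data, cfg)


def _lv_prior(data):
    v = float(np.var(np.log(data.y.astype(float) + 0.5)))
    return float(np.log(max(v, 1e-6) / 2)), np.sqrt(10)


def _lr_prior(data):
    d = np.linalg.norm(data.coords[:, None] - data.coords[None, :], axis=-1)
    return float(np.log(d.max() / 2)), 1.0


class TestSpatialUpdates:
    def test_psi_never_leaves_open_interval(self, tiny_gaussian_dataset):
        data, _ = tiny_gaussian_dataset
        cfg = SamplerConfig(n_iter=3000, burn_in=500, seed=9, include_anisotropy=True)
        out = run_parj(data, cfg)
        assert np.all(np.abs(out.theta_draws["psi"]) < 1.0)

    def test_total_logit_parameterization_targets_same_posterior(
        self, tiny_gaussian_dataset
    ):
        """Both variance parameterizations agree on the posterior mean of the
        total variance (they are proposal changes, not model changes)."""
        data, _ = tiny_gaussian_dataset
        outs = []
        for vp in ("independent", "total_logit"):
            cfg = SamplerConfig(
                n_iter=8000,
                burn_in=2000,
                seed=17,
                include_anisotropy=False,
                variance_param=vp,
            )
            out = run_parj(data, cfg)
            total = np.exp(out.theta_draws["log_sill"]) + np.exp(
                out.theta_draws["log_nugget"]
            )
            outs.append((total.mean(), total.std()))
        (m1, s1), (m2, s2) = outs
        assert abs(m1 - m2) < 0.5 * max(s1, s2)


class TestModelMove:
    def test_zero_prior_covariate_never_enters(self, tiny_gaussian_dataset):
        data, _ = tiny_gaussian_dataset
        cfg = SamplerConfig(
            n_iter=1500,
            burn_in=100,
            seed=4,
            include_anisotropy=False,
            inclusion_prob={"x1": 0.5, "x2": 0.0, "x3": 0.5},
        )
        out = run_parj(data, cfg)
        j = out.covariate_names.index("x2")
        assert np.all(out.gamma_draws[:, j] == 0)


class TestLatentFieldUpdates:
    def test_gradient_zero_at_joint_stationary_point(self):
        data, scn = poisson_dataset()
        theta = scn.true_theta
        model = make_indicator(3, [])
        beta = np.zeros(3)
        z = np.zeros(data.n)  # X beta = 0 = z, so the prior term vanishes
        y1 = np.ones(data.n, dtype=int)  # y = exp(z) kills the data term
        data1 = SpatialDataset(data.coords, data.X, y1, data.covariate_names, "poisson")
        grad = latent_log_gradient(ChainState(theta, model, beta, z=z), data1)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_gradient_matches_finite_differences(self):
        data, scn = poisson_dataset()
        cfg = poisson_config()
        rng = np.random.default_rng(5)
        z = np.log(data.y + 0.5) + 0.2 * rng.standard_normal(data.n)
        beta = np.array([0.8, 0.3, 0.0])
        state = ChainState(scn.true_theta, make_indicator(3, [1]), beta, z=z)
        grad = latent_log_gradient(state, data)
        eps = 1e-6
        for i in range(0, data.n, 4):
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            fd = (
                log_joint(ChainState(scn.true_theta, state.model, beta, z=zp), data, cfg)
                - log_joint(ChainState(scn.true_theta, state.model, beta, z=zm), data, cfg)
            ) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_gradient_rejected_for_gaussian_family(self, tiny_gaussian_dataset):
        data, scn = tiny_gaussian_dataset
        state = ChainState(scn.true_theta, make_indicator(4, []), np.zeros(4))
        with pytest.raises(ValueError, match="poisson"):
            latent_log_gradient(state, data)

    def test_vanishing_step_size_accepts_everything(self):
        data, scn = poisson_dataset()
        cfg = poisson_config(mala_step=1e-8, auto_tune=False)
        eng = _Engine(data, cfg, np.random.default_rng(21))
        for _ in range(1000):
            eng.step_latent()
        acc, total = eng.acc["mala"]
        assert acc / total > 0.999

    def test_zeroed_gradient_reduces_to_symmetric_random_walk(self):
        """With the drift removed, the Hastings correction cancels exactly and
        the update must match a plain random-walk Metropolis trajectory."""
        data, scn = poisson_dataset()
        cfg = poisson_config(mala_step=0.05, auto_tune=False)
        h = 0.05
        theta = scn.true_theta
        model = make_indicator(3, [1])
        beta = np.array([0.9, 0.4, 0.0])
        sigma = build_covariance_matrix(data.coords, theta)
        from scipy.special import gammaln

        def target(z):
            return float(
                np.sum(data.y * z - np.exp(z) - gammaln(data.y + 1.0))
            ) + multivariate_normal(mean=data.X @ beta, cov=sigma).logpdf(z)

        z_impl = np.log(data.y + 0.5)
        z_manual = z_impl.copy()
        zero_grad = lambda z: np.zeros_like(z)
        for seed in range(40):
            state = ChainState(theta, model, beta.copy(), z=z_impl.copy())
            new = mala_update_latent(
                state, data, cfg, np.random.default_rng(seed), _gradient_fn=zero_grad
            )
            z_impl = new.z
            r = np.random.default_rng(seed)
            prop = z_manual + np.sqrt(h) * r.standard_normal(data.n)
            if np.log(r.uniform()) < target(prop) - target(z_manual):
                z_manual = prop
        np.testing.assert_allclose(z_impl, z_manual, rtol=1e-10)


class TestRunParj:
    def test_same_seed_gives_bit_identical_output(self, tiny_gaussian_dataset):
        data, _ = tiny_gaussian_dataset
        cfg = SamplerConfig(n_iter=500, burn_in=100, seed=13)
        a, b = run_parj(data, cfg), run_parj(data, cfg)
        np.testing.assert_array_equal(a.theta_draws.to_numpy(), b.theta_draws.to_numpy())
        np.testing.assert_array_equal(a.gamma_draws, b.gamma_draws)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)

    def test_stored_states_satisfy_invariants(self, tiny_gaussian_dataset):
        data, _ = tiny_gaussian_dataset
        cfg = SamplerConfig(n_iter=2000, burn_in=200, seed=6)
        out = run_parj(data, cfg)
        assert np.all(out.beta_draws[out.gamma_draws == 0] == 0.0)
        assert np.all(out.gamma_draws[:, out.forced_mask] == 1)
        assert np.all(np.abs(out.theta_draws["psi"]) < 1.0)
        assert out.z_draws is None  # gaussian family never allocates z

    def test_poisson_family_stores_thinned_latent_draws(self):
        data, _ = poisson_dataset()
        cfg = poisson_config(n_iter=300, burn_in=100, store_z=True, thin_z=10)
        out = run_parj(data, cfg)
        assert out.z_draws is not None
        assert out.z_draws.shape == (20, data.n)

    def test_fixed_model_posterior_mean_agrees_with_gls(self):
        """With all covariates forced and a flat-ish prior the posterior mean
        of beta must sit near the generalized-least-squares estimate."""
        rng = np.random.default_rng(30)
        scn = SimulationScenario(
            n_sites=100,
            true_theta=CovarianceParams(
                log_sill=0.0, log_ranges=(np.log(1.5),) * 2, log_nugget=np.log(0.25)
            ),
            true_gamma=make_indicator(4, [1, 2, 3], n_forced=1),
            true_beta=np.array([0.5, 1.0, -0.7, 0.4]),
            seed=31,
        )
        data = simulate_gaussian_data(scn)
        cfg = SamplerConfig(
            n_iter=3000,
            burn_in=1000,
            seed=32,
            include_anisotropy=False,
            forced=tuple(data.covariate_names),
            coef_prior_variance=1e4,
            intercept_prior_mean=0.0,
        )
        out = run_parj(data, cfg)
        sigma = build_covariance_matrix(data.coords, scn.true_theta)
        Si = np.linalg.inv(sigma)
        gls = np.linalg.solve(data.X.T @ Si @ data.X, data.X.T @ Si @ data.y)
        post_mean = out.beta_draws.mean(axis=0)
        post_sd = out.beta_draws.std(axis=0)
        assert np.all(np.abs(post_mean - gls) < 2 * post_sd)


class TestJointCorrectness:
    def test_successive_conditional_simulation_preserves_the_prior(self):
        """Geweke-style check: alternating a full kernel sweep with fresh data
        simulated from the current state leaves the prior invariant, so the
        chain's log-sill marginal must match its normal prior and a null
        covariate's inclusion rate must match its Bernoulli(1/2) prior."""
        rng = np.random.default_rng(77)
        n, n_sweeps = 15, 50_000
        coords = rng.uniform(0, 10, size=(n, 2))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        names = ["intercept", "x1", "x2"]
        cfg = SamplerConfig(
            seed=0,
            include_anisotropy=False,
            include_nugget=True,
            auto_tune=False,
            sd_log_variance=2.5,
            sd_log_range=1.0,
            intercept_prior_mean=0.0,
            log_variance_prior_mean=0.0,
            log_range_prior_mean=float(np.log(5.0)),
            coef_prior_variance=4.0,
        )

        def prior_state():
            theta = CovarianceParams(
                log_sill=rng.normal(0, np.sqrt(10)),
                log_ranges=(rng.normal(np.log(5), 1.0),) * 2,
                log_nugget=rng.normal(0, np.sqrt(10)),
            )
            gamma = np.array([1, rng.integers(2), rng.integers(2)], dtype=np.int8)
            forced = np.array([True, False, False])
            beta = np.zeros(3)
            beta[gamma == 1] = rng.normal(0, 2.0, size=int(gamma.sum()))
            return ChainState(theta, ModelIndicator(gamma, forced), beta)

        state = prior_state()
        y0 = np.zeros(n)
        data = SpatialDataset(coords, X, y0, names, "gaussian")
        eng = _Engine(data, cfg, rng, state)
        # first data draw from the initial prior state
        eng.data.y = X @ eng.state.beta + eng.chol @ rng.standard_normal(n)
        eng._lcp_memo = {}
        log_sills = np.empty(n_sweeps)
        gammas = np.empty(n_sweeps, dtype=np.int8)
        for s in range(n_sweeps):
            eng.step_spatial()
            eng.step_model()
            eng.step_beta()
            eng.data.y = X @ eng.state.beta + eng.chol @ rng.standard_normal(n)
            eng._lcp_memo = {}
            log_sills[s] = eng.state.theta.log_sill
            gammas[s] = eng.state.model.gamma[1]
        ks = kstest(log_sills, "norm", args=(0.0, np.sqrt(10))).statistic
        assert ks < 0.05
        assert abs(gammas.mean() - 0.5) < 0.05
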