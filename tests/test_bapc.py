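"""Bayesian APC model: cohort indexing, sampler correctness, prediction,
DIC and effect decomposition."""

import dataclasses

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy.stats import binom

import mortproj as mp
from mortproj.bapc import (
    BAPCModelSpec,
    apply_gauge,
    cohort_index,
    cohort_index_map,
    dic,
    fit_bapc,
    predict_bapc,
    rw_penalty,
    _extrapolate_rw,
)


class TestCohortIndex:
    def test_documented_geometry(self):
        # I=6, C=10, J=33: youngest age in the last period is cohort 83
        assert cohort_index(1, 33, n_ages=6, n_periods=33, band_width=10) == 83
        # oldest age, first period is the first cohort
        assert cohort_index(6, 1, n_ages=6, n_periods=33, band_width=10) == 1

    def test_enumeration_covers_exactly_k_cohorts(self):
        I, J, C = 6, 33, 10
        ii, jj = np.meshgrid(np.arange(1, I + 1), np.arange(1, J + 1),
                             indexing="ij")
        k = cohort_index(ii, jj, n_ages=I, n_periods=J, band_width=C)
        distinct = np.unique(k)
        assert distinct.size == C * (I - 1) + J == 83
        assert np.array_equal(distinct, np.arange(1, 84))

    @given(
        st.integers(min_value=2, max_value=8),
        st.integers(min_value=3, max_value=25),
        st.integers(min_value=1, max_value=10),
    )
    def test_enumeration_property(self, I, J, C):
        # the identity K = C(I-1) + J holds when bands are no wider than the
        # observed window (C <= J), so consecutive ages' cohort ranges abut
        assume(C <= J)
        ii, jj = np.meshgrid(np.arange(1, I + 1), np.arange(1, J + 1),
                             indexing="ij")
        k = cohort_index(ii, jj, n_ages=I, n_periods=J, band_width=C)
        distinct = np.unique(k)
        assert distinct.size == C * (I - 1) + J
        assert distinct[0] == 1 and distinct[-1] == C * (I - 1) + J

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="age index"):
            cohort_index(0, 1, n_ages=6, n_periods=33, band_width=10)
        with pytest.raises(ValueError, match="period index"):
            cohort_index(1, 34, n_ages=6, n_periods=33, band_width=10)

    def test_map_matches_scalar_formula(self):
        kmap = cohort_index_map(6, 33, 10)
        assert kmap[0, 32] == 82  # 0-based for cohort 83
        assert kmap[5, 0] == 0


class TestSpecValidation:
    def test_chain_settings_validated(self):
        with pytest.raises(ValueError, match="iterations > burnin"):
            BAPCModelSpec(iterations=100, burnin=100)
        with pytest.raises(ValueError, match="rw1"):
            BAPCModelSpec(age_prior="arima")
        with pytest.raises(ValueError, match="hyperparameters"):
            BAPCModelSpec(tau_rate=0.0)

    def test_cohort_parameter_count(self, fitted_bapc):
        post, _ = fitted_bapc
        assert post.n_cohorts == 83
        assert post.psi.shape[1] == 83


class TestSamplerCorrectness:
    def test_toy_posterior_matches_grid_oracle(self):
        """2-age x 3-period age-period model with fixed precisions: the
        sampler's posterior mean of mu must match dense grid integration."""
        D = np.array([[5.0, 8.0, 11.0], [12.0, 15.0, 20.0]])
        N = np.full((2, 3), 50.0)
        ages = mp.AgeGroupScheme(labels=("35-44", "45-54"),
                                 lower_bounds=(35, 45), width=10)
        surface = mp.MortalitySurface(
            sex="male", ages=ages, years=np.arange(2000, 2003),
            deaths=D.astype(int), exposures=N,
        )
        tau_th, tau_ph = 2.0, 2.0

        # oracle: integrate over the sum-to-zero section
        # theta=(t1,-t1), phi=(p1,p2,-p1-p2)
        def logpost(mu, t1, p1, p2):
            th = np.stack([t1, -t1], -1)
            ph = np.stack([p1, p2, -p1 - p2], -1)
            eta = mu[..., None, None] + th[..., :, None] + ph[..., None, :]
            ll = np.sum(D * eta - N * np.logaddexp(0, eta), axis=(-2, -1))
            lp = -0.5 * tau_th * np.sum(np.diff(th, axis=-1) ** 2, axis=-1)
            lp -= 0.5 * tau_ph * np.sum(np.diff(ph, axis=-1) ** 2, axis=-1)
            return ll + lp

        g = np.linspace(-2.5, 0.5, 61)
        h = np.linspace(-1.2, 1.2, 49)
        MU, T1, P1, P2 = np.meshgrid(g, h, h, h, indexing="ij")
        lp = logpost(MU, T1, P1, P2)
        w = np.exp(lp - lp.max())
        mu_oracle = float((w * MU).sum() / w.sum())
        t1_oracle = float((w * T1).sum() / w.sum())

        spec = BAPCModelSpec(
            include_cohort=False, age_prior="rw1", period_prior="rw1",
            fixed_tau={"age": tau_th, "period": tau_ph},
            chains=2, iterations=20000, burnin=2000, thin=2, seed=5,
        )
        post = fit_bapc(surface, spec)
        assert abs(float(post.mu.mean()) - mu_oracle) < 0.02
        assert abs(float(post.theta[:, 0].mean()) - t1_oracle) < 0.02

    def test_flat_surface_recovers_intercept(self):
        # data generated with all effects zero and q = 0.01
        rng = np.random.default_rng(0)
        q_true = 0.01
        N = np.full((6, 10), 200000.0)
        D = rng.binomial(200000, q_true, size=(6, 10))
        surface = mp.MortalitySurface(
            sex="male", ages=mp.AgeGroupScheme.default(),
            years=np.arange(2000, 2010), deaths=D, exposures=N,
        )
        spec = BAPCModelSpec(chains=1, iterations=3000, burnin=1000, thin=2,
                             seed=2)
        post = fit_bapc(surface, spec)
        from scipy.special import expit

        q_hat = expit(post.mu)
        assert abs(q_hat.mean() - q_true) < 3 * q_hat.std() + 2e-4
        # effect blocks are essentially flat
        assert np.abs(post.theta.mean(axis=0)).max() < 0.05
        assert np.abs(post.phi.mean(axis=0)).max() < 0.05

    def test_same_seed_identical_chains(self, default_surface):
        surface, _ = default_surface
        spec = BAPCModelSpec(chains=2, iterations=600, burnin=200, thin=2,
                             seed=17)
        p1 = fit_bapc(surface, spec)
        p2 = fit_bapc(surface, spec)
        assert np.array_equal(p1.mu, p2.mu)
        assert np.array_equal(p1.psi, p2.psi)
        assert np.array_equal(p1.deviance, p2.deviance)

    def test_recovery_rmse_decreases_with_exposure(self):
        rmses = []
        for expo in (1e4, 1e6):
            cfg = mp.SimulationConfig(population_base=expo, seed=42)
            surface, truth = mp.simulate_surface(cfg)
            spec = BAPCModelSpec(chains=1, iterations=3000, burnin=1000,
                                 thin=2, seed=1)
            post = fit_bapc(surface, spec)
            eta_bar = post.linear_predictor().mean(axis=0)
            rmses.append(float(np.sqrt(np.mean((eta_bar - truth["eta"]) ** 2))))
        assert rmses[1] < rmses[0]

    def test_acceptance_rates_in_healthy_band(self, fitted_bapc):
        post, _ = fitted_bapc
        for key, rate in post.acceptance.items():
            assert 0.1 < rate < 0.8, f"{key} acceptance {rate}"


class TestGauge:
    def test_gauge_leaves_linear_predictor_unchanged(self, fitted_bapc):
        post, _ = fitted_bapc
        kmap = cohort_index_map(*post.deaths.shape, post.band_width)
        eta0 = post.linear_predictor() - (post.z if post.z is not None else 0.0)
        for gauge in ("cohort", "age"):
            mu, th, ph, ps = apply_gauge(post.mu, post.theta, post.phi,
                                         post.psi, post.band_width,
                                         zero_linear=gauge)
            eta = mu[:, None, None] + th[:, :, None] + ph[:, None, :] + ps[:, kmap]
            assert np.max(np.abs(eta - eta0)) < 1e-10

    def test_gauge_idempotent(self, fitted_bapc):
        post, _ = fitted_bapc
        once = apply_gauge(post.mu, post.theta, post.phi, post.psi,
                           post.band_width, zero_linear="age")
        twice = apply_gauge(*once, post.band_width, zero_linear="age")
        for a, b in zip(once, twice):
            assert np.max(np.abs(a - b)) < 1e-12

    def test_stored_draws_satisfy_canonical_gauge(self, fitted_bapc):
        post, _ = fitted_bapc
        assert np.abs(post.theta.mean(axis=1)).max() < 1e-10
        assert np.abs(post.phi.mean(axis=1)).max() < 1e-10
        assert np.abs(post.psi.mean(axis=1)).max() < 1e-10
        K = post.psi.shape[1]
        v = np.arange(1, K + 1) - (K + 1) / 2
        lin = post.psi @ v / (v @ v)
        assert np.abs(lin).max() < 1e-10

    def test_prediction_invariant_to_gauge_of_chains(self, fitted_bapc):
        post, _ = fitted_bapc
        mu, th, ph, ps = apply_gauge(post.mu, post.theta, post.phi, post.psi,
                                     post.band_width, zero_linear="age")
        regauged = dataclasses.replace(post, mu=mu, theta=th, phi=ph, psi=ps)
        f1 = predict_bapc(post, 10, seed=11)
        f2 = predict_bapc(regauged, 10, seed=11)
        assert np.max(np.abs(f1.draws - f2.draws)) < 1e-12


class TestPrediction:
    def test_rw2_continues_exact_line_under_infinite_precision(self):
        # last fitted period effects on a line, innovation sd -> 0
        nd, n, H = 5, 12, 8
        slope, intercept = -0.07, 0.4
        values = intercept + slope * np.arange(n)
        values = np.tile(values, (nd, 1))
        out = _extrapolate_rw(values, order=2, sd=np.zeros(nd), horizon=H,
                              rng=np.random.default_rng(0))
        expected = intercept + slope * np.arange(n, n + H)
        assert np.max(np.abs(out - expected)) < 1e-10

    def test_rw1_freezes_last_level_under_infinite_precision(self):
        nd, n, H = 3, 10, 6
        values = np.tile(np.linspace(1.0, -0.5, n), (nd, 1))
        out = _extrapolate_rw(values, order=1, sd=np.zeros(nd), horizon=H,
                              rng=np.random.default_rng(0))
        assert np.max(np.abs(out - values[:, -1:])) < 1e-12

    def test_rw1_predictive_variance_is_h_over_tau(self):
        tau = 4.0
        nd, H = 200000, 6
        values = np.zeros((nd, 2))
        sd = np.full(nd, 1.0 / np.sqrt(tau))
        out = _extrapolate_rw(values, order=1, sd=sd, horizon=H,
                              rng=np.random.default_rng(1))
        var = out.var(axis=0)
        expected = np.arange(1, H + 1) / tau
        assert np.allclose(var, expected, rtol=0.03)

    def test_intervals_widen_with_horizon(self, fitted_bapc):
        post, _ = fitted_bapc
        f = predict_bapc(post, 15, seed=0)
        width = np.log(f.upper / np.maximum(f.lower, 1e-300))
        # compare early vs late horizon per age; allow percentile noise
        assert np.all(width[:, -1] > width[:, 0])

    def test_forecast_years_continue_observed_window(self, fitted_bapc):
        post, _ = fitted_bapc
        f = predict_bapc(post, 5, seed=0)
        assert f.years[0] == post.years[-1] + 1
        assert f.draws.shape[0] == post.n_draws


class TestDIC:
    def test_degenerate_posterior_gives_zero_pd(self):
        # all draws identical: pD = 0 and DIC equals the plug-in deviance,
        # cross-checked against scipy's binomial log-pmf
        D = np.array([[3, 7], [10, 4]])
        N = np.full((2, 2), 60.0)
        ages = mp.AgeGroupScheme(labels=("35-44", "45-54"),
                                 lower_bounds=(35, 45), width=10)
        surface = mp.MortalitySurface(sex="male", ages=ages,
                                      years=np.arange(2000, 2002),
                                      deaths=D, exposures=N)
        spec = BAPCModelSpec(include_cohort=False, age_prior="rw1",
                             period_prior="rw1", chains=1, iterations=4,
                             burnin=0, thin=1, seed=0)
        post = fit_bapc(surface, spec)
        eta = post.linear_predictor()[0]
        frozen = dataclasses.replace(
            post,
            mu=np.full(3, post.mu[0]),
            theta=np.tile(post.theta[0], (3, 1)),
            phi=np.tile(post.phi[0], (3, 1)),
            deviance=np.full(3, post.deviance[0]),
        )
        res = dic(frozen)
        q = 1.0 / (1.0 + np.exp(-eta))
        oracle = -2.0 * binom.logpmf(D, N.astype(int), q).sum()
        assert res.p_d == pytest.approx(0.0, abs=1e-8)
        assert res.dic == pytest.approx(oracle, rel=1e-10)
        assert res.mean_deviance == pytest.approx(oracle, rel=1e-10)

    def test_needs_at_least_two_draws(self, fitted_bapc):
        post, _ = fitted_bapc
        single = dataclasses.replace(
            post, mu=post.mu[:1], theta=post.theta[:1], phi=post.phi[:1],
            psi=post.psi[:1], deviance=post.deviance[:1],
        )
        with pytest.raises(ValueError, match="at least 2"):
            dic(single)

    def test_heterogeneity_wins_on_overdispersed_data(self):
        cfg = mp.SimulationConfig(overdispersion_sd=0.2, seed=8)
        surface, _ = mp.simulate_surface(cfg)
        base = dict(chains=1, iterations=2500, burnin=1000, thin=3, seed=8)
        d_plain = dic(fit_bapc(surface, BAPCModelSpec(**base))).dic
        d_het = dic(fit_bapc(surface,
                             BAPCModelSpec(heterogeneity=True, **base))).dic
        assert d_het < d_plain


class TestDecomposition:
    def test_no_cohort_signal_gives_tiny_cohort_share(self):
        cfg = mp.SimulationConfig(cohort_sd=0.0, seed=3, population_base=1e6)
        surface, _ = mp.simulate_surface(cfg)
        spec = BAPCModelSpec(chains=1, iterations=2500, burnin=1000, thin=3,
                             seed=3)
        post = fit_bapc(surface, spec)
        shares = mp.decompose_effects(post)["variance_shares"]
        assert shares["cohort"] < 0.02

    def test_age_dominates_with_steep_age_schedule(self, fitted_bapc):
        post, _ = fitted_bapc
        shares = mp.decompose_effects(post)["variance_shares"]
        assert shares["age"] == max(shares.values())
        assert shares["age"] > shares["period"] > shares["cohort"]

    def test_shares_sum_to_one(self, fitted_bapc):
        post, _ = fitted_bapc
        shares = mp.decompose_effects(post)["variance_shares"]
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-6)


class TestEstimatorFacade:
    def test_fit_forecast_dic_roundtrip(self, small_surface):
        _, surface, _ = small_surface
        est = mp.BayesianAPC(chains=1, iterations=800, burnin=300, thin=2,
                             seed=0)
        est.fit(surface)
        f = est.forecast(4, seed=0)
        assert f.point.shape == (surface.n_ages, 4)
        assert est.dic().dic > 0
        shares = est.decompose()["variance_shares"]
        assert set(shares) >= {"age", "period", "cohort"}

    def test_sklearn_clone_preserves_params(self):
        from sklearn.base import clone

        est = mp.BayesianAPC(heterogeneity=True, iterations=1234, seed=9)
        cloned = clone(est)
        assert cloned.get_params()["iterations"] == 1234
        assert cloned.get_params()["heterogeneity"] is True


def test_rw_penalty_ranks():
    for n, order in [(6, 1), (6, 2), (33, 2), (83, 2)]:
        R = rw_penalty(n, order)
        assert np.linalg.matrix_rank(R) == n - order
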