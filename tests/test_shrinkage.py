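"""Triple-gamma hierarchy: prior samplers, conjugate conditionals, MH steps."""

import copy

import numpy as np
import pytest
from scipy import stats

from shrinksurv.shrinkage import (
    ShrinkageHyperConfig,
    TripleGammaLayer,
    sample_conjugate_regression,
    sample_gig,
    sample_initial_means,
    sample_means_scales_ncp,
    sample_pole_tail_mh,
    sample_prior_replicates,
    sample_theta_centered,
    update_triple_gamma_layer,
)


class TestPriorReplicates:
    def test_supports(self, rng):
        rep = sample_prior_replicates(4, ShrinkageHyperConfig(), rng, n=2000)
        for layer in ("theta", "beta"):
            assert np.all(rep[layer]["a"] > 0) and np.all(rep[layer]["a"] < 0.5)
            assert np.all(rep[layer]["c"] > 0) and np.all(rep[layer]["c"] < 0.5)
            assert np.all(rep[layer]["lam"] > 0) and np.all(rep[layer]["tau"] > 0)
        assert np.all(rep["theta"]["value"] >= 0)

    def test_gamma_ratio_equals_f_distribution(self, rng):
        """lam = Gamma(a,a)/Gamma(c,c) is exactly F(2a, 2c)."""
        a, c = 0.3, 0.4
        n = 100_000
        lam = rng.gamma(a, 1 / a, n) / rng.gamma(c, 1 / c, n)
        ref = stats.f(2 * a, 2 * c).rvs(size=n, random_state=np.random.default_rng(1))
        _, p = stats.ks_2samp(lam, ref)
        assert p > 0.01

    def test_horseshoe_case_has_heavy_tails(self):
        """a = c = 0.5 makes the local scale F(1,1) — the horseshoe: |beta|
        draws show clear excess kurtosis relative to a Gaussian."""
        rng = np.random.default_rng(3)
        n = 100_000
        lam = rng.gamma(0.5, 2.0, n) / rng.gamma(0.5, 2.0, n)  # F(1,1)
        beta = rng.normal(0.0, np.sqrt(lam))
        clipped = np.clip(beta, -50, 50)  # kurtosis of the bulk, not one outlier
        kurt = stats.kurtosis(clipped)
        assert kurt > 5.0  # Gaussian excess kurtosis is 0


class TestInitialMeans:
    def test_flat_prior_limit(self, rng):
        draws = sample_initial_means(
            np.full(20_000, 2.0), np.ones(20_000), np.full(20_000, 1e12), 1.0, rng
        )
        assert draws.mean() == pytest.approx(2.0, abs=0.03)  # posterior mean -> beta_k0

    def test_point_mass_limit(self, rng):
        d = sample_initial_means(np.array([2.0]), np.array([1.0]), np.array([1e-14]), 1.0, rng)
        assert abs(d[0]) < 1e-5

    def test_finite_case_moments(self, rng):
        draws = np.array([
            sample_initial_means(np.array([2.0]), np.array([1.0]), np.array([1.0]), 1.0, rng)[0]
            for _ in range(20_000)
        ])
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        assert draws.var() == pytest.approx(0.5, abs=0.02)


class TestThetaConditional:
    def test_draws_nonnegative(self, rng):
        path = rng.standard_normal((5, 3)) * 0.2
        th = sample_theta_centered(path, path[0], np.ones(3), 1.0, rng)
        assert np.all(th >= 0)

    def test_one_state_toy_matches_quadrature(self, rng):
        """J=1, K=0: histogram of GIG draws vs the gridded conditional density
        (total-variation distance below 0.02 at 1e5 draws)."""
        beta_path = np.array([[0.6], [1.1]])
        beta_mean = np.array([0.2])
        lam, tau = np.array([0.8]), 1.3
        draws = np.array([
            sample_theta_centered(beta_path, beta_mean, lam, tau, rng)[0]
            for _ in range(0)
        ])
        # vectorised draws: chi and psi are fixed, so sample the GIG directly
        S = (0.6 - 0.2) ** 2 + (1.1 - 0.6) ** 2
        psi = 1.0 / (lam[0] * tau)
        draws = sample_gig(np.full(100_000, -0.5), np.full(100_000, S), np.full(100_000, psi), rng)
        edges = np.linspace(0, np.quantile(draws, 0.999), 120)
        grid = 0.5 * (edges[:-1] + edges[1:])
        logdens = (-0.5 - 1.0) * np.log(grid) - 0.5 * (S / grid + psi * grid)
        dens = np.exp(logdens - logdens.max())
        dens /= dens.sum()
        hist, _ = np.histogram(draws, bins=edges)
        hist = hist / draws.shape[0]
        tv = 0.5 * np.abs(hist - dens).sum()
        assert tv < 0.02

    def test_theta_conditional_agrees_with_centered_formula(self, rng):
        path = np.array([[0.6], [1.1]])
        one = sample_theta_centered(path, np.array([0.2]), np.array([0.8]), 1.3, rng)
        assert one.shape == (1,) and one[0] > 0


class TestNCPJointDraw:
    def test_posterior_matches_conjugate_regression(self, rng):
        """The joint (mean, signed-scale) draw is a Bayesian linear regression;
        its first two moments must match the closed form."""
        n, m = 400, 2
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        bt = rng.standard_normal((n, m)) * 0.7
        truth = np.array([0.5, -1.0, 0.4, 0.8])
        D = np.concatenate([Z, Z * bt], axis=1)
        v = np.full(n, 0.6)
        x = D @ truth + rng.normal(0, np.sqrt(v))
        pv_mean, pv_scale = np.array([4.0, 4.0]), np.array([2.0, 2.0])
        prec = (D.T / v) @ D + np.diag(1.0 / np.concatenate([pv_mean, pv_scale]))
        mean = np.linalg.solve(prec, (D.T / v) @ x)
        cov = np.linalg.inv(prec)
        draws = np.array([
            np.concatenate(sample_means_scales_ncp(x, v, Z, bt, pv_mean, pv_scale, rng))
            for _ in range(20_000)
        ])
        se = np.sqrt(np.diag(cov) / draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se)
        np.testing.assert_allclose(np.cov(draws.T), cov, atol=2e-3)

    def test_degenerate_path_reverts_to_prior(self, rng):
        """All-zero standardised paths leave the scale column data-free: the
        signed scale is then drawn from its prior."""
        n = 200
        Z = np.ones((n, 1))
        bt = np.zeros((n, 1))
        x = rng.normal(2.0, 0.1, n)
        draws = np.array([
            sample_means_scales_ncp(x, np.full(n, 0.01), Z, bt,
                                    np.array([100.0]), np.array([1.5]), rng)[1][0]
            for _ in range(5000)
        ])
        assert draws.mean() == pytest.approx(0.0, abs=0.07)
        assert draws.var() == pytest.approx(1.5, rel=0.1)


class TestScaleUpdates:
    def test_positivity(self, rng):
        lay = TripleGammaLayer.initial(5)
        update_triple_gamma_layer(rng.gamma(0.5, 1.0, 5), lay, rng)
        assert np.all(lay.lam > 0) and lay.tau > 0
        assert np.all(lay.psi > 0) and np.all(lay.zeta > 0)

    def test_gibbs_stationary_distribution_is_prior(self):
        """With values resampled from their prior every sweep and a, c held
        fixed, the scale conditionals must leave the F-marginals invariant."""
        rng = np.random.default_rng(21)
        a = c = 0.25
        m = 3
        lay = TripleGammaLayer.initial(m, a=a, c=c)
        lam_draws, tau_draws = [], []
        n_sweep, thin = 30_000, 10
        for it in range(n_sweep):
            theta = rng.gamma(0.5, 2.0 * lay.lam * lay.tau)  # prior draw given scales
            update_triple_gamma_layer(theta, lay, rng)
            if it % thin == 0:
                lam_draws.append(lay.lam[0])
                tau_draws.append(lay.tau)
        direct = np.random.default_rng(22)
        lam_ref = direct.gamma(a, 1 / a, 3000) / direct.gamma(c, 1 / c, 3000)
        tau_ref = direct.gamma(c, 1 / c, 3000) / direct.gamma(a, 1 / a, 3000)
        _, p_lam = stats.ks_2samp(np.log(lam_draws), np.log(lam_ref))
        _, p_tau = stats.ks_2samp(np.log(tau_draws), np.log(tau_ref))
        assert p_lam > 0.01
        assert p_tau > 0.01

    def test_conditional_matches_2d_quadrature(self):
        """For a fixed theta, iterating the auxiliary-gamma updates must
        reproduce the exact conditional p(lam, tau | theta) obtained by
        brute-force quadrature of F x F x Gamma-kernel on a log grid."""
        from scipy.stats import f as fdist

        rng = np.random.default_rng(31)
        a = c = 0.25
        theta = np.array([0.001])
        lay = TripleGammaLayer.initial(1, a=a, c=c)
        lam_d, tau_d = [], []
        for it in range(40_000):
            update_triple_gamma_layer(theta, lay, rng)
            if it > 500 and it % 5 == 0:
                lam_d.append(lay.lam[0])
                tau_d.append(lay.tau)
        lg = np.linspace(-14, 10, 401)
        L, T = np.meshgrid(np.exp(lg), np.exp(lg), indexing="ij")
        logp = (
            fdist(2 * a, 2 * c).logpdf(L) + np.log(L)
            + fdist(2 * c, 2 * a).logpdf(T) + np.log(T)
            - 0.5 * np.log(L * T) - theta[0] / (2 * L * T)
        )
        P = np.exp(logp - logp.max())
        P /= P.sum()
        exact_log_lam = float((P.sum(axis=1) * lg).sum())
        exact_log_tau = float((P.sum(axis=0) * lg).sum())
        assert np.mean(np.log(lam_d)) == pytest.approx(exact_log_lam, abs=0.15)
        assert np.mean(np.log(tau_d)) == pytest.approx(exact_log_tau, abs=0.15)

    def test_global_scale_monotone_in_signal(self, rng):
        """Inflating every |beta| tenfold shifts the conditional of tau up."""
        base = np.array([0.5, -0.3, 0.8, -0.2])

        def tau_draws(vals, seed):
            r = np.random.default_rng(seed)
            out = []
            for _ in range(2000):
                lay = TripleGammaLayer.initial(4, a=0.2, c=0.2)
                update_triple_gamma_layer(vals**2, lay, r)
                out.append(lay.tau)
            return np.median(out)

        assert tau_draws(10 * base, 5) > tau_draws(base, 5)


class TestPoleTailMH:
    def test_support_preserved(self, rng):
        val, log_sd = 0.2, 0.0
        for _ in range(500):
            gammas = rng.gamma(val, 1 / val, 4)
            val, _, log_sd = sample_pole_tail_mh(val, gammas, 5.0, 10.0, log_sd, rng, adapt=True)
            assert 0.0 < val < 0.5

    def test_prior_only_chain_recovers_scaled_beta(self):
        """With no likelihood terms the MH chain targets 2a ~ Beta(5, 10)."""
        rng = np.random.default_rng(9)
        val, log_sd = 0.2, 0.0
        draws = []
        for it in range(30_000):
            val, _, log_sd = sample_pole_tail_mh(
                val, np.zeros(0), 5.0, 10.0, log_sd, rng, adapt=it < 2000
            )
            if it >= 2000 and it % 10 == 0:
                draws.append(2 * val)
        ref = np.random.default_rng(10).beta(5.0, 10.0, size=len(draws))
        _, p = stats.ks_2samp(np.array(draws), ref)
        assert p > 0.01

    def test_adaptation_moves_toward_target_acceptance(self):
        rng = np.random.default_rng(2)
        val, log_sd = 0.2, np.log(30.0)  # absurdly wide proposal
        acc = 0
        for it in range(4000):
            val, a, log_sd = sample_pole_tail_mh(
                val, np.zeros(0), 5.0, 10.0, log_sd, rng, adapt=True
            )
            acc += a
        assert np.exp(log_sd) < 30.0  # scale shrank
        assert 0.1 < acc / 4000 + 0.05  # chain did not freeze entirely


class TestConjugateRegression:
    def test_matches_normal_equations(self, rng):
        n = 300
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        x = Z @ np.array([1.0, -2.0]) + rng.normal(0, 0.3, n)
        v = np.full(n, 0.09)
        prior = np.array([25.0, 25.0])
        draws = np.array([
            sample_conjugate_regression(x, v, Z, prior, rng) for _ in range(4000)
        ])
        prec = (Z.T / v) @ Z + np.diag(1 / prior)
        mean = np.linalg.solve(prec, (Z.T / v) @ x)
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=0.01)
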