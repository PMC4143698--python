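"""Sampler correctness against closed-form oracles and analytic densities."""

import numpy as np
import pytest
from scipy import stats

from wgrvar import (BayesianWGR, MCMCConfig, WGRPrior, center_genotypes,
                    default_prior, gibbs_fit, r_squared,
                    sample_scaled_inv_chi2)


def _ess(chain):
    import arviz as az
    return max(float(az.ess(np.asarray(chain)[None, :])), 4.0)


class TestScaledInvChi2:
    def test_matches_inverse_gamma_density(self, rng):
        # scaled-inv-chi2(df, s) == InvGamma(df/2, df*s/2)
        for df, scale in [(4.0, 1.0), (1.0, 2.5)]:
            draws = sample_scaled_inv_chi2(df, scale, rng, size=100_000)
            ks = stats.kstest(draws, stats.invgamma(df / 2,
                                                    scale=df * scale / 2).cdf)
            assert ks.pvalue > 0.001

    def test_analytic_mean(self, rng):
        df, scale, n = 6.0, 1.0, 1_000_000
        draws = sample_scaled_inv_chi2(df, scale, rng, size=n)
        mean = df * scale / (df - 2)
        sd = mean * np.sqrt(2.0 / (df - 4))  # var = 2 mean^2 / (df-4)
        assert draws.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(n))

    def test_heavy_tail_median_quantile_oracle(self, rng):
        df, scale = 1.0, 1.0
        draws = sample_scaled_inv_chi2(df, scale, rng, size=200_000)
        expected_median = df * scale / stats.chi2(df).ppf(0.5)
        assert np.median(draws) == pytest.approx(expected_median, rel=0.05)

    def test_large_df_concentrates_at_scale(self, rng):
        draws = sample_scaled_inv_chi2(1e6, 2.0, rng, size=10_000)
        assert draws.mean() == pytest.approx(2.0, rel=1e-2)
        assert draws.std() < 0.01

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_scaled_inv_chi2(0.0, 1.0, rng)
        with pytest.raises(ValueError):
            sample_scaled_inv_chi2(3.0, -1.0, rng)


class TestCenterGenotypes:
    def test_closed_form_column(self):
        Xc, f = center_genotypes(np.array([[0.0], [1.0], [2.0]]))
        assert f[0] == pytest.approx(0.5)
        assert np.allclose(Xc.ravel(), [-1, 0, 1])

    def test_monomorphic_column_zeroed(self):
        Xc, f = center_genotypes(np.zeros((3, 1)))
        assert f[0] == 0.0 and np.all(Xc == 0)

    def test_missing_imputed_at_mean(self):
        Xc, f = center_genotypes(np.array([[0.0], [np.nan], [2.0]]))
        assert f[0] == pytest.approx(0.5)
        assert np.allclose(Xc.ravel(), [-1, 0, 1])

    def test_column_means_zero_without_missingness(self, rng):
        X = rng.binomial(2, 0.3, (50, 20)).astype(float)
        Xc, _ = center_genotypes(X)
        assert np.max(np.abs(Xc.mean(axis=0))) < 1e-10

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            center_genotypes(np.full((4, 1), np.nan))

    def test_frequency_is_unfolded(self):
        # all-ALT column: coded-allele frequency 1, not folded to 0
        Xc, f = center_genotypes(np.full((5, 1), 2.0))
        assert f[0] == 1.0


class TestFullConditionals:
    """Each conditional, isolated so its draws are iid, vs its density."""

    def test_beta_conditional_is_the_stated_normal(self, rng):
        n = 60
        x = rng.normal(size=(n, 1))
        y = 0.4 * x[:, 0] + rng.normal(size=n)
        s_e2, s_b2 = 0.8, 0.3
        est = BayesianWGR(prior=WGRPrior(scale_beta=s_b2), n_iter=60_000,
                          burn_in=0, seed=42, include_intercept=False,
                          store_beta=True, fix_sigma_beta2=s_b2,
                          fix_sigma_eps2=s_e2)
        est.fit(x, y)
        c = 1.0 / (x[:, 0] @ x[:, 0] + s_e2 / s_b2)
        target = stats.norm(c * (x[:, 0] @ y), np.sqrt(s_e2 * c))
        ks = stats.kstest(est.chains_["beta"][:, 0], target.cdf)
        assert ks.pvalue > 0.001

    def test_mu_conditional_is_the_stated_normal(self, rng):
        n = 40
        y = rng.normal(1.5, 1.0, n)
        est = BayesianWGR(n_iter=60_000, burn_in=0, seed=7,
                          fix_sigma_eps2=0.9)
        est.fit(None, y)
        target = stats.norm(y.mean(), np.sqrt(0.9 / n))
        ks = stats.kstest(est.chains_["mu"], target.cdf)
        assert ks.pvalue > 0.001

    def test_sigma_eps_conditional_is_scaled_inv_chi2(self, rng):
        n = 30
        y = rng.normal(size=n)
        prior = WGRPrior(df_eps=5.0, scale_eps=0.8)
        est = BayesianWGR(prior=prior, n_iter=60_000, burn_in=0, seed=9,
                          include_intercept=False)
        est.fit(None, y)
        dfp = prior.df_eps + n
        sc = (y @ y + prior.df_eps * prior.scale_eps) / dfp
        target = stats.invgamma(dfp / 2, scale=dfp * sc / 2)
        ks = stats.kstest(est.chains_["sigma_eps2"], target.cdf)
        assert ks.pvalue > 0.001


class TestGibbsOracles:
    def test_covariates_only_matches_ols(self, rng):
        n = 150
        Z = np.column_stack([rng.uniform(30, 70, n),
                             rng.binomial(1, 0.5, n)]).astype(float)
        y = 0.02 * Z[:, 0] + 0.5 * Z[:, 1] + rng.normal(size=n)
        y = (y - y.mean()) / y.std(ddof=1)
        post = gibbs_fit(y, Z, None,
                         mcmc=MCMCConfig(n_iter=8_000, burn_in=1_000, seed=2))
        W = np.column_stack([np.ones(n), Z])
        ols = np.linalg.lstsq(W, y, rcond=None)[0]
        est = np.concatenate([[post.mu], post.gamma])
        chains = np.column_stack([post.chains["mu"], post.chains["gamma"]])
        for j in range(3):
            se = chains[:, j].std(ddof=1) / np.sqrt(_ess(chains[:, j]))
            assert abs(est[j] - ols[j]) < 3 * se + 1e-8

    def test_clamped_variances_match_ridge_solution(self, rng):
        n, L = 200, 100
        X = rng.binomial(2, rng.uniform(0.05, 0.5, L), (n, L)).astype(float)
        Xc, _ = center_genotypes(X)
        Z = rng.binomial(1, 0.4, (n, 2)).astype(float)
        beta_true = rng.normal(0, 0.05, L)
        y = Z @ [0.3, -0.2] + Xc @ beta_true + rng.normal(0, 0.8, n)
        y = (y - y.mean()) / y.std(ddof=1)
        s_e2, s_b2 = 0.7, 0.005
        est = BayesianWGR(prior=WGRPrior(scale_beta=s_b2), n_iter=12_000,
                          burn_in=2_000, seed=4, store_beta=True,
                          fix_sigma_eps2=s_e2, fix_sigma_beta2=s_b2)
        est.fit(Xc, y, Z=Z)
        # mixed-model equations: flat-prior effects, ridge on markers
        W = np.column_stack([np.ones(n), Z])
        lam = s_e2 / s_b2
        A = np.block([[W.T @ W, W.T @ Xc],
                      [Xc.T @ W, Xc.T @ Xc + lam * np.eye(L)]])
        sol = np.linalg.solve(A, np.concatenate([W.T @ y, Xc.T @ y]))
        got = np.concatenate([[est.mu_], est.gamma_, est.beta_])
        chains = np.column_stack([est.chains_["mu"], est.chains_["gamma"],
                                  est.chains_["beta"]])
        n_bad = 0
        for j in range(got.size):
            se = chains[:, j].std(ddof=1) / np.sqrt(_ess(chains[:, j]))
            if abs(got[j] - sol[j]) > 3 * se + 1e-9:
                n_bad += 1
        # 3-sigma bands miss ~0.3% of draws; allow a few of the 103 coords
        assert n_bad <= 3

    def test_same_seed_bit_identical_chains(self, small_cohort, short_mcmc):
        y, Z, Xc = (small_cohort[k] for k in ("y", "Z", "Xc"))
        a = gibbs_fit(y, Z, Xc, mcmc=short_mcmc)
        b = gibbs_fit(y, Z, Xc, mcmc=short_mcmc)
        assert np.array_equal(a.chains["sigma_eps2"], b.chains["sigma_eps2"])
        assert np.array_equal(a.beta, b.beta)
        assert a.r_squared == b.r_squared

    def test_chain_length_contract(self, small_cohort):
        y, Z = small_cohort["y"], small_cohort["Z"]
        post = gibbs_fit(y, Z, None,
                         mcmc=MCMCConfig(n_iter=900, burn_in=300, thin=3,
                                         seed=1))
        assert post.chains["sigma_eps2"].size == 200

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            BayesianWGR(n_iter=10, burn_in=0).fit(
                None, np.array([1.0]), Z=np.ones((1, 2)))


class TestDefaultPrior:
    def test_prior_mode_splits_variance(self, rng):
        Xc, _ = center_genotypes(rng.binomial(2, 0.3, (50, 10)).astype(float))
        p = default_prior(1.0, Xc, partition_r2=0.5)
        mode = p.df_eps * p.scale_eps / (p.df_eps + 2)
        assert mode == pytest.approx(0.5)
        implied = np.sum(np.var(Xc, axis=0)) * \
            p.df_beta * p.scale_beta / (p.df_beta - 2)
        assert implied == pytest.approx(0.5)

    def test_doubling_column_variance_halves_scale_beta(self, rng):
        Xc, _ = center_genotypes(rng.binomial(2, 0.3, (50, 10)).astype(float))
        p1 = default_prior(1.0, Xc, 0.5)
        p2 = default_prior(1.0, np.sqrt(2) * Xc, 0.5)
        assert p2.scale_beta == pytest.approx(p1.scale_beta / 2)

    def test_no_markers_no_scale_beta(self):
        p = default_prior(1.0, None, 0.5)
        assert p.scale_beta is None

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            default_prior(1.0, None, 1.0)


class TestRSquared:
    def test_identity_with_posterior_mean(self, small_cohort, short_mcmc):
        y, Z = small_cohort["y"], small_cohort["Z"]
        post = gibbs_fit(y, Z, None, mcmc=short_mcmc)
        assert post.r_squared == 1.0 - post.sigma_eps2
        assert r_squared(post) == post.r_squared

    def test_overfitting_bound_on_pure_noise(self):
        # no signal at all: the marker increment must stay modest
        rng = np.random.default_rng(123)
        n, L = 400, 500
        X = rng.binomial(2, rng.uniform(0.05, 0.5, L), (n, L)).astype(float)
        Xc, _ = center_genotypes(X)
        Z = np.column_stack([rng.uniform(30, 70, n),
                             rng.binomial(1, 0.5, n)]).astype(float)
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std(ddof=1)
        mc = MCMCConfig(n_iter=3_000, burn_in=1_000, seed=6)
        r_full = gibbs_fit(y, Z, Xc, mcmc=mc).r_squared
        r_cov = gibbs_fit(y, Z, None, mcmc=mc).r_squared
        assert r_full - r_cov < 0.15

    def test_split_chain_stationarity(self, small_cohort):
        y, Z, Xc = (small_cohort[k] for k in ("y", "Z", "Xc"))
        est = BayesianWGR(n_iter=4_000, burn_in=1_000, seed=8)
        est.fit(Xc, y, Z=Z)
        assert est.rhat("sigma_eps2") < 1.05
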