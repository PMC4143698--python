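"""Bayesian whole-genome regression fitted by Gibbs sampling.

The model regresses a unit-variance response on fixed nongenetic
covariates and on a (possibly large) set of centered marker dosages,

    y_i = mu + sum_j Z_ij gamma_j + sum_l x_il beta_l + eps_i,

with flat priors on the intercept and covariate effects, iid
N(0, sigma_beta^2) priors on the marker effects, and scaled-inverse-
chi-square priors on the two variance components.  Because the response
is standardized to unit variance, the proportion of phenotypic variance
captured by a model is summarised as R^2 = 1 - sigma_eps^2-hat, with
sigma_eps^2-hat the posterior mean of the residual variance.

The estimator follows scikit-learn conventions: hyperparameters at
construction, data at :meth:`BayesianWGR.fit`, fitted quantities in
trailing-underscore attributes, and full ``get_params``/``set_params``
support so it composes with sklearn model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._gibbs import fixed_sweep, marker_sweep

__all__ = [
    "WGRPrior",
    "MCMCConfig",
    "WGRPosterior",
    "BayesianWGR",
    "sample_scaled_inv_chi2",
    "center_genotypes",
    "default_prior",
    "gibbs_fit",
    "r_squared",
]


@dataclass(frozen=True)
class WGRPrior:
    """Scaled-inverse-chi-square hyperparameters for the two variances.

    ``scale_beta`` may be ``None`` for a covariates-only model (no
    markers, hence no marker-variance parameter).
    """

    df_beta: float = 5.0
    scale_beta: Optional[float] = None
    df_eps: float = 5.0
    scale_eps: float = 1.0

    def __post_init__(self) -> None:
        if self.df_beta <= 0 or self.df_eps <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if self.scale_eps <= 0:
            raise ValueError("scale_eps must be positive")
        if self.scale_beta is not None and self.scale_beta <= 0:
            raise ValueError("scale_beta must be positive when given")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length settings.

    Defaults keep 25,000 samples after a 15,000-iteration burn-in.
    """

    n_iter: int = 40_000
    burn_in: int = 15_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class WGRPosterior:
    """Posterior summaries and scalar chains from one Gibbs run."""

    mu: float
    gamma: np.ndarray
    beta: np.ndarray
    sigma_beta2: Optional[float]
    sigma_eps2: float
    r_squared: float
    chains: dict = field(repr=False)
    ess: dict = field(default_factory=dict)
    n_kept: int = 0
    seed: int = 0


def sample_scaled_inv_chi2(df: float, scale: float, rng: np.random.Generator, size=None):
    """Draw from a scaled-inverse-chi-square(df, scale) density.

    Uses the quantile-free construction df*scale / chi2_df.  Equivalent
    to an inverse-gamma(df/2, df*scale/2).
    """
    if df <= 0 or scale <= 0:
        raise ValueError("df and scale must be positive")
    return df * scale / rng.chisquare(df, size=size)


def center_genotypes(X: np.ndarray):
    """Center dosage columns at twice the coded-allele frequency.

    Each column l becomes ``x_il - 2 f_l`` where ``f_l`` is the
    (unfolded) frequency of the allele coded 1, estimated from the
    non-missing calls.  Missing dosages (NaN) are imputed at the column
    mean, i.e. 0 after centering.

    Returns
    -------
    Xc : float64 array, centered, no missing values.
    freq : per-column coded-allele frequency.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects x variants)")
    if X.shape[1] == 0:
        return X.copy(), np.empty(0)
    n_obs = np.sum(~np.isnan(X), axis=0)
    if np.any(n_obs == 0):
        bad = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"column {bad} has no observed genotypes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nansum(X, axis=0) / (2.0 * n_obs)
    Xc = X - 2.0 * freq
    Xc[np.isnan(Xc)] = 0.0
    return Xc, freq


def default_prior(var_y: float, Xc: Optional[np.ndarray], partition_r2: float = 0.5,
                  df: float = 5.0) -> WGRPrior:
    """Weakly informative prior splitting Var(y) between markers and noise.

    ``scale_eps`` is chosen so the prior mode of sigma_eps^2 equals
    ``(1 - partition_r2) * var_y``; ``scale_beta`` so that the implied
    prior marker variance ``sum_l var(x_l) * E[sigma_beta^2]`` equals
    ``partition_r2 * var_y``.  With no markers only the residual part is
    set and ``scale_beta`` is absent.
    """
    if not 0.0 < partition_r2 < 1.0:
        raise ValueError("partition_r2 must be in (0, 1)")
    # mode of scaled-inv-chi2(df, s) is df*s/(df+2)
    scale_eps = (1.0 - partition_r2) * var_y * (df + 2.0) / df
    scale_beta = None
    if Xc is not None and Xc.shape[1] > 0:
        sum_var = float(np.sum(np.var(Xc, axis=0)))
        if sum_var <= 0:
            raise ValueError("markers carry no variance; cannot set scale_beta")
        # mean of scaled-inv-chi2(df, s) is df*s/(df-2), df > 2
        scale_beta = partition_r2 * var_y * (df - 2.0) / (df * sum_var)
    return WGRPrior(df_beta=df, scale_beta=scale_beta, df_eps=df, scale_eps=scale_eps)


def r_squared(posterior_or_sigma) -> float:
    """Proportion of variance explained, 1 - sigma_eps^2-hat.

    Accepts either a :class:`WGRPosterior` or the residual-variance
    estimate itself.  Only meaningful when the response was standardized
    to unit variance.
    """
    if isinstance(posterior_or_sigma, WGRPosterior):
        return 1.0 - posterior_or_sigma.sigma_eps2
    return 1.0 - float(posterior_or_sigma)


class BayesianWGR(RegressorMixin, BaseEstimator):
    """Gibbs-sampled Bayesian ridge over markers with fixed covariates.

    Parameters
    ----------
    prior : WGRPrior or None
        Variance hyperparameters; if None, :func:`default_prior` is
        applied to the fit data with ``partition_r2``.
    n_iter, burn_in, thin : chain length controls (defaults keep 25,000
        post burn-in samples).
    seed : RNG seed; identical seed and inputs give bit-identical chains.
    partition_r2 : prior variance split used when ``prior`` is None.
    include_intercept : drop the intercept only for targeted conjugacy
        tests; the model in normal use always carries mu.
    store_beta : keep the full (n_kept, L) marker-effect chain.  Off by
        default (memory); the running posterior mean is always kept.
    fix_sigma_beta2, fix_sigma_eps2 : clamp a variance at this value
        instead of sampling it (used to compare against the closed-form
        ridge solution).
    estimator : "mean" or "median" summary of the sigma_eps^2 chain.
    refresh_every : recompute the residual from scratch every this many
        iterations to stop incremental floating-point drift.
    """

    def __init__(self, prior=None, n_iter=40_000, burn_in=15_000, thin=1, seed=0,
                 partition_r2=0.5, include_intercept=True, store_beta=False,
                 fix_sigma_beta2=None, fix_sigma_eps2=None, estimator="mean",
                 refresh_every=512):
        self.prior = prior
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.partition_r2 = partition_r2
        self.include_intercept = include_intercept
        self.store_beta = store_beta
        self.fix_sigma_beta2 = fix_sigma_beta2
        self.fix_sigma_eps2 = fix_sigma_eps2
        self.estimator = estimator
        self.refresh_every = refresh_every

    # ------------------------------------------------------------------
    def fit(self, X, y, Z=None):
        """Run the Gibbs sampler.

        Parameters
        ----------
        X : (n, L) centered marker matrix; may have L = 0 columns (or be
            None) for a covariates-only model.
        y : (n,) response, expected to have unit variance (warned if not).
        Z : (n, J) fixed covariates, optional.
        """
        y = np.asarray(y, dtype=np.float64).ravel()
        n = y.size
        if X is None:
            X = np.empty((n, 0))
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        if X.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        L = X.shape[1]
        if Z is None:
            Z = np.empty((n, 0))
        Z = np.asarray(Z, dtype=np.float64)
        if Z.shape[0] != n:
            raise ValueError("Z and y have incompatible shapes")

        cols = [np.ones((n, 1))] if self.include_intercept else []
        cols.append(Z)
        W = np.hstack(cols) if cols else np.empty((n, 0))
        J = W.shape[1]
        if n < J + 1:
            raise ValueError(f"n={n} too small for {J} fixed effects")
        vy = float(np.var(y, ddof=1)) if n > 1 else 0.0
        if abs(vy - 1.0) > 0.05:
            warnings.warn(
                f"response variance is {vy:.3f}, not 1; R^2 = 1 - sigma_eps^2 "
                "is only interpretable for a unit-variance response",
                UserWarning,
            )

        mcmc = MCMCConfig(n_iter=self.n_iter, burn_in=self.burn_in,
                          thin=self.thin, seed=self.seed)
        prior = self.prior
        if prior is None:
            prior = default_prior(vy if vy > 0 else 1.0, X, self.partition_r2)
        if L > 0 and prior.scale_beta is None and self.fix_sigma_beta2 is None:
            raise ValueError("prior.scale_beta required when markers are present")

        rng = np.random.default_rng(self.seed)
        xt = np.ascontiguousarray(X.T)
        xtx = np.einsum("li,li->l", xt, xt)
        wt = np.ascontiguousarray(W.T)
        wtw = np.einsum("ji,ji->j", wt, wt)
        if J and np.any(wtw == 0):
            raise ValueError("a fixed-effect column is identically zero")

        alpha = np.zeros(J)
        beta = np.zeros(L)
        sigma_e2 = self.fix_sigma_eps2 if self.fix_sigma_eps2 is not None \
            else float(prior.scale_eps)
        if L:
            sigma_b2 = self.fix_sigma_beta2 if self.fix_sigma_beta2 is not None \
                else float(prior.scale_beta)
        else:
            sigma_b2 = None
        e = y.copy()

        n_kept = mcmc.n_kept
        chain_mu = np.empty(n_kept) if self.include_intercept else None
        chain_gamma = np.empty((n_kept, Z.shape[1]))
        chain_se2 = np.empty(n_kept)
        chain_sb2 = np.empty(n_kept) if L else None
        chain_beta = np.empty((n_kept, L)) if (self.store_beta and L) else None
        beta_sum = np.zeros(L)
        gamma_sum = np.zeros(J)
        kept = 0

        for it in range(mcmc.n_iter):
            if J:
                zf = rng.standard_normal(J)
                fixed_sweep(wt, wtw, e, alpha, sigma_e2, zf)
            if L:
                zm = rng.standard_normal(L)
                marker_sweep(xt, xtx, e, beta, sigma_e2 / sigma_b2, sigma_e2, zm)
                if self.fix_sigma_beta2 is None:
                    dfp = prior.df_beta + L
                    sc = (beta @ beta + prior.df_beta * prior.scale_beta) / dfp
                    sigma_b2 = float(sample_scaled_inv_chi2(dfp, sc, rng))
            if self.fix_sigma_eps2 is None:
                dfp = prior.df_eps + n
                sc = (e @ e + prior.df_eps * prior.scale_eps) / dfp
                sigma_e2 = float(sample_scaled_inv_chi2(dfp, sc, rng))

            if self.refresh_every and (it + 1) % self.refresh_every == 0:
                e = y - W @ alpha
                if L:
                    e -= X @ beta

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                if self.include_intercept:
                    chain_mu[kept] = alpha[0]
                chain_gamma[kept] = alpha[1:] if self.include_intercept else alpha
                chain_se2[kept] = sigma_e2
                if L:
                    chain_sb2[kept] = sigma_b2
                    beta_sum += beta
                    if chain_beta is not None:
                        chain_beta[kept] = beta
                gamma_sum += alpha
                kept += 1

        summary = np.mean if self.estimator == "mean" else np.median
        se2_hat = float(summary(chain_se2))
        alpha_hat = gamma_sum / kept
        self.mu_ = float(alpha_hat[0]) if self.include_intercept else 0.0
        self.gamma_ = alpha_hat[1:] if self.include_intercept else alpha_hat
        self.beta_ = beta_sum / kept if L else np.empty(0)
        self.sigma_beta2_ = float(np.mean(chain_sb2)) if L else None
        self.sigma_eps2_ = se2_hat
        self.r_squared_ = 1.0 - se2_hat
        self.prior_ = prior
        self.n_kept_ = kept
        chains = {"sigma_eps2": chain_se2, "gamma": chain_gamma}
        if self.include_intercept:
            chains["mu"] = chain_mu
        if L:
            chains["sigma_beta2"] = chain_sb2
        if chain_beta is not None:
            chains["beta"] = chain_beta
        self.chains_ = chains
        self.n_features_in_ = L
        self.posterior_ = WGRPosterior(
            mu=self.mu_, gamma=self.gamma_, beta=self.beta_,
            sigma_beta2=self.sigma_beta2_, sigma_eps2=self.sigma_eps2_,
            r_squared=self.r_squared_, chains=chains, n_kept=kept,
            seed=self.seed,
        )
        return self

    # ------------------------------------------------------------------
    def predict(self, X, Z=None):
        """Posterior-mean linear predictor mu + Z gamma + X beta."""
        if not hasattr(self, "beta_"):
            raise AttributeError("estimator is not fitted")
        if X is None:
            n = len(Z)
            X = np.empty((n, 0))
        X = np.asarray(X, dtype=np.float64)
        out = np.full(X.shape[0], self.mu_)
        if X.shape[1]:
            out = out + X @ self.beta_
        if Z is not None and self.gamma_.size:
            out = out + np.asarray(Z, dtype=np.float64) @ self.gamma_
        return out

    def ess(self, var_names=("mu", "sigma_eps2", "sigma_beta2")) -> dict:
        """Effective sample size of the scalar chains (via arviz)."""
        import arviz as az

        out = {}
        for name in var_names:
            ch = self.chains_.get(name)
            if ch is None or ch.ndim != 1:
                continue
            out[name] = float(az.ess(ch[None, :]))
        self.ess_ = out
        return out

    def rhat(self, name="sigma_eps2") -> float:
        """Split-chain rank-normalized R-hat of one scalar chain."""
        import arviz as az

        ch = self.chains_[name]
        half = ch.size // 2
        split = np.stack([ch[:half], ch[half:2 * half]])
        return float(az.rhat(split))

    def plot_traces(self, outdir, names=("mu", "sigma_eps2", "sigma_beta2")):
        """Write PNG trace plots of the scalar chains; returns the paths."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in names:
            ch = self.chains_.get(name)
            if ch is None or ch.ndim != 1:
                continue
            fig, ax = plt.subplots(figsize=(7, 2.2))
            ax.plot(ch, lw=0.4)
            ax.set_xlabel("kept iteration")
            ax.set_ylabel(name)
            fig.tight_layout()
            p = outdir / f"trace_{name}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            paths.append(p)
        return paths


def gibbs_fit(y, Z, Xc, prior: Optional[WGRPrior] = None,
              mcmc: Optional[MCMCConfig] = None, **kwargs) -> WGRPosterior:
    """Functional wrapper: fit :class:`BayesianWGR` and return the posterior."""
    mcmc = mcmc or MCMCConfig()
    est = BayesianWGR(prior=prior, n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
                      thin=mcmc.thin, seed=mcmc.seed, **kwargs)
    est.fit(Xc, y, Z=Z)
    est.posterior_.ess = est.ess()
    return est.posterior_
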