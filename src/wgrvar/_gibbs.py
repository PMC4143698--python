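"""Numba kernels for the Gibbs sampler inner loops.

The marker sweep is sequential (each effect's full conditional depends on
the residual left by the previous update), so it cannot be vectorised;
it is compiled instead.  Random normal deviates are drawn outside the
kernel by the caller's Generator so that the whole chain is reproducible
from a single seed.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def marker_sweep(xt, xtx, e, beta, lam, sigma_e2, z):
    """One Gibbs sweep over all marker effects.

    Parameters
    ----------
    xt : (L, n) C-contiguous centered genotypes, markers in rows.
    xtx : (L,) precomputed diagonal of X'X.
    e : (n,) current residual y - W a - X b; updated in place.
    beta : (L,) current marker effects; updated in place.
    lam : shrinkage ratio sigma_e2 / sigma_b2.
    sigma_e2 : current residual variance.
    z : (L,) iid standard normal deviates for this sweep.
    """
    L, n = xt.shape
    for l in range(L):
        xl = xt[l]
        c = 1.0 / (xtx[l] + lam)
        # x_l' e_l where e_l restores this marker's own contribution
        xe = xtx[l] * beta[l]
        for i in range(n):
            xe += xl[i] * e[i]
        b_new = c * xe + z[l] * math.sqrt(sigma_e2 * c)
        d = beta[l] - b_new
        if d != 0.0:
            for i in range(n):
                e[i] += xl[i] * d
        beta[l] = b_new


@njit(cache=True)
def fixed_sweep(wt, wtw, e, alpha, sigma_e2, z):
    """One Gibbs sweep over intercept/covariate effects (flat priors)."""
    J, n = wt.shape
    for j in range(J):
        wj = wt[j]
        we = wtw[j] * alpha[j]
        for i in range(n):
            we += wj[i] * e[i]
        a_new = we / wtw[j] + z[j] * math.sqrt(sigma_e2 / wtw[j])
        d = alpha[j] - a_new
        if d != 0.0:
            for i in range(n):
                e[i] += wj[i] * d
        alpha[j] = a_new
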