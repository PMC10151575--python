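"""Numba kernels for the single-site Gibbs marker-effect updates.

The genotype matrix is passed Fortran-ordered so column slices are contiguous.
Each kernel seeds numba's own RNG from an integer drawn from the master
generator, keeping runs exactly reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def update_markers_univariate(
    M, e, beta, delta, xtx, sig2b, sigma2_e, incl_prob, bayes_b, nu, scale, seed
):
    """One sweep of single-site updates for all markers (threshold/linear model).

    Mixture prior: effect 0 with probability 1 - incl_prob, else normal with
    variance ``sig2b[j]`` (marker-specific when ``bayes_b``, common otherwise).
    The inclusion indicator is drawn from the marginalized ratio with the
    effect integrated out.  Residual vector ``e`` is kept in sync in place.
    Returns (number included, sum of squared included effects).
    """
    np.random.seed(seed)
    n, p = M.shape
    k_incl = 0
    ssq = 0.0
    log_prior_odds = 0.0
    certain = incl_prob >= 1.0
    if not certain:
        log_prior_odds = np.log(incl_prob) - np.log(1.0 - incl_prob)
    for j in range(p):
        if xtx[j] <= 1e-12:
            # monomorphic marker: forced out of the model
            if beta[j] != 0.0:
                b_old = beta[j]
                for i in range(n):
                    e[i] += M[i, j] * b_old
                beta[j] = 0.0
            delta[j] = 0
            continue
        b_old = beta[j]
        r = b_old * xtx[j]
        for i in range(n):
            r += M[i, j] * e[i]
        v_b = sig2b[j]
        lhs = xtx[j] / sigma2_e + 1.0 / v_b
        rhs = r / sigma2_e
        include = True
        if not certain:
            log_bf = 0.5 * (-np.log(v_b * lhs) + rhs * rhs / lhs)
            log_odds = log_prior_odds + log_bf
            if log_odds > 35.0:
                include = True
            elif log_odds < -35.0:
                include = False
            else:
                include = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
        if include:
            b_new = rhs / lhs + np.random.normal() / np.sqrt(lhs)
            delta[j] = 1
            k_incl += 1
            ssq += b_new * b_new
        else:
            b_new = 0.0
            delta[j] = 0
        diff = b_new - b_old
        if diff != 0.0:
            for i in range(n):
                e[i] -= M[i, j] * diff
        beta[j] = b_new
        if bayes_b:
            # marker-specific variance: scaled-inv-chi2 conditional update
            df = nu + delta[j]
            sig2b[j] = (nu * scale + b_new * b_new) / np.random.chisquare(df)
    return k_incl, ssq


@njit(cache=True, fastmath=True)
def update_markers_bivariate(M, E, B, xtx, Ginv, Rinv, seed):
    """One sweep of joint two-trait effect updates for all markers (Bayes-C0).

    ``E`` is the n x 2 residual matrix, ``B`` the p x 2 effect matrix.  The
    conditional for marker j's effect pair is MVN with precision
    ``xtx_j * Rinv + Ginv``.  Returns B'B (2x2 upper-triangular sums).
    """
    np.random.seed(seed)
    n, p = M.shape
    s11 = 0.0
    s12 = 0.0
    s22 = 0.0
    for j in range(p):
        if xtx[j] <= 1e-12:
            for t in range(2):
                if B[j, t] != 0.0:
                    for i in range(n):
                        E[i, t] += M[i, j] * B[j, t]
                    B[j, t] = 0.0
            continue
        b0 = B[j, 0]
        b1 = B[j, 1]
        r0 = b0 * xtx[j]
        r1 = b1 * xtx[j]
        for i in range(n):
            r0 += M[i, j] * E[i, 0]
            r1 += M[i, j] * E[i, 1]
        # rhs = Rinv @ r
        rhs0 = Rinv[0, 0] * r0 + Rinv[0, 1] * r1
        rhs1 = Rinv[1, 0] * r0 + Rinv[1, 1] * r1
        # precision = xtx * Rinv + Ginv
        p00 = xtx[j] * Rinv[0, 0] + Ginv[0, 0]
        p01 = xtx[j] * Rinv[0, 1] + Ginv[0, 1]
        p11 = xtx[j] * Rinv[1, 1] + Ginv[1, 1]
        det = p00 * p11 - p01 * p01
        # mean = precision^-1 @ rhs
        m0 = (p11 * rhs0 - p01 * rhs1) / det
        m1 = (p00 * rhs1 - p01 * rhs0) / det
        # sample MVN(m, precision^-1) via Cholesky of the precision:
        # if L L' = P then x = m + L'^{-1} z
        l00 = np.sqrt(p00)
        l10 = p01 / l00
        l11 = np.sqrt(p11 - l10 * l10)
        z0 = np.random.normal()
        z1 = np.random.normal()
        # solve L' u = z  (upper triangular back-substitution)
        u1 = z1 / l11
        u0 = (z0 - l10 * u1) / l00
        bn0 = m0 + u0
        bn1 = m1 + u1
        d0 = bn0 - b0
        d1 = bn1 - b1
        if d0 != 0.0 or d1 != 0.0:
            for i in range(n):
                E[i, 0] -= M[i, j] * d0
                E[i, 1] -= M[i, j] * d1
        B[j, 0] = bn0
        B[j, 1] = bn1
        s11 += bn0 * bn0
        s12 += bn0 * bn1
        s22 += bn1 * bn1
    return s11, s12, s22
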