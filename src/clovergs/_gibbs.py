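"""Numba-compiled Gibbs sampler for BayesCpi whole-genome regression.

The model is y = 1*mu + X beta + e with spike-and-slab marker effects:
each marker is included with probability pi_in, included effects share a
common slab variance sigma2_b, and sigma2_b / sigma2_e carry scaled-inverse
chi-square priors.  pi_in has a uniform prior (Beta(1,1) conjugate update).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bayes_c_pi_gibbs(
    Xt: np.ndarray,  # m x n, markers in rows (centred, imputed)
    y: np.ndarray,
    iterations: int,
    burn_in: int,
    thin: int,
    df_prior: float,
    scale_b: float,
    scale_e: float,
    seed: int,
):
    np.random.seed(seed)
    m, n = Xt.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx[j] = s

    mu = y.mean()
    e = y - mu
    beta = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    sigma2_b = scale_b
    sigma2_e = max(e.var(), 1e-8) * 0.5
    pi_in = 0.5

    n_saved = 0
    beta_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    pi_sum = 0.0
    s2b_sum = 0.0
    s2e_sum = 0.0
    g_sum = np.zeros(n)
    g_sumsq = np.zeros(n)
    n_in_sum = 0.0

    for it in range(iterations):
        # intercept
        e += mu
        mu = e.mean() + np.random.normal() * np.sqrt(sigma2_e / n)
        e -= mu

        # marker effects with spike-and-slab indicator
        log_odds_prior = np.log(pi_in) - np.log(1.0 - pi_in)
        n_in = 0
        sum_b2 = 0.0
        for j in range(m):
            xx = xtx[j]
            if xx <= 0.0:
                continue
            if delta[j] == 1:
                for i in range(n):
                    e[i] += Xt[j, i] * beta[j]
            rhs = 0.0
            for i in range(n):
                rhs += Xt[j, i] * e[i]
            v1 = xx * sigma2_b + sigma2_e
            log_bf = 0.5 * (
                -np.log(v1 / sigma2_e) + rhs * rhs * sigma2_b / (sigma2_e * v1)
            )
            prob = 1.0 / (1.0 + np.exp(-(log_odds_prior + log_bf)))
            if np.random.random() < prob:
                c = xx + sigma2_e / sigma2_b
                b = rhs / c + np.random.normal() * np.sqrt(sigma2_e / c)
                beta[j] = b
                delta[j] = 1
                n_in += 1
                sum_b2 += b * b
                for i in range(n):
                    e[i] -= Xt[j, i] * b
            else:
                beta[j] = 0.0
                delta[j] = 0

        # variances (scaled-inverse chi-square via chi-square draw)
        sigma2_b = (sum_b2 + df_prior * scale_b) / np.random.chisquare(
            df_prior + n_in
        )
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2_e = (sse + df_prior * scale_e) / np.random.chisquare(df_prior + n)
        if not np.isfinite(sigma2_e) or not np.isfinite(sigma2_b) or sigma2_e > 1e12:
            raise RuntimeError("BayesCpi chain diverged: variance overflow")
        pi_in = np.random.beta(1.0 + n_in, 1.0 + m - n_in)

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_saved += 1
            mu_sum += mu
            pi_sum += pi_in
            s2b_sum += sigma2_b
            s2e_sum += sigma2_e
            n_in_sum += n_in
            for j in range(m):
                beta_sum[j] += beta[j]
                incl_sum[j] += delta[j]
            for i in range(n):
                g = y[i] - mu - e[i]
                g_sum[i] += g
                g_sumsq[i] += g * g

    beta_mean = beta_sum / n_saved
    incl_prob = incl_sum / n_saved
    g_mean = g_sum / n_saved
    g_var = g_sumsq / n_saved - g_mean**2
    g_sd = np.sqrt(np.maximum(g_var, 0.0))
    return (
        beta_mean,
        incl_prob,
        mu_sum / n_saved,
        pi_sum / n_saved,
        s2b_sum / n_saved,
        s2e_sum / n_saved,
        g_mean,
        g_sd,
        n_in_sum / n_saved,
    )
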