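"""Numba-compiled Gibbs sampler for the BayesB marker model.

Model: y = W alpha + sum_j delta_j Z_j u_j + e, with a point mass at zero
(probability pi) on each marker effect, marker-specific scaled-inverse-
chi-square variances, and conjugate updates throughout.  The chain is
fully reproducible from the seed.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs(y, W, Zt, zz, ww, n_iter, burn, nu, S0, nu_e, Se,
          pi0, kappa, fix_pi, common_var, seed):
    np.random.seed(seed)
    n = y.shape[0]
    p = W.shape[1]
    m = Zt.shape[0]
    alpha = np.zeros(p)
    u = np.zeros(m)
    delta = np.zeros(m, np.int64)
    sig2 = np.full(m, S0 * nu / (nu - 2.0))
    pi = pi0 if fix_pi < 0.0 else fix_pi
    s2e = Se if Se > 0.0 else 1.0
    e = y.copy()

    n_keep = n_iter - burn
    sum_alpha = np.zeros(p)
    sum_u = np.zeros(m)
    sum_delta = np.zeros(m)
    sum_pi = 0.0
    s2e_chain = np.zeros(n_keep)
    err_iter = -1

    for it in range(n_iter):
        # fixed effects (flat prior)
        for k in range(p):
            ak = alpha[k]
            c = ww[k]
            r = 0.0
            for i in range(n):
                e[i] += W[i, k] * ak
                r += W[i, k] * e[i]
            mean = r / c
            ak = mean + np.sqrt(s2e / c) * np.random.standard_normal()
            alpha[k] = ak
            for i in range(n):
                e[i] -= W[i, k] * ak
        # markers
        for j in range(m):
            c = zz[j]
            if c <= 0.0:
                delta[j] = 0
                u[j] = 0.0
                continue
            uj = u[j]
            if delta[j] == 1:
                r = 0.0
                for i in range(n):
                    e[i] += Zt[j, i] * uj
                    r += Zt[j, i] * e[i]
            else:
                r = 0.0
                for i in range(n):
                    r += Zt[j, i] * e[i]
            v = 1.0 / (c / s2e + 1.0 / sig2[j])
            mean = v * r / s2e
            logbf = 0.5 * (np.log(v) - np.log(sig2[j])) + 0.5 * mean * mean / v
            if pi <= 0.0:
                pin = 1.0
            elif pi >= 1.0:
                pin = 0.0
            else:
                lo = logbf + np.log(1.0 - pi) - np.log(pi)
                if lo > 35.0:
                    pin = 1.0
                elif lo < -35.0:
                    pin = 0.0
                else:
                    pin = 1.0 / (1.0 + np.exp(-lo))
            if np.random.random() < pin:
                delta[j] = 1
                uj = mean + np.sqrt(v) * np.random.standard_normal()
                u[j] = uj
                for i in range(n):
                    e[i] -= Zt[j, i] * uj
            else:
                delta[j] = 0
                u[j] = 0.0
        # marker variances
        if common_var:
            ssq = 0.0
            nin = 0
            for j in range(m):
                if delta[j] == 1:
                    ssq += u[j] * u[j]
                    nin += 1
            sv = (nu * S0 + ssq) / np.random.chisquare(nu + nin)
            for j in range(m):
                sig2[j] = sv
        else:
            for j in range(m):
                if delta[j] == 1:
                    sig2[j] = (nu * S0 + u[j] * u[j]) / np.random.chisquare(nu + 1.0)
                else:
                    sig2[j] = nu * S0 / np.random.chisquare(nu)
        # mixture probability
        nin = 0
        for j in range(m):
            nin += delta[j]
        if fix_pi < 0.0:
            pi = np.random.beta(kappa * pi0 + (m - nin), kappa * (1.0 - pi0) + nin)
        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        s2e = (sse + nu_e * Se) / np.random.chisquare(nu_e + n)
        if not np.isfinite(s2e):
            err_iter = it
            break
        if it >= burn:
            for k in range(p):
                sum_alpha[k] += alpha[k]
            for j in range(m):
                sum_u[j] += u[j]
                sum_delta[j] += delta[j]
            sum_pi += pi
            s2e_chain[it - burn] = s2e

    return sum_alpha, sum_u, sum_delta, sum_pi, s2e_chain, err_iter
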