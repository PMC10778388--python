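"""Numba Gibbs/Metropolis kernels for the Bayesian whole-genome regressions.

Each kernel runs a full single-site sweep over loci per iteration with
residual updating, in the classic order: overall mean, marker effects,
hyperparameters, residual variance.  Kernels are deterministic given the
seed.  They return thinned post-burn-in samples plus per-locus posterior
tallies; a negative ``err_iter`` means the chain stayed finite throughout.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _dot_col(Z, j, e, n):
    s = 0.0
    for i in range(n):
        s += Z[i, j] * e[i]
    return s


@njit(cache=True)
def _axpy_col(Z, j, e, a, n):
    for i in range(n):
        e[i] += Z[i, j] * a


@njit(cache=True)
def _rinvgauss(mu, lam):
    v = np.random.normal() ** 2
    x = mu + mu * mu * v / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * v + mu * mu * v * v)
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def bayesb_kernel(y, Z, zsq, pi, nu, S, n_iter, burn, thin, seed):
    np.random.seed(seed)
    n, m = Z.shape
    T = (n_iter - burn) // thin
    g = np.zeros(m)
    delta = np.zeros(m, np.int64)
    v = np.zeros(m)
    mu = y.mean()
    e = y - mu
    sige = e.dot(e) / n
    g_out = np.zeros((T, m))
    mu_out = np.zeros(T)
    sige_out = np.zeros(T)
    incl = np.zeros(m)
    t_idx = 0
    err_iter = -1
    for it in range(1, n_iter + 1):
        ebar = e.mean()
        mu_new = mu + ebar + np.random.normal() * np.sqrt(sige / n)
        for i in range(n):
            e[i] -= mu_new - mu
        mu = mu_new
        for j in range(m):
            if zsq[j] < 1e-12:
                continue
            rhs = _dot_col(Z, j, e, n) + zsq[j] * g[j]
            var0 = zsq[j] * sige
            if delta[j] == 1:
                var_cur = var0 + zsq[j] * zsq[j] * v[j]
            else:
                var_cur = var0
            ll_cur = -0.5 * np.log(var_cur) - 0.5 * rhs * rhs / var_cur
            if np.random.random() < 1.0 - pi:
                d_prop = 1
                v_prop = nu * S / np.random.chisquare(nu)
                var_prop = var0 + zsq[j] * zsq[j] * v_prop
            else:
                d_prop = 0
                v_prop = 0.0
                var_prop = var0
            ll_prop = -0.5 * np.log(var_prop) - 0.5 * rhs * rhs / var_prop
            if np.log(np.random.random() + 1e-300) < ll_prop - ll_cur:
                delta[j] = d_prop
                v[j] = v_prop
            old = g[j]
            if delta[j] == 1 and v[j] > 0.0:
                c = zsq[j] + sige / v[j]
                g[j] = rhs / c + np.random.normal() * np.sqrt(sige / c)
            else:
                g[j] = 0.0
            if g[j] != old:
                _axpy_col(Z, j, e, old - g[j], n)
        sse = e.dot(e)
        sige = sse / np.random.chisquare(n)
        if not np.isfinite(sige) or sige <= 0.0:
            err_iter = it
            break
        if it > burn and (it - burn) % thin == 0:
            for j in range(m):
                g_out[t_idx, j] = g[j]
                incl[j] += delta[j]
            mu_out[t_idx] = mu
            sige_out[t_idx] = sige
            t_idx += 1
    return g_out, mu_out, sige_out, incl / max(T, 1), err_iter


@njit(cache=True)
def bayeslasso_kernel(y, Z, zsq, lam2_init, a_lam, b_lam, sample_lambda,
                      n_iter, burn, thin, seed):
    np.random.seed(seed)
    n, m = Z.shape
    T = (n_iter - burn) // thin
    g = np.zeros(m)
    tau2 = np.full(m, 2.0 / lam2_init)
    lam2 = lam2_init
    mu = y.mean()
    e = y - mu
    sige = e.dot(e) / n
    g_out = np.zeros((T, m))
    mu_out = np.zeros(T)
    sige_out = np.zeros(T)
    lam2_out = np.zeros(T)
    n_floor = 0
    t_idx = 0
    err_iter = -1
    for it in range(1, n_iter + 1):
        ebar = e.mean()
        mu_new = mu + ebar + np.random.normal() * np.sqrt(sige / n)
        for i in range(n):
            e[i] -= mu_new - mu
        mu = mu_new
        tau_sum = 0.0
        for j in range(m):
            if zsq[j] < 1e-12:
                continue
            rhs = _dot_col(Z, j, e, n) + zsq[j] * g[j]
            c = zsq[j] + sige / tau2[j]
            old = g[j]
            g[j] = rhs / c + np.random.normal() * np.sqrt(sige / c)
            if g[j] != old:
                _axpy_col(Z, j, e, old - g[j], n)
            # locus variance: 1/tau2 | g ~ InvGauss(sqrt(lam2/g^2), lam2)
            g2 = g[j] * g[j]
            if g2 > 1e-20:
                inv_t = _rinvgauss(np.sqrt(lam2 / g2), lam2)
                tau2[j] = 1.0 / inv_t
            else:
                tau2[j] = np.random.exponential(2.0 / lam2)
            if tau2[j] < 1e-12:
                tau2[j] = 1e-12
                n_floor += 1
            tau_sum += tau2[j]
        if sample_lambda == 1:
            lam2 = np.random.gamma(a_lam + m, 1.0 / (b_lam + 0.5 * tau_sum))
        sse = e.dot(e)
        sige = sse / np.random.chisquare(n)
        if not np.isfinite(sige) or sige <= 0.0 or not np.isfinite(lam2):
            err_iter = it
            break
        if it > burn and (it - burn) % thin == 0:
            for j in range(m):
                g_out[t_idx, j] = g[j]
            mu_out[t_idx] = mu
            sige_out[t_idx] = sige
            lam2_out[t_idx] = lam2
            t_idx += 1
    return g_out, mu_out, sige_out, lam2_out, n_floor, err_iter


@njit(cache=True)
def bayesr_kernel(y, Z, zsq, gam, pi_init, nu0, S0, sample_sigg, sample_pi,
                  sample_mu, sample_sige, sige_init,
                  n_iter, burn, thin, seed):
    np.random.seed(seed)
    n, m = Z.shape
    K = gam.size
    T = (n_iter - burn) // thin
    g = np.zeros(m)
    comp = np.zeros(m, np.int64)
    pi = pi_init.copy()
    mu = y.mean() if sample_mu == 1 else 0.0
    e = y - mu
    sige = e.dot(e) / n if sige_init <= 0.0 else sige_init
    sigg = S0 * nu0 / max(nu0 - 2.0, 1.0)
    g_out = np.zeros((T, m))
    mu_out = np.zeros(T)
    sige_out = np.zeros(T)
    sigg_out = np.zeros(T)
    pi_out = np.zeros((T, K))
    comp_tally = np.zeros((m, K))
    logp = np.zeros(K)
    t_idx = 0
    err_iter = -1
    for it in range(1, n_iter + 1):
        if sample_mu == 1:
            ebar = e.mean()
            mu_new = mu + ebar + np.random.normal() * np.sqrt(sige / n)
            for i in range(n):
                e[i] -= mu_new - mu
            mu = mu_new
        counts = np.zeros(K)
        for j in range(m):
            if zsq[j] < 1e-12:
                continue
            rhs = _dot_col(Z, j, e, n) + zsq[j] * g[j]
            mx = -1e300
            for c in range(K):
                vc = gam[c] * sigg
                var_c = zsq[j] * sige + zsq[j] * zsq[j] * vc
                logp[c] = np.log(pi[c] + 1e-300) - 0.5 * np.log(var_c) \
                    - 0.5 * rhs * rhs / var_c
                if logp[c] > mx:
                    mx = logp[c]
            tot = 0.0
            for c in range(K):
                logp[c] = np.exp(logp[c] - mx)
                tot += logp[c]
            u = np.random.random() * tot
            acc = 0.0
            cj = K - 1
            for c in range(K):
                acc += logp[c]
                if u <= acc:
                    cj = c
                    break
            comp[j] = cj
            counts[cj] += 1.0
            old = g[j]
            vc = gam[cj] * sigg
            if vc > 0.0:
                cc = zsq[j] + sige / vc
                g[j] = rhs / cc + np.random.normal() * np.sqrt(sige / cc)
            else:
                g[j] = 0.0
            if g[j] != old:
                _axpy_col(Z, j, e, old - g[j], n)
        if sample_pi == 1:
            tot = 0.0
            for c in range(K):
                pi[c] = np.random.gamma(1.0 + counts[c], 1.0)
                tot += pi[c]
            for c in range(K):
                pi[c] /= tot
        if sample_sigg == 1:
            ssq = 0.0
            nnz = 0.0
            for j in range(m):
                if comp[j] > 0 and gam[comp[j]] > 0.0:
                    ssq += g[j] * g[j] / gam[comp[j]]
                    nnz += 1.0
            sigg = (ssq + nu0 * S0) / np.random.chisquare(nu0 + nnz)
        if sample_sige == 1:
            sse = e.dot(e)
            sige = sse / np.random.chisquare(n)
        if not np.isfinite(sige) or sige <= 0.0 or not np.isfinite(sigg):
            err_iter = it
            break
        if it > burn and (it - burn) % thin == 0:
            for j in range(m):
                g_out[t_idx, j] = g[j]
                comp_tally[j, comp[j]] += 1.0
            mu_out[t_idx] = mu
            sige_out[t_idx] = sige
            sigg_out[t_idx] = sigg
            for c in range(K):
                pi_out[t_idx, c] = pi[c]
            t_idx += 1
    return (g_out, mu_out, sige_out, sigg_out, pi_out,
            comp_tally / max(T, 1), err_iter)
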