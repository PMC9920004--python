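"""Numba kernels for maximum-likelihood fitting of the functional-mapping model.

The joint residual covariance Sigma = Lambda Sigma_eps Lambda' has a unit
lower-triangular Lambda, so the likelihood factors exactly through the
innovation (whitened) representation: along each density's week grid,

    z_k = (r_k - phi^(t_k - t_prev) * r_prev) / sqrt(v_k),
    v_k = sum over grid weeks t_m in (t_prev, t_k] of phi^(2 (t_k - t_m)),

with r the residual y - alpha * x**beta, t_prev the progeny's previous
observed week, and the v_k > 1 terms arising when intermediate weeks are
missing (this equals row/column deletion of the dense Sigma, by the Markov
property of SAD(1)).  The scale alpha of every genotype-by-density group
enters the whitened residual linearly and the innovation variance sigma2
multiplies the whole covariance, so both are profiled out in closed form.
What remains is a low-dimensional search over the beta exponents and
(phi_high, phi_low), done by Nelder-Mead.

Hypothesis coding via the (genotype, density) lookup tables ``beta_of`` and
``agrp_of``:

    H1 (genotype x density)        beta_of = [[0,1],[2,3]]  (6 free params)
    H0 pooled over genotypes       beta_of = [[0,1],[0,1]]  (4 free params)
    H0 equal across densities      beta_of = [[0,0],[1,1]]  (4 free params)

Profiled objective minimized: f = N log RSS_w + sum_k log v_k, equivalent
to -2 logL up to constants; logL is recovered afterwards.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# hypothesis lookup tables, row = genotype j, column = density (0=high, 1=low)
BETA_OF = {
    "H1": np.array([[0, 1], [2, 3]], dtype=np.int64),
    "H0-pooled": np.array([[0, 1], [0, 1]], dtype=np.int64),
    "H0-density-equal": np.array([[0, 0], [1, 1]], dtype=np.int64),
}
N_GROUPS = {"H1": 4, "H0-pooled": 2, "H0-density-equal": 2}

_BIG = 1e300


@njit(cache=False)
def _objective(params, beta_of, n_agrp, y_h, lx_h, t_h, y_l, lx_l, t_l, geno):
    """Profiled -2logL surrogate; also returns the profiling accumulators."""
    n_beta = params.shape[0] - 2
    sgg = np.zeros(n_agrp)
    sgy = np.zeros(n_agrp)
    syy = np.zeros(n_agrp)
    lv = 0.0
    n_obs = 0
    n = geno.shape[0]
    for d in range(2):
        if d == 0:
            y, lx, t, phi = y_h, lx_h, t_h, params[n_beta]
        else:
            y, lx, t, phi = y_l, lx_l, t_l, params[n_beta + 1]
        T = t.shape[0]
        # phi powers over all week differences, computed once per call
        pm = np.zeros((T, T))
        for k in range(T):
            for m in range(k):
                pm[k, m] = phi ** (t[k] - t[m])
        for i in range(n):
            j = geno[i]
            if j < 0:
                continue
            b = params[beta_of[j, d]]
            a = beta_of[j, d]  # alpha group follows the beta group
            prev = -1
            y_prev = 0.0
            g_prev = 0.0
            for k in range(T):
                yv = y[i, k]
                lxv = lx[i, k]
                if not (np.isfinite(yv) and np.isfinite(lxv)):
                    continue
                v = 1.0  # innovation at t_k itself
                for m in range(prev + 1, k):
                    v += pm[k, m] * pm[k, m]
                if v <= 0.0 or not np.isfinite(v):
                    return _BIG, sgg, sgy, syy, 1.0, 1
                g = np.exp(b * lxv)
                if prev >= 0:
                    c = pm[k, prev]
                    zy = yv - c * y_prev
                    zg = g - c * g_prev
                else:
                    zy = yv
                    zg = g
                sgg[a] += zg * zg / v
                sgy[a] += zg * zy / v
                syy[a] += zy * zy / v
                lv += np.log(v)
                n_obs += 1
                prev = k
                y_prev = yv
                g_prev = g
    rss = 0.0
    for a in range(n_agrp):
        if sgg[a] > 0.0:
            rss += syy[a] - sgy[a] * sgy[a] / sgg[a]
        else:
            rss += syy[a]
    if rss <= 0.0:
        rss = 1e-300
    f = n_obs * np.log(rss) + lv
    if not np.isfinite(f):
        f = _BIG
    return f, sgg, sgy, syy, rss, n_obs


@njit(cache=False)
def _nelder_mead(x0, steps, beta_of, n_agrp,
                 y_h, lx_h, t_h, y_l, lx_l, t_l, geno,
                 fatol, xatol, maxiter):
    """Plain Nelder-Mead on the profiled objective (no derivatives needed)."""
    m = x0.shape[0]
    sim = np.empty((m + 1, m))
    fv = np.empty(m + 1)
    sim[0] = x0
    for i in range(m):
        sim[i + 1] = x0.copy()
        sim[i + 1, i] += steps[i]
    for i in range(m + 1):
        fv[i] = _objective(sim[i], beta_of, n_agrp,
                           y_h, lx_h, t_h, y_l, lx_l, t_l, geno)[0]
    n_eval = m + 1
    while n_eval < maxiter:
        order = np.argsort(fv)
        sim = sim[order]
        fv = fv[order]
        # convergence on both function spread and simplex size
        fspread = fv[m] - fv[0]
        xspread = 0.0
        for i in range(1, m + 1):
            for k in range(m):
                dx = abs(sim[i, k] - sim[0, k])
                if dx > xspread:
                    xspread = dx
        if fspread <= fatol and xspread <= xatol:
            break
        centroid = np.zeros(m)
        for i in range(m):
            centroid += sim[i]
        centroid /= m
        xr = centroid + (centroid - sim[m])
        fr = _objective(xr, beta_of, n_agrp,
                        y_h, lx_h, t_h, y_l, lx_l, t_l, geno)[0]
        n_eval += 1
        if fr < fv[0]:
            xe = centroid + 2.0 * (centroid - sim[m])
            fe = _objective(xe, beta_of, n_agrp,
                            y_h, lx_h, t_h, y_l, lx_l, t_l, geno)[0]
            n_eval += 1
            if fe < fr:
                sim[m] = xe
                fv[m] = fe
            else:
                sim[m] = xr
                fv[m] = fr
        elif fr < fv[m - 1]:
            sim[m] = xr
            fv[m] = fr
        else:
            if fr < fv[m]:
                xc = centroid + 0.5 * (xr - centroid)
            else:
                xc = centroid + 0.5 * (sim[m] - centroid)
            fc = _objective(xc, beta_of, n_agrp,
                            y_h, lx_h, t_h, y_l, lx_l, t_l, geno)[0]
            n_eval += 1
            if fc < min(fr, fv[m]):
                sim[m] = xc
                fv[m] = fc
            else:  # shrink toward the best vertex
                for i in range(1, m + 1):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    fv[i] = _objective(sim[i], beta_of, n_agrp,
                                       y_h, lx_h, t_h, y_l, lx_l, t_l, geno)[0]
                n_eval += m
    order = np.argsort(fv)
    return sim[order[0]], fv[order[0]], n_eval


@njit(cache=False)
def _ols_beta_init(beta_of, n_beta, ly_h, lx_h, ly_l, lx_l, geno):
    """Log-log least-squares slope per beta group (pooled over its cells)."""
    s1 = np.zeros(n_beta)
    sx = np.zeros(n_beta)
    sy = np.zeros(n_beta)
    sxx = np.zeros(n_beta)
    sxy = np.zeros(n_beta)
    n = geno.shape[0]
    for d in range(2):
        if d == 0:
            ly, lx = ly_h, lx_h
        else:
            ly, lx = ly_l, lx_l
        T = ly.shape[1]
        for i in range(n):
            j = geno[i]
            if j < 0:
                continue
            g = beta_of[j, d]
            for k in range(T):
                a = lx[i, k]
                b = ly[i, k]
                if np.isfinite(a) and np.isfinite(b):
                    s1[g] += 1.0
                    sx[g] += a
                    sy[g] += b
                    sxx[g] += a * a
                    sxy[g] += a * b
    betas = np.ones(n_beta)
    logas = np.zeros(n_beta)
    for g in range(n_beta):
        if s1[g] > 1.0:
            var = sxx[g] - sx[g] * sx[g] / s1[g]
            if var > 1e-12:
                betas[g] = (sxy[g] - sx[g] * sy[g] / s1[g]) / var
            logas[g] = (sy[g] - betas[g] * sx[g]) / s1[g]
    return betas, logas


@njit(cache=False)
def _lag1_phi_init(beta_of, betas, logas, y_h, lx_h, t_h, y_l, lx_l, t_l, geno):
    """Lag-1 autoregression of the OLS-init residuals, per density."""
    phis = np.empty(2)
    n = geno.shape[0]
    for d in range(2):
        if d == 0:
            y, lx = y_h, lx_h
        else:
            y, lx = y_l, lx_l
        T = y.shape[1]
        s01 = 0.0
        s00 = 0.0
        for i in range(n):
            j = geno[i]
            if j < 0:
                continue
            g = beta_of[j, d]
            r_prev = np.nan
            for k in range(T):
                yv = y[i, k]
                lxv = lx[i, k]
                if np.isfinite(yv) and np.isfinite(lxv):
                    r = yv - np.exp(logas[g] + betas[g] * lxv)
                    if np.isfinite(r_prev):
                        s01 += r * r_prev
                        s00 += r_prev * r_prev
                    r_prev = r
                else:
                    r_prev = np.nan
        phis[d] = s01 / s00 if s00 > 0.0 else 0.5
        if phis[d] > 2.0:
            phis[d] = 2.0
        elif phis[d] < -2.0:
            phis[d] = -2.0
    return phis


@njit(cache=False)
def _fit_hypothesis(beta_of, n_beta, y_h, lx_h, ly_h, t_h, y_l, lx_l, ly_l, t_l,
                    geno, fatol, xatol, maxiter, n_starts):
    """Multi-start Nelder-Mead fit; returns (params, objective, n_eval_total)."""
    m = n_beta + 2
    b0, la0 = _ols_beta_init(beta_of, n_beta, ly_h, lx_h, ly_l, lx_l, geno)
    p0 = _lag1_phi_init(beta_of, b0, la0, y_h, lx_h, t_h, y_l, lx_l, t_l, geno)
    starts = np.empty((3, m))
    for g in range(n_beta):
        starts[0, g] = b0[g]
        starts[1, g] = b0[g]
        starts[2, g] = b0[g] + 0.15
    starts[0, n_beta] = p0[0]
    starts[0, n_beta + 1] = p0[1]
    starts[1, n_beta] = 0.0
    starts[1, n_beta + 1] = 0.0
    starts[2, n_beta] = 0.5 * p0[0] + 0.45
    starts[2, n_beta + 1] = 0.5 * p0[1] + 0.45
    steps = np.empty(m)
    for g in range(n_beta):
        steps[g] = 0.1
    steps[n_beta] = 0.25
    steps[n_beta + 1] = 0.25
    best_f = np.inf
    best_x = starts[0].copy()
    total_eval = 0
    for s in range(min(n_starts, 3)):
        x, f, ne = _nelder_mead(starts[s], steps, beta_of, n_beta,
                                y_h, lx_h, t_h, y_l, lx_l, t_l, geno,
                                fatol, xatol, maxiter)
        total_eval += ne
        if f < best_f:
            best_f = f
            best_x = x
    return best_x, best_f, total_eval


@njit(cache=False)
def _loglik_from_objective(params, beta_of, n_agrp,
                           y_h, lx_h, t_h, y_l, lx_l, t_l, geno):
    """Maximized log-likelihood and profiled (alpha, sigma2) at ``params``."""
    f, sgg, sgy, syy, rss, n_obs = _objective(
        params, beta_of, n_agrp, y_h, lx_h, t_h, y_l, lx_l, t_l, geno
    )
    alphas = np.zeros(n_agrp)
    for a in range(n_agrp):
        if sgg[a] > 0.0:
            alphas[a] = sgy[a] / sgg[a]
    sigma2 = rss / n_obs
    lv = f - n_obs * np.log(rss)
    logl = -0.5 * (n_obs * np.log(2.0 * np.pi) + n_obs * np.log(sigma2) + lv + n_obs)
    return logl, alphas, sigma2


@njit(cache=False)
def _scan_h1(codes, beta_of, y_h, lx_h, ly_h, t_h, y_l, lx_l, ly_l, t_l,
             min_group, fatol, xatol, maxiter, n_starts):
    """H1 fit at every SNP; returns per-SNP logL1 (NaN = skipped) and params."""
    n_snp = codes.shape[0]
    logl = np.full(n_snp, np.nan)
    params = np.full((n_snp, 6), np.nan)
    alphas = np.full((n_snp, 4), np.nan)
    sigma2s = np.full(n_snp, np.nan)
    n = codes.shape[1]
    geno = np.empty(n, dtype=np.int64)
    for s in range(n_snp):
        n0 = 0
        n1 = 0
        for i in range(n):
            geno[i] = codes[s, i]
            if geno[i] == 0:
                n0 += 1
            elif geno[i] == 1:
                n1 += 1
        if n0 < min_group or n1 < min_group:
            continue
        x, f, _ = _fit_hypothesis(beta_of, 4, y_h, lx_h, ly_h, t_h,
                                  y_l, lx_l, ly_l, t_l, geno,
                                  fatol, xatol, maxiter, n_starts)
        ll, al, s2 = _loglik_from_objective(x, beta_of, 4,
                                            y_h, lx_h, t_h, y_l, lx_l, t_l, geno)
        logl[s] = ll
        params[s] = x
        alphas[s] = al
        sigma2s[s] = s2
    return logl, params, alphas, sigma2s


@njit(cache=False)
def _max_logl1(codes, beta_of, y_h, lx_h, ly_h, t_h, y_l, lx_l, ly_l, t_l,
               min_group, fatol, xatol, maxiter, n_starts):
    """Maximum H1 log-likelihood over SNPs (for permutation maxima)."""
    n_snp = codes.shape[0]
    n = codes.shape[1]
    geno = np.empty(n, dtype=np.int64)
    best = -np.inf
    for s in range(n_snp):
        n0 = 0
        n1 = 0
        for i in range(n):
            geno[i] = codes[s, i]
            if geno[i] == 0:
                n0 += 1
            elif geno[i] == 1:
                n1 += 1
        if n0 < min_group or n1 < min_group:
            continue
        x, f, _ = _fit_hypothesis(beta_of, 4, y_h, lx_h, ly_h, t_h,
                                  y_l, lx_l, ly_l, t_l, geno,
                                  fatol, xatol, maxiter, n_starts)
        ll, _, _ = _loglik_from_objective(x, beta_of, 4,
                                          y_h, lx_h, t_h, y_l, lx_l, t_l, geno)
        if ll > best:
            best = ll
    return best
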