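"""Numba kernels for the hierarchical model log densities and gradients.

These evaluate the joint unconstrained log posterior and its analytic
gradient in one pass; they are the hot path of NUTS and are written as
explicit loops.  Layouts must match the fit functions in
:mod:`moodcast.hierarchical`:

linear:  [mu_alpha, mu_beta(P), (log_tau_alpha, log_tau_beta(P)),
          (log_sigma), a_raw(J), b_raw(J*P)]
ordinal: [mu_beta(P), log_tau_beta(P), mu_g(K-1), log_tau_g(K-1),
          b_raw(J*P), g_raw(J*(K-1))]

Scale parameters are sampled on the log scale with half-normal priors; the
log-Jacobian terms are included here.  ``fix_tau``/``fix_sigma`` < 0 mean
"sample it"; >= 0 pins the value and removes it from the vector.
"""

import numpy as np
from numba import njit


@njit(cache=False, fastmath=False)
def linear_logp_grad(
    theta,
    X,
    y,
    starts,
    mu_beta_scale,
    tau_beta_scale,
    mu_alpha_scale,
    tau_alpha_scale,
    sigma_scale,
    fix_tau,
    fix_sigma,
):
    n, p = X.shape
    j_count = len(starts) - 1
    g = np.zeros(theta.shape[0])

    mu_a = theta[0]
    mu_b = theta[1 : 1 + p]
    pos = 1 + p
    if fix_tau < 0.0:
        lt_a = theta[pos]
        tau_a = np.exp(lt_a)
        lt_b = theta[pos + 1 : pos + 1 + p]
        tau_b = np.exp(lt_b)
        tau_pos = pos
        pos += 1 + p
    else:
        tau_a = fix_tau
        tau_b = np.full(p, fix_tau)
        tau_pos = -1
    if fix_sigma < 0.0:
        sigma = np.exp(theta[pos])
        sigma_pos = pos
        pos += 1
    else:
        sigma = fix_sigma
        sigma_pos = -1
    a_off = pos
    b_off = pos + j_count
    inv_s2 = 1.0 / (sigma * sigma)

    logp = -0.5 * (mu_a / mu_alpha_scale) ** 2
    g[0] = -mu_a / mu_alpha_scale**2
    for q in range(p):
        logp -= 0.5 * (mu_b[q] / mu_beta_scale[q]) ** 2
        g[1 + q] = -mu_b[q] / mu_beta_scale[q] ** 2

    ssr = 0.0
    g_tau_a = 0.0
    beta_j = np.empty(p)
    g_beta_j = np.empty(p)
    g_tau_b = np.zeros(p)
    for j in range(j_count):
        a_raw = theta[a_off + j]
        alpha_j = mu_a + tau_a * a_raw
        boff = b_off + j * p
        for q in range(p):
            beta_j[q] = mu_b[q] + tau_b[q] * theta[boff + q]
            g_beta_j[q] = 0.0
        g_alpha_j = 0.0
        lo = starts[j]
        hi = starts[j + 1]
        for i in range(lo, hi):
            fit = alpha_j
            for q in range(p):
                fit += X[i, q] * beta_j[q]
            r = y[i] - fit
            ssr += r * r
            g_alpha_j += r
            for q in range(p):
                g_beta_j[q] += r * X[i, q]
        g_alpha_j *= inv_s2
        # priors on the raw (standard-normal) individual residuals
        logp -= 0.5 * a_raw * a_raw
        g[0] += g_alpha_j
        g[a_off + j] = g_alpha_j * tau_a - a_raw
        g_tau_a += g_alpha_j * a_raw
        for q in range(p):
            b_raw = theta[boff + q]
            logp -= 0.5 * b_raw * b_raw
            gb = g_beta_j[q] * inv_s2
            g[1 + q] += gb
            g[boff + q] = gb * tau_b[q] - b_raw
            g_tau_b[q] += gb * b_raw

    logp -= 0.5 * ssr * inv_s2 + n * np.log(sigma)

    if tau_pos >= 0:
        logp += lt_a - 0.5 * (tau_a / tau_alpha_scale) ** 2
        g[tau_pos] = g_tau_a * tau_a + 1.0 - (tau_a / tau_alpha_scale) ** 2
        for q in range(p):
            logp += lt_b[q] - 0.5 * (tau_b[q] / tau_beta_scale[q]) ** 2
            g[tau_pos + 1 + q] = (
                g_tau_b[q] * tau_b[q] + 1.0 - (tau_b[q] / tau_beta_scale[q]) ** 2
            )
    if sigma_pos >= 0:
        logp += theta[sigma_pos] - 0.5 * (sigma / sigma_scale) ** 2
        g[sigma_pos] = ssr * inv_s2 - n + 1.0 - (sigma / sigma_scale) ** 2
    return logp, g


@njit(cache=False, fastmath=False)
def _softplus(x):
    if x > 30.0:
        return x
    if x < -30.0:
        return 0.0
    return np.log1p(np.exp(x))


@njit(cache=False, fastmath=False)
def ordinal_logp_grad(
    theta,
    X,
    cat,
    starts,
    n_cut,
    mu_beta_scale,
    tau_beta_scale,
    mu_cut_loc,
    mu_cut_scale,
    tau_cut_scale,
):
    n, p = X.shape
    j_count = len(starts) - 1
    g = np.zeros(theta.shape[0])

    mu_b = theta[0:p]
    lt_b = theta[p : 2 * p]
    tau_b = np.exp(lt_b)
    mg_off = 2 * p
    ltg_off = 2 * p + n_cut
    b_off = 2 * p + 2 * n_cut
    g_off = b_off + j_count * p
    mu_g = theta[mg_off : mg_off + n_cut]
    tau_g = np.exp(theta[ltg_off : ltg_off + n_cut])

    logp = 0.0
    for q in range(p):
        logp -= 0.5 * (mu_b[q] / mu_beta_scale[q]) ** 2
        g[q] = -mu_b[q] / mu_beta_scale[q] ** 2
        logp += lt_b[q] - 0.5 * (tau_b[q] / tau_beta_scale[q]) ** 2
    for m in range(n_cut):
        logp -= 0.5 * ((mu_g[m] - mu_cut_loc[m]) / mu_cut_scale[m]) ** 2
        g[mg_off + m] = -(mu_g[m] - mu_cut_loc[m]) / mu_cut_scale[m] ** 2
        tg = tau_g[m]
        logp += theta[ltg_off + m] - 0.5 * (tg / tau_cut_scale) ** 2

    beta_j = np.empty(p)
    g_beta_j = np.empty(p)
    g_tau_b = np.zeros(p)
    g_unc = np.empty(n_cut)
    cuts = np.empty(n_cut)
    inc = np.empty(n_cut)
    d_cuts = np.empty(n_cut)
    g_tau_g = np.zeros(n_cut)

    for j in range(j_count):
        boff = b_off + j * p
        goff = g_off + j * n_cut
        for q in range(p):
            b_raw = theta[boff + q]
            logp -= 0.5 * b_raw * b_raw
            beta_j[q] = mu_b[q] + tau_b[q] * b_raw
            g_beta_j[q] = 0.0
        for m in range(n_cut):
            graw = theta[goff + m]
            logp -= 0.5 * graw * graw
            g_unc[m] = mu_g[m] + tau_g[m] * graw
            d_cuts[m] = 0.0
        cuts[0] = g_unc[0]
        inc[0] = 1.0
        for m in range(1, n_cut):
            inc[m] = np.exp(g_unc[m])
            cuts[m] = cuts[m - 1] + inc[m]

        for i in range(starts[j], starts[j + 1]):
            z = 0.0
            for q in range(p):
                z += X[i, q] * beta_j[q]
            k = cat[i]  # 0-based category
            # a = z - c_{k-1} (k>0), b = z - c_k (k<n_cut)
            if k > 0:
                a = z - cuts[k - 1]
                sa = 1.0 / (1.0 + np.exp(-a))
                da = sa * (1.0 - sa)
            else:
                sa = 1.0
                da = 0.0
            if k < n_cut:
                b = z - cuts[k]
                sb = 1.0 / (1.0 + np.exp(-b))
                db = sb * (1.0 - sb)
            else:
                sb = 0.0
                db = 0.0
            if k > 0 and k < n_cut:
                diff = a - b
                ll = -b + np.log(-np.expm1(-diff)) - _softplus(-a) - _softplus(-b)
            elif k == 0:
                ll = -_softplus(b)
            else:
                ll = -_softplus(-a)
            logp += ll
            prob = sa - sb
            if prob < 1e-300:
                prob = 1e-300
            dz = (da - db) / prob
            for q in range(p):
                g_beta_j[q] += dz * X[i, q]
            if k > 0:
                d_cuts[k - 1] += -da / prob
            if k < n_cut:
                d_cuts[k] += db / prob

        # back through cumsum and exp: dL/dg_unc[m] = (sum_{k>=m} dL/dc_k) * inc
        acc = 0.0
        for m in range(n_cut - 1, -1, -1):
            acc += d_cuts[m]
            dg = acc if m == 0 else acc * inc[m]
            g[mg_off + m] += dg
            g[goff + m] = dg * tau_g[m] - theta[goff + m]
            g_tau_g[m] += dg * theta[goff + m]
        for q in range(p):
            g[q] += g_beta_j[q]
            g[boff + q] = g_beta_j[q] * tau_b[q] - theta[boff + q]
            g_tau_b[q] += g_beta_j[q] * theta[boff + q]

    for q in range(p):
        g[p + q] = g_tau_b[q] * tau_b[q] + 1.0 - (tau_b[q] / tau_beta_scale[q]) ** 2
    for m in range(n_cut):
        g[ltg_off + m] = g_tau_g[m] * tau_g[m] + 1.0 - (tau_g[m] / tau_cut_scale) ** 2
    return logp, g
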