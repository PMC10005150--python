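"""Gibbs-sampler cores for the Bayesian whole-genome regressions.

The Bayesian Lasso marker-effect sampler is a single-site Gibbs sweep over
markers (Park & Casella parameterisation: q_j | tau_j^2, s2_e ~
N(0, tau_j^2 * s2_e), 1/tau_j^2 | q_j inverse-Gaussian, lambda^2 Gamma) and
is compiled with numba when available; a pure-Python fallback keeps the
package functional (slowly) without it.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f
        return wrap


@njit(cache=False)
def _inv_gauss(mu: float, lam: float) -> float:
    """Michael-Schucany-Haas inverse-Gaussian draw."""
    v = np.random.standard_normal()
    y = v * v
    x = mu + mu * mu * y / (2.0 * lam) \
        - mu / (2.0 * lam) * np.sqrt(4.0 * mu * lam * y + mu * mu * y * y)
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=False)
def bl_gibbs(C, W, y, iterations, burn_in, df0, s0, lambda2_init,
             r_lambda, delta_lambda, seed):
    """Bayesian Lasso Gibbs sampler.

    C: fixed-effect design (flat priors, first column the intercept);
    W: centered marker doses.  Returns posterior means of the fixed effects
    and marker effects, and the posterior means of s2_e and lambda^2.
    """
    np.random.seed(seed)
    n, p = W.shape
    k = C.shape[1]
    ctc = np.empty(k)
    for j in range(k):
        s = 0.0
        for i in range(n):
            s += C[i, j] * C[i, j]
        ctc[j] = s
    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        xtx[j] = s

    alpha = np.zeros(k)
    q = np.zeros(p)
    tau2 = np.ones(p)
    lambda2 = lambda2_init
    vy = 0.0
    my = 0.0
    for i in range(n):
        my += y[i]
    my /= n
    for i in range(n):
        vy += (y[i] - my) ** 2
    vy /= max(n - 1, 1)
    s2e = 0.5 * vy if vy > 0 else 1.0

    e = y.copy()
    alpha[0] = my
    for i in range(n):
        e[i] -= C[i, 0] * alpha[0]

    alpha_sum = np.zeros(k)
    q_sum = np.zeros(p)
    s2e_sum = 0.0
    lam_sum = 0.0
    n_kept = 0

    for it in range(iterations):
        # fixed effects, flat prior
        for j in range(k):
            if ctc[j] <= 0.0:
                continue
            old = alpha[j]
            cty = 0.0
            for i in range(n):
                cty += C[i, j] * (e[i] + C[i, j] * old)
            mean = cty / ctc[j]
            new = mean + np.random.standard_normal() * np.sqrt(s2e / ctc[j])
            diff = new - old
            for i in range(n):
                e[i] -= C[i, j] * diff
            alpha[j] = new
        # marker effects
        for j in range(p):
            if xtx[j] <= 0.0:
                q[j] = 0.0
                continue
            old = q[j]
            xty = 0.0
            for i in range(n):
                xty += W[i, j] * e[i]
            xty += xtx[j] * old
            prec = xtx[j] + 1.0 / tau2[j]
            mean = xty / prec
            new = mean + np.random.standard_normal() * np.sqrt(s2e / prec)
            diff = new - old
            for i in range(n):
                e[i] -= W[i, j] * diff
            q[j] = new
        # tau2 and lambda2
        sum_tau2 = 0.0
        for j in range(p):
            qj2 = q[j] * q[j]
            if qj2 < 1e-14:
                qj2 = 1e-14
            mu_ig = np.sqrt(lambda2 * s2e / qj2)
            itau = _inv_gauss(mu_ig, lambda2)
            tau2[j] = 1.0 / itau
            sum_tau2 += tau2[j]
        lambda2 = np.random.gamma(p + r_lambda,
                                  1.0 / (sum_tau2 / 2.0 + delta_lambda))
        # residual variance (includes the scaled marker-effect term)
        ss = df0 * s0
        for i in range(n):
            ss += e[i] * e[i]
        for j in range(p):
            ss += q[j] * q[j] / tau2[j]
        s2e = ss / np.random.chisquare(n + p + df0)

        if it >= burn_in:
            n_kept += 1
            for j in range(k):
                alpha_sum[j] += alpha[j]
            for j in range(p):
                q_sum[j] += q[j]
            s2e_sum += s2e
            lam_sum += lambda2

    return (alpha_sum / n_kept, q_sum / n_kept, s2e_sum / n_kept,
            lam_sum / n_kept)


def rkhs_gibbs(C: np.ndarray, U: np.ndarray, lam: np.ndarray, y: np.ndarray,
               iterations: int, burn_in: int, df0: float, s0_g: float,
               s0_e: float, seed: int):
    """Gibbs sampler for y = C alpha + g + e with var(g) = G s2_g.

    Works in the eigenbasis of G (G = U diag(lam) U', positive eigenvalues
    only), where the conditional posterior of the transformed genetic values
    is diagonal, so each iteration is fully vectorized.  Returns posterior
    means of alpha, g, s2_g and s2_e.
    """
    rng = np.random.default_rng(seed)
    n, r = U.shape
    k = C.shape[1]
    CtC = C.T @ C
    a = np.zeros(r)
    s2g = max(s0_g, 1e-8)
    s2e = max(s0_e, 1e-8)
    alpha = np.zeros(k)
    alpha_sum = np.zeros(k)
    g_sum = np.zeros(n)
    s2g_sum = 0.0
    s2e_sum = 0.0
    n_kept = 0
    jitter = 1e-8 * np.eye(k)
    for it in range(iterations):
        g = U @ a
        # fixed effects, flat prior: joint normal around the GLS solution
        resid = y - g
        mean = np.linalg.solve(CtC + jitter, C.T @ resid)
        L = np.linalg.cholesky(np.linalg.inv(CtC + jitter) * s2e)
        alpha = mean + L @ rng.standard_normal(k)
        # transformed genetic values: diagonal conditional
        z = U.T @ (y - C @ alpha)
        v = 1.0 / (1.0 / s2e + 1.0 / (s2g * lam))
        m = v * z / s2e
        a = m + rng.standard_normal(r) * np.sqrt(v)
        g = U @ a
        # variance components
        ss_g = float(np.sum(a * a / lam))
        s2g = (ss_g + df0 * s0_g) / rng.chisquare(r + df0)
        e = y - C @ alpha - g
        s2e = (float(e @ e) + df0 * s0_e) / rng.chisquare(n + df0)
        if it >= burn_in:
            n_kept += 1
            alpha_sum += alpha
            g_sum += g
            s2g_sum += s2g
            s2e_sum += s2e
    return (alpha_sum / n_kept, g_sum / n_kept, s2g_sum / n_kept,
            s2e_sum / n_kept)
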