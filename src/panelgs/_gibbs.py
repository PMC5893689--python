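"""Single-site Gibbs sampler kernel for the Bayesian-alphabet models.

One numba-compiled kernel serves Bayes RR / A / B / Cpi / Lasso; the model
code selects the prior on marker effects.  Residuals are updated in place
(O(n p) per sweep).  The spike probability ``pi`` is the prior probability
that a marker effect is exactly zero.
"""

import numpy as np
from numba import njit

MODEL_RR = 0
MODEL_A = 1
MODEL_B = 2
MODEL_CPI = 3
MODEL_LASSO = 4


@njit(cache=True)
def _scaled_inv_chi2(nu, S):
    return nu * S / np.random.chisquare(nu)


@njit(cache=True)
def run_gibbs(M, y, model, n_iter, burn_in, thin, seed,
              nu_e, S_e, nu_a, S_a, pi_init, pi_is_fixed, a_pi, b_pi,
              lasso_shape, lasso_rate,
              fix_sigma2_e, sigma2_e_fixed, fix_sigma2_a, sigma2_a_fixed):
    np.random.seed(seed)
    n, p = M.shape
    xx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += M[i, j] * M[i, j]
        xx[j] = s

    mu = y.mean()
    alpha = np.zeros(p)
    e = y - mu
    sigma2_e = sigma2_e_fixed if fix_sigma2_e else max(S_e * nu_e / max(nu_e - 2.0, 1.0), 1e-10)
    sigma2_a = sigma2_a_fixed if fix_sigma2_a else S_a * nu_a / max(nu_a - 2.0, 1.0)
    sigma2_j = np.full(p, S_a * nu_a / max(nu_a - 2.0, 1.0))
    tau2 = np.ones(p)
    lam2 = lasso_shape / lasso_rate
    pi = pi_init
    incl = np.ones(p)

    n_keep = 0
    mu_sum = 0.0
    alpha_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    se_sum = 0.0
    sa_sum = 0.0
    pi_sum = 0.0

    for it in range(n_iter):
        # intercept (flat prior)
        acc = 0.0
        for i in range(n):
            e[i] += mu
            acc += e[i]
        mu = acc / n + np.random.normal() * np.sqrt(sigma2_e / n)
        for i in range(n):
            e[i] -= mu

        # marker effects
        k_incl = 0
        for j in range(p):
            a_old = alpha[j]
            if a_old != 0.0:
                for i in range(n):
                    e[i] += M[i, j] * a_old
            rhs = 0.0
            for i in range(n):
                rhs += M[i, j] * e[i]

            if model == MODEL_B or model == MODEL_CPI:
                v = sigma2_j[j] if model == MODEL_B else sigma2_a
                if pi >= 1.0:
                    a_new = 0.0
                    incl[j] = 0.0
                elif pi <= 0.0:
                    C = xx[j] + sigma2_e / v
                    a_new = rhs / C + np.random.normal() * np.sqrt(sigma2_e / C)
                    incl[j] = 1.0
                else:
                    t = xx[j] * v / sigma2_e
                    log_odds = (np.log((1.0 - pi) / pi)
                                - 0.5 * np.log1p(t)
                                + 0.5 * rhs * rhs * v
                                / (sigma2_e * (sigma2_e + xx[j] * v)))
                    if log_odds > 35.0:
                        p_in = 1.0
                    elif log_odds < -35.0:
                        p_in = 0.0
                    else:
                        p_in = 1.0 / (1.0 + np.exp(-log_odds))
                    if np.random.random() < p_in:
                        C = xx[j] + sigma2_e / v
                        a_new = rhs / C + np.random.normal() * np.sqrt(sigma2_e / C)
                        incl[j] = 1.0
                    else:
                        a_new = 0.0
                        incl[j] = 0.0
                if incl[j] > 0.0:
                    k_incl += 1
            else:
                if model == MODEL_RR:
                    prec_prior = sigma2_e / sigma2_a
                elif model == MODEL_A:
                    prec_prior = sigma2_e / sigma2_j[j]
                else:  # Lasso: prior var = tau2_j * sigma2_e
                    prec_prior = 1.0 / tau2[j]
                C = xx[j] + prec_prior
                a_new = rhs / C + np.random.normal() * np.sqrt(sigma2_e / C)
                incl[j] = 1.0
                k_incl += 1

            alpha[j] = a_new
            if a_new != 0.0:
                for i in range(n):
                    e[i] -= M[i, j] * a_new

        # marker-variance hyperparameters
        if model == MODEL_A:
            for j in range(p):
                sigma2_j[j] = _scaled_inv_chi2(
                    nu_a + 1.0, (nu_a * S_a + alpha[j] * alpha[j]) / (nu_a + 1.0))
        elif model == MODEL_B:
            for j in range(p):
                if incl[j] > 0.0:
                    sigma2_j[j] = _scaled_inv_chi2(
                        nu_a + 1.0,
                        (nu_a * S_a + alpha[j] * alpha[j]) / (nu_a + 1.0))
                else:
                    sigma2_j[j] = _scaled_inv_chi2(nu_a, S_a)
        elif model == MODEL_RR:
            if not fix_sigma2_a:
                ssa = 0.0
                for j in range(p):
                    ssa += alpha[j] * alpha[j]
                sigma2_a = _scaled_inv_chi2(nu_a + p, (nu_a * S_a + ssa) / (nu_a + p))
        elif model == MODEL_CPI:
            ssa = 0.0
            for j in range(p):
                ssa += alpha[j] * alpha[j]
            sigma2_a = _scaled_inv_chi2(nu_a + k_incl,
                                        (nu_a * S_a + ssa) / (nu_a + k_incl))
        elif model == MODEL_LASSO:
            st = 0.0
            for j in range(p):
                a2 = alpha[j] * alpha[j]
                if a2 < 1e-12:
                    a2 = 1e-12
                m_ig = np.sqrt(lam2 * sigma2_e / a2)
                inv_t = np.random.wald(m_ig, lam2)
                if inv_t < 1e-10:
                    inv_t = 1e-10
                tau2[j] = 1.0 / inv_t
                st += tau2[j]
            lam2 = np.random.gamma(lasso_shape + p, 1.0 / (lasso_rate + 0.5 * st))

        # mixture probability (probability of the spike)
        if (model == MODEL_B or model == MODEL_CPI) and not pi_is_fixed:
            pi = np.random.beta(a_pi + (p - k_incl), b_pi + k_incl)

        # residual variance
        if not fix_sigma2_e:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            sigma2_e = _scaled_inv_chi2(nu_e + n, (nu_e * S_e + sse) / (nu_e + n))

        if not np.isfinite(sigma2_e) or not np.isfinite(mu):
            return (mu_sum, alpha_sum, incl_sum, se_sum, sa_sum, pi_sum,
                    n_keep, it + 1)

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_keep += 1
            mu_sum += mu
            se_sum += sigma2_e
            sa_sum += sigma2_a
            pi_sum += pi
            for j in range(p):
                alpha_sum[j] += alpha[j]
                incl_sum[j] += incl[j]

    return mu_sum, alpha_sum, incl_sum, se_sum, sa_sum, pi_sum, n_keep, 0
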