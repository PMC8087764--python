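"""Numba kernel for the hierarchical F-model MCMC (environmental
association genome scan).

Population allele frequencies are beta-distributed around an ancestral
frequency pi_i with a locus-by-population precision set on the logit
scale: eta_ij = beta_j (neutral), beta_j + alpha_i (locus effect) or
beta_j + g_i * E_j (environmental effect); F_ij = sigmoid(eta_ij) is the
locus-population F_ST-scale parameter and the marginal likelihood of the
derived-allele counts is beta-binomial with shape
(pi * exp(-eta), (1 - pi) * exp(-eta)).  Per-locus model indicators move
through a product-space (Carlin-Chib) step in which inactive parameters
are refreshed from their priors.
"""

import math

import numpy as np
from numba import njit

M_NEUTRAL, M_LOCUS, M_ENV = 0, 1, 2


@njit(cache=True, inline="always")
def _llcell(a, n, pi, eta):
    phi = math.exp(-eta)
    u = pi * phi
    v = (1.0 - pi) * phi
    return (math.lgamma(a + u) + math.lgamma(n - a + v)
            - math.lgamma(n + u + v) - math.lgamma(u) - math.lgamma(v)
            + math.lgamma(u + v))


@njit(cache=True, inline="always")
def _eta(beta_j, alpha_i, g_i, e_j, m):
    if m == M_LOCUS:
        return beta_j + alpha_i
    if m == M_ENV:
        return beta_j + g_i * e_j
    return beta_j


@njit(cache=True)
def run_chain(a, n, E, pi, alpha, g, beta, mcur, ll,
              n_iter, record, thin,
              sd_pi, sd_alpha, sd_g, sd_beta,
              prior_alpha_sd, prior_g_sd, prior_beta_mean, prior_beta_sd,
              logp_m, beta_every, seed,
              post_counts, beta_trace, lnl_trace, acc):
    """Run ``n_iter`` MCMC iterations in place.

    When ``record`` is true, every ``thin``-th iteration adds to
    ``post_counts`` (L x 3 model-indicator tallies) and appends to
    ``beta_trace`` / ``lnl_trace``.  ``acc`` accumulates
    [accepted, proposed] pairs for the pi, alpha, g, beta blocks.
    Returns the number of recorded samples.
    """
    np.random.seed(seed)
    L, P = a.shape
    # refresh cached log-likelihood matrix
    for i in range(L):
        for j in range(P):
            ll[i, j] = _llcell(a[i, j], n[i, j], pi[i],
                               _eta(beta[j], alpha[i], g[i], E[j], mcur[i]))
    n_rec = 0
    for it in range(n_iter):
        # --- ancestral frequencies (logit random walk, uniform prior)
        for i in range(L):
            x = math.log(pi[i] / (1.0 - pi[i]))
            xp = x + sd_pi * np.random.normal()
            pip = 1.0 / (1.0 + math.exp(-xp))
            if pip <= 0.0 or pip >= 1.0:
                acc[0, 1] += 1
                continue
            dll = 0.0
            for j in range(P):
                dll += _llcell(a[i, j], n[i, j], pip,
                               _eta(beta[j], alpha[i], g[i], E[j],
                                    mcur[i])) - ll[i, j]
            # uniform prior on pi => Jacobian of the logit transform
            dll += (math.log(pip * (1.0 - pip))
                    - math.log(pi[i] * (1.0 - pi[i])))
            acc[0, 1] += 1
            if dll >= 0.0 or np.random.random() < math.exp(dll):
                acc[0, 0] += 1
                pi[i] = pip
                for j in range(P):
                    ll[i, j] = _llcell(a[i, j], n[i, j], pi[i],
                                       _eta(beta[j], alpha[i], g[i], E[j],
                                            mcur[i]))
        # --- locus effects alpha (active) / prior refresh (inactive)
        for i in range(L):
            if mcur[i] != M_LOCUS:
                alpha[i] = prior_alpha_sd * np.random.normal()
                continue
            ap = alpha[i] + sd_alpha * np.random.normal()
            dll = 0.0
            for j in range(P):
                dll += _llcell(a[i, j], n[i, j], pi[i],
                               beta[j] + ap) - ll[i, j]
            dll += 0.5 * (alpha[i] ** 2 - ap ** 2) / prior_alpha_sd ** 2
            acc[1, 1] += 1
            if dll >= 0.0 or np.random.random() < math.exp(dll):
                acc[1, 0] += 1
                alpha[i] = ap
                for j in range(P):
                    ll[i, j] = _llcell(a[i, j], n[i, j], pi[i],
                                       beta[j] + alpha[i])
        # --- environmental sensitivities g
        for i in range(L):
            if mcur[i] != M_ENV:
                g[i] = prior_g_sd * np.random.normal()
                continue
            gp = g[i] + sd_g * np.random.normal()
            dll = 0.0
            for j in range(P):
                dll += _llcell(a[i, j], n[i, j], pi[i],
                               beta[j] + gp * E[j]) - ll[i, j]
            dll += 0.5 * (g[i] ** 2 - gp ** 2) / prior_g_sd ** 2
            acc[2, 1] += 1
            if dll >= 0.0 or np.random.random() < math.exp(dll):
                acc[2, 0] += 1
                g[i] = gp
                for j in range(P):
                    ll[i, j] = _llcell(a[i, j], n[i, j], pi[i],
                                       beta[j] + g[i] * E[j])
        # --- per-locus model indicators (product-space move)
        for i in range(L):
            mp = np.random.randint(0, 2)
            if mp >= mcur[i]:
                mp += 1
            dll = logp_m[mp] - logp_m[mcur[i]]
            for j in range(P):
                dll += _llcell(a[i, j], n[i, j], pi[i],
                               _eta(beta[j], alpha[i], g[i], E[j],
                                    mp)) - ll[i, j]
            if dll >= 0.0 or np.random.random() < math.exp(dll):
                mcur[i] = mp
                for j in range(P):
                    ll[i, j] = _llcell(a[i, j], n[i, j], pi[i],
                                       _eta(beta[j], alpha[i], g[i], E[j],
                                            mcur[i]))
        # --- locus <-> env mode swap with value transfer (alpha and g
        # exchanged; involution with unit Jacobian, so acceptance is the
        # likelihood ratio times prior and model-prior ratios)
        for i in range(L):
            if mcur[i] == M_NEUTRAL:
                continue
            mp = M_ENV if mcur[i] == M_LOCUS else M_LOCUS
            dll = logp_m[mp] - logp_m[mcur[i]]
            dll += 0.5 * ((alpha[i] ** 2 - g[i] ** 2) / prior_alpha_sd ** 2
                          + (g[i] ** 2 - alpha[i] ** 2) / prior_g_sd ** 2)
            for j in range(P):
                dll += _llcell(a[i, j], n[i, j], pi[i],
                               _eta(beta[j], g[i], alpha[i], E[j],
                                    mp)) - ll[i, j]
            if dll >= 0.0 or np.random.random() < math.exp(dll):
                tmp = alpha[i]
                alpha[i] = g[i]
                g[i] = tmp
                mcur[i] = mp
                for j in range(P):
                    ll[i, j] = _llcell(a[i, j], n[i, j], pi[i],
                                       _eta(beta[j], alpha[i], g[i], E[j],
                                            mcur[i]))
        # --- population effects beta
        if it % beta_every == 0:
            for j in range(P):
                bp = beta[j] + sd_beta * np.random.normal()
                dll = 0.0
                for i in range(L):
                    dll += _llcell(a[i, j], n[i, j], pi[i],
                                   _eta(bp, alpha[i], g[i], E[j],
                                        mcur[i])) - ll[i, j]
                dll += 0.5 * ((beta[j] - prior_beta_mean) ** 2
                              - (bp - prior_beta_mean) ** 2
                              ) / prior_beta_sd ** 2
                acc[3, 1] += 1
                if dll >= 0.0 or np.random.random() < math.exp(dll):
                    acc[3, 0] += 1
                    beta[j] = bp
                    for i in range(L):
                        ll[i, j] = _llcell(a[i, j], n[i, j], pi[i],
                                           _eta(beta[j], alpha[i], g[i],
                                                E[j], mcur[i]))
        # --- record
        if record and (it % thin == thin - 1):
            for i in range(L):
                post_counts[i, mcur[i]] += 1
            tot = 0.0
            for i in range(L):
                for j in range(P):
                    tot += ll[i, j]
            for j in range(P):
                beta_trace[n_rec, j] = beta[j]
            lnl_trace[n_rec] = tot
            n_rec += 1
    return n_rec
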