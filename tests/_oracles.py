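"""Independent oracles: brute-force / closed-form references the tests
compare the package against. Deliberately simple and slow."""

from __future__ import annotations

import numpy as np


def blup_solution(X, y, components, sig2e):
    """Closed-form posterior mean of (alpha, u_k) with fixed variances, no
    censoring: solve the mixed-model normal equations in the eigenbasis.

    ``components``: list of (Gamma, lam, sig2_k). Returns (alpha, [u_k], eta).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, q = X.shape
    blocks = [X] + [G for G, _, _ in components]
    Z = np.hstack(blocks)
    m = Z.shape[1]
    C = Z.T @ Z / sig2e
    ofs = q
    for G, lam, s2 in components:
        r = G.shape[1]
        C[ofs:ofs + r, ofs:ofs + r] += np.diag(1.0 / (np.asarray(lam) * s2))
        ofs += r
    rhs = Z.T @ y / sig2e
    sol = np.linalg.solve(C, rhs)
    alpha = sol[:q]
    us, ofs = [], q
    eta = X @ alpha
    for G, lam, s2 in components:
        r = G.shape[1]
        u = G @ sol[ofs:ofs + r]
        us.append(u)
        eta = eta + u
        ofs += r
    return alpha, us, eta


def feature_space_gibbs(X, y, Z, sig2_beta, sig2e, n_iter=6000, burn_in=1000, seed=0):
    """Explicit per-feature ridge-prior Gibbs sampler (no censoring, fixed
    variances): y = X alpha + Z beta + eps, beta_j ~ N(0, sig2_beta).

    Returns the chain of linear predictors eta (draws x n). The kernel
    representation with K = ZZ' s (rescaled) and sig2_k = sig2_beta / s must
    give the same posterior.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    n, q = X.shape
    p = Z.shape[1]
    XtXi = np.linalg.inv(X.T @ X)
    cXtXi = np.linalg.cholesky(XtXi)
    alpha = np.zeros(q)
    beta = np.zeros(p)
    zb = Z @ beta
    z2 = np.sum(Z**2, axis=0)
    etas = []
    for it in range(n_iter):
        r = y - zb
        ahat = XtXi @ (X.T @ r)
        alpha = ahat + np.sqrt(sig2e) * (cXtXi @ rng.standard_normal(q))
        xb = X @ alpha
        e = y - xb - zb
        for j in range(p):
            e += Z[:, j] * beta[j]
            prec = z2[j] / sig2e + 1.0 / sig2_beta
            mu = (Z[:, j] @ e) / sig2e / prec
            beta[j] = mu + rng.standard_normal() / np.sqrt(prec)
            e -= Z[:, j] * beta[j]
        zb = Z @ beta
        if it >= burn_in:
            etas.append(xb + zb)
    return np.asarray(etas)


def pairwise_auc(labels, scores):
    """O(n^2) concordance count: ties contribute 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up q-values, O(m^2) by direct minimum."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        # q_i = min over all j with p_j >= p_i of p_j * m / rank(p_j)
        order = np.argsort(p, kind="stable")
        ranks = np.empty(m, int)
        ranks[order] = np.arange(1, m + 1)
        q[i] = min(min(p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]), 1.0)
    return q


def breslow_grid_max(times, events, x, lo=-5, hi=5, n_grid=200001):
    """Grid-search maximizer of the one-covariate Breslow partial likelihood."""
    from omisurv.coxph import breslow_partial_loglik

    grid = np.linspace(lo, hi, n_grid)
    ll = np.array([breslow_partial_loglik([b], times, events, np.asarray(x, float)[:, None])
                   for b in grid])
    return grid[np.argmax(ll)]
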