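"""Independent brute-force oracles, written as direct transcriptions of the
defining formulas.  They deliberately share no code with the package: loops
instead of vectorization, explicit normal equations instead of pinv-based
solvers, dense eigendecomposition instead of SVD."""

import numpy as np


def wc_fst_loop(G, demes, groups):
    """Weir & Cockerham (1984) theta, per locus, by literal formula transcription.

    G: (n, m) dosages with -1 missing; returns (theta array, multi-locus theta).
    """
    demes = np.asarray(demes)
    m = G.shape[1]
    thetas = np.full(m, np.nan)
    sum_a = sum_d = 0.0
    for j in range(m):
        ns, ps, hs = [], [], []
        for g in groups:
            col = G[demes == g, j]
            col = col[col >= 0]
            if len(col) < 2:
                continue
            ns.append(len(col))
            ps.append(col.sum() / (2 * len(col)))
            hs.append(np.mean(col == 1))
        r = len(ns)
        if r < 2:
            continue
        ns, ps, hs = map(np.asarray, (ns, ps, hs))
        nbar = ns.mean()
        nc = (ns.sum() - (ns ** 2).sum() / ns.sum()) / (r - 1)
        pbar = (ns * ps).sum() / (r * nbar)
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * hs).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                           * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        if a + b + c != 0:
            thetas[j] = a / (a + b + c)
        sum_a += a
        sum_d += a + b + c
    return thetas, sum_a / sum_d


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values by the explicit step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def rda_brute(G, X, n_axes):
    """Constrained ordination by explicit normal equations + dense eigh.

    G: centered genotypes (n, m); X: standardized predictors (n, p).
    Returns (axis eigenvalues, locus-axis correlation loadings).
    """
    n = G.shape[0]
    B = np.linalg.solve(X.T @ X, X.T @ G)
    Yhat = X @ B
    C = Yhat @ Yhat.T / (n - 1)           # site-space covariance of fitted values
    w, U = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    scores = U[:, :n_axes] * np.sqrt(np.maximum(w[:n_axes], 0) * (n - 1))
    load = np.empty((G.shape[1], n_axes))
    for j in range(G.shape[1]):
        for k in range(n_axes):
            y, s_ = G[:, j], scores[:, k]
            denom = np.sqrt((y ** 2).sum() * ((s_ - s_.mean()) ** 2).sum())
            load[j, k] = (y @ (s_ - s_.mean())) / denom if denom > 0 else 0.0
    return w[:n_axes], load


def mrm_normal_equations(response, predictor_mats):
    """MRM coefficients by explicit normal equations on lower-triangle pairs."""
    k = response.shape[0]
    pairs = [(i, j) for i in range(1, k) for j in range(i)]
    y = np.array([response[i, j] for i, j in pairs])
    X = np.column_stack(
        [np.ones(len(pairs))]
        + [np.array([m[i, j] for i, j in pairs]) for m in predictor_mats])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
    return beta, r2
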