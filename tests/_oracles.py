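"""Independent reference solvers used to validate the package's fits.

These deliberately avoid the package's coordinate-descent/rotation code
path: the penalized quasi-likelihood objective is minimized directly by
accelerated proximal gradient (FISTA) over the joint (β, b) parameters.
"""

from __future__ import annotations

import numpy as np


def pql_objective(Xfull, y, d, U, v, lam, beta, b):
    """Exact penalized PQL objective at (β, b): -ℓ + ½bᵀK⁻¹b + λΣv|β|."""
    pos = d > 1e-12
    c = (U.T @ b)[pos]
    eta = Xfull @ beta + b
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    return float(-ll + 0.5 * np.sum(c**2 / d[pos]) + lam * np.sum(v * np.abs(beta)))


def fista_pql(Xfull, y, d, U, v, lam, max_iter=400_000, tol=1e-14):
    """Proximal-gradient minimizer of the penalized PQL objective.

    The random effect is parametrized as b = U_pos c over the positive
    eigendirections of K so the ridge term stays finite; d = 0 (no random
    effect) reduces to a plain penalized logistic regression.

    Returns (beta, b, objective).
    """
    Xfull = np.asarray(Xfull, dtype=float)
    y = np.asarray(y, dtype=float)
    q = Xfull.shape[1]
    pos = d > 1e-12
    Upos = U[:, pos]
    dpos = d[pos]
    npos = int(pos.sum())

    M = np.column_stack([Xfull, Upos]) if npos else Xfull
    L = 0.25 * np.linalg.norm(M, 2) ** 2
    if npos:
        L += (1.0 / dpos).max()

    beta = np.zeros(q)
    c = np.zeros(npos)
    zb, zc = beta.copy(), c.copy()
    t = 1.0

    def objective(beta, c):
        eta = Xfull @ beta + (Upos @ c if npos else 0.0)
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        ridge = 0.5 * np.sum(c**2 / dpos) if npos else 0.0
        return float(-ll + ridge + lam * np.sum(v * np.abs(beta)))

    o_prev = np.inf
    o_check = np.inf
    for it in range(max_iter):
        eta = Xfull @ zb + (Upos @ zc if npos else 0.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        gb = -Xfull.T @ (y - mu)
        bn = zb - gb / L
        thr = lam * v / L
        bn = np.sign(bn) * np.maximum(np.abs(bn) - thr, 0.0)
        if npos:
            gc = -Upos.T @ (y - mu) + zc / dpos
            cn = zc - gc / L
        else:
            cn = zc
        o = objective(bn, cn)
        if o > o_prev:  # adaptive restart: drop momentum when we overshoot
            t = 1.0
        o_prev = o
        tn = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        zb = bn + (t - 1.0) / tn * (bn - beta)
        zc = cn + (t - 1.0) / tn * (cn - c)
        beta, c, t = bn, cn, tn
        if it % 2000 == 1999:
            if 0.0 <= o_check - o < tol * max(1.0, abs(o)):
                break
            o_check = o
    b = Upos @ c if npos else np.zeros(Xfull.shape[0])
    return beta, b, objective(beta, c)


def gaussian_pen_lmm_oracle(Xfull, y, Sigma, v, lam, max_iter=200_000, tol=1e-15):
    """Dense-solve penalized LMM: min ½(y-Xβ)ᵀΣ⁻¹(y-Xβ) + λΣv|β| by FISTA.

    The response is whitened with Σ^{-1/2} so the smooth part is an ordinary
    least-squares loss; this is the exact profiled Gaussian objective.
    """
    w, E = np.linalg.eigh(Sigma)
    root_inv = E @ np.diag(1.0 / np.sqrt(w)) @ E.T
    yw = root_inv @ y
    Xw = root_inv @ Xfull
    q = Xw.shape[1]
    L = np.linalg.norm(Xw, 2) ** 2
    beta = np.zeros(q)
    z = beta.copy()
    t = 1.0

    def objective(beta):
        r = yw - Xw @ beta
        return float(0.5 * r @ r + lam * np.sum(v * np.abs(beta)))

    o_prev = np.inf
    for it in range(max_iter):
        g = -Xw.T @ (yw - Xw @ z)
        bn = z - g / L
        thr = lam * v / L
        bn = np.sign(bn) * np.maximum(np.abs(bn) - thr, 0.0)
        tn = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = bn + (t - 1.0) / tn * (bn - beta)
        beta, t = bn, tn
        if it % 1000 == 999:
            o = objective(beta)
            if 0.0 <= o_prev - o < tol * max(1.0, abs(o)):
                break
            o_prev = o
    return beta, objective(beta)
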