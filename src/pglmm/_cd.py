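"""Numba kernel for the cyclic coordinate-descent inner loop."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _sweep(Xw, Xs, r, beta, lamv, colnorm, active_only):
    n, k = Xs.shape
    maxd = 0.0
    for j in range(k):
        if active_only and beta[j] == 0.0 and lamv[j] > 0.0:
            continue
        cn = colnorm[j]
        if cn <= 0.0:
            continue
        grad = 0.0
        for i in range(n):
            grad += Xw[i, j] * r[i]
        z = beta[j] * cn + grad
        t = lamv[j]
        if t > 0.0:
            if z > t:
                bj = (z - t) / cn
            elif z < -t:
                bj = (z + t) / cn
            else:
                bj = 0.0
        else:
            bj = z / cn
        d = bj - beta[j]
        if d != 0.0:
            beta[j] = bj
            for i in range(n):
                r[i] -= d * Xs[i, j]
            step = abs(d) * np.sqrt(cn)
            if step > maxd:
                maxd = step
    return maxd


@njit(cache=False)
def cd_sweeps(Xw, Xs, r, beta, lamv, colnorm, tol, max_sweeps):
    """Cycle coordinates of a weighted lasso until stable.

    Xw = diag(w) @ Xs precomputed; r is the current residual Y* - Xs @ beta
    and is updated in place along with beta.  lamv[j] is the per-coordinate
    threshold λ·v_j (0 for unpenalized columns); colnorm[j] = Σ_i w_i X_ij².

    Uses the standard active-set strategy: after each full sweep, cycle only
    the currently nonzero (or unpenalized) coordinates until stable, then
    re-check with a full sweep.  Converged when a full sweep moves no
    coefficient by more than tol on the √colnorm scale.

    Returns (sweeps_used, converged).
    """
    total = 0
    while total < max_sweeps:
        maxd = _sweep(Xw, Xs, r, beta, lamv, colnorm, False)
        total += 1
        if maxd < tol:
            return total, True
        while total < max_sweeps:
            maxd = _sweep(Xw, Xs, r, beta, lamv, colnorm, True)
            total += 1
            if maxd < tol:
                break
    return total, False
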