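"""PQL null-model fit with average-information REML variance components.

The binary-trait GLMM is fitted with all SNP effects set to zero: the
working linearization Ỹ = η + (y − μ)/W turns each iteration into a linear
mixed model Ỹ = Xα + b + ε, ε ~ N(0, W⁻¹), whose variance components τ are
updated by one average-information Newton step per working update.  The
resulting (τ̂, α̂, b̃, Ỹ, W) are held fixed downstream — variance components
are estimated once under the null and reused along the whole lasso path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

MU_EPS = 1e-10


@dataclass
class BinomialFamily:
    """Bernoulli response with canonical logit link (dispersion fixed at 1)."""

    phi: float = 1.0

    @staticmethod
    def inverse_link(eta):
        # expit, numerically safe for large |eta|
        out = np.empty_like(eta, dtype=float)
        pos = eta >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
        e = np.exp(eta[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    @staticmethod
    def link(mu):
        return np.log(mu) - np.log1p(-mu)

    @staticmethod
    def variance(mu):
        return mu * (1.0 - mu)

    @staticmethod
    def loglik(y, eta):
        # sum y*eta - log(1 + e^eta), stable via logaddexp
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def working_update(y, eta, family: BinomialFamily | None = None):
    """One IRLS linearization: returns (mu, W, Ytilde).

    W_i = μ_i(1-μ_i) is the PQL working weight for canonical logit;
    Ỹ_i = η_i + (y_i - μ_i)/W_i.  μ is clipped away from {0,1} so saturated
    linear predictors stay finite.
    """
    family = family or BinomialFamily()
    eta = np.asarray(eta, dtype=float)
    mu = np.clip(family.inverse_link(eta), MU_EPS, 1.0 - MU_EPS)
    W = family.variance(mu)
    ytilde = eta + (np.asarray(y) - mu) / W
    return mu, W, ytilde


@dataclass
class NullFit:
    """Converged null-model state reused by the penalized path."""

    alpha: np.ndarray
    tau: np.ndarray
    phi: float
    b_tilde: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    W: np.ndarray
    ytilde: np.ndarray
    converged: bool
    n_iter: int
    tau_trace: list = field(default_factory=list, repr=False)


def _initial_alpha(X, y):
    import statsmodels.api as sm

    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return np.asarray(res.params, dtype=float)


def fit_null(X, y, Vs, family: BinomialFamily | None = None,
             tol: float = 1e-5, max_iter: int = 100) -> NullFit:
    """Fit the no-genetic-effect GLMM by PQL with AI-REML τ updates.

    Alternates (a) the working linearization, (b) one AI-REML Newton step
    for τ on the working LMM with step-halving and a lower clamp at
    1e-6·Var(Ỹ), and (c) GLS updates of α and the random-effect BLUP b̃,
    until the largest relative change in (α, τ) drops below ``tol``.
    """
    family = family or BinomialFamily()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if isinstance(Vs, np.ndarray):
        Vs = [Vs]
    Vs = [np.asarray(V, dtype=float) for V in Vs]
    n, m = X.shape
    S = len(Vs)
    if np.linalg.matrix_rank(X) < m:
        raise ValueError("covariate matrix is rank deficient")
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both classes")

    alpha = _initial_alpha(X, y)
    b = np.zeros(n)
    eta = X @ alpha
    mu, W, ytilde = working_update(y, eta, family)
    tau = np.full(S, 0.1 * np.var(ytilde) / S)
    tau_trace = [tau.copy()]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu, W, ytilde = working_update(y, eta, family)
        floor = 1e-6 * np.var(ytilde)

        Sigma = np.diag(1.0 / W) + sum(t * V for t, V in zip(tau, Vs))
        cho = linalg.cho_factor(Sigma, lower=True)
        Sinv = linalg.cho_solve(cho, np.eye(n))
        SinvX = Sinv @ X
        XtSX = X.T @ SinvX
        XtSX_inv = np.linalg.inv(XtSX)
        P = Sinv - SinvX @ XtSX_inv @ SinvX.T

        Py = P @ ytilde
        VPy = [V @ Py for V in Vs]
        score = np.array([
            0.5 * (Py @ VPy[s] - np.sum(P * Vs[s])) for s in range(S)
        ])
        PVPy = [P @ v for v in VPy]
        AI = 0.5 * np.array([[VPy[s] @ PVPy[t] for t in range(S)] for s in range(S)])
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(AI) @ score
        if not np.isfinite(step).all():
            raise RuntimeError(
                f"AI-REML diverged at iteration {it}; tau trace: {tau_trace}")

        new_tau = tau + step
        halvings = 0
        while (new_tau < 0).any() and halvings < 10:
            step *= 0.5
            new_tau = tau + step
            halvings += 1
        new_tau = np.maximum(new_tau, floor)

        alpha_new = XtSX_inv @ (SinvX.T @ ytilde)
        K = sum(t * V for t, V in zip(new_tau, Vs))
        b = K @ (Sinv @ (ytilde - X @ alpha_new))
        eta = X @ alpha_new + b

        theta_old = np.concatenate([alpha, tau])
        theta_new = np.concatenate([alpha_new, new_tau])
        rel = np.max(np.abs(theta_new - theta_old) /
                     np.maximum(np.abs(theta_old), 1e-4))
        alpha, tau = alpha_new, new_tau
        tau_trace.append(tau.copy())
        logger.debug("null iter %d: tau=%s rel=%.3g", it, tau, rel)
        if rel < tol:
            converged = True
            break

    if not np.isfinite(tau).all():
        raise RuntimeError(f"variance components diverged; trace: {tau_trace}")
    if not converged:
        logger.warning("null model did not converge in %d iterations", max_iter)

    mu, W, ytilde = working_update(y, eta, family)
    return NullFit(alpha=alpha, tau=tau, phi=family.phi, b_tilde=b, eta=eta,
                   mu=mu, W=W, ytilde=ytilde, converged=converged, n_iter=it,
                   tau_trace=tau_trace)


def reml_loglik(tau, ytilde, W, X, Vs):
    """Restricted log-likelihood of the working LMM at fixed (Ỹ, W).

    Used as an independent check that the AI-REML update converged to the
    REML optimum of the final working model.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if isinstance(Vs, np.ndarray):
        Vs = [Vs]
    n = len(ytilde)
    Sigma = np.diag(1.0 / W) + sum(t * V for t, V in zip(tau, Vs))
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf
    Sinv = np.linalg.inv(Sigma)
    XtSX = X.T @ Sinv @ X
    sign2, logdet2 = np.linalg.slogdet(XtSX)
    P = Sinv - Sinv @ X @ np.linalg.inv(XtSX) @ X.T @ Sinv
    return float(-0.5 * (logdet + logdet2 + ytilde @ P @ ytilde))


def write_nullfit(fit: NullFit, path) -> None:
    """Serialize a NullFit as a single long-format CSV."""
    import pandas as pd

    rows = []
    for name, vec in [("alpha", fit.alpha), ("tau", fit.tau),
                      ("b_tilde", fit.b_tilde), ("eta", fit.eta),
                      ("mu", fit.mu), ("W", fit.W), ("ytilde", fit.ytilde)]:
        rows.extend({"name": name, "index": i, "value": v}
                    for i, v in enumerate(np.atleast_1d(vec)))
    rows.append({"name": "phi", "index": 0, "value": fit.phi})
    rows.append({"name": "converged", "index": 0, "value": float(fit.converged)})
    rows.append({"name": "n_iter", "index": 0, "value": float(fit.n_iter)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_nullfit(path) -> NullFit:
    import pandas as pd

    df = pd.read_csv(path)
    vec = {name: grp.sort_values("index")["value"].to_numpy()
           for name, grp in df.groupby("name")}
    return NullFit(
        alpha=vec["alpha"], tau=vec["tau"], phi=float(vec["phi"][0]),
        b_tilde=vec["b_tilde"], eta=vec["eta"], mu=vec["mu"], W=vec["W"],
        ytilde=vec["ytilde"], converged=bool(vec["converged"][0]),
        n_iter=int(vec["n_iter"][0]),
    )
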