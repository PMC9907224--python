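"""Lasso-penalized PQL path by coordinate descent on the rotated model.

With variance components held at their null estimates, the penalized
working model has covariance Σ = W⁻¹ + K, K = Σ_s τ̂_s V_s.  For a logistic
model the curvature satisfies W ⪯ I/4, so Σ is dominated by the fixed
surrogate Σ_b = c·I + K with c = 4; a single eigendecomposition K = U D Uᵀ
then diagonalizes Σ_b for the whole path.  In the rotated basis the random
effect profiles out in closed form (per-component shrinkage d_i/(c+d_i))
and each λ is solved by cyclic coordinate descent with sequential strong
rules and a full KKT repair sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._cd import cd_sweeps
from .kinship import KinshipModel
from .nullmodel import BinomialFamily, NullFit

logger = logging.getLogger(__name__)

BOUND_BINOMIAL = 4.0  # 1/max μ(1-μ): sharpest uniform logistic curvature bound


@dataclass
class PenaltySpec:
    """Regularization path settings.

    penalty_factors v_j are 0 for unpenalized columns (intercept, non-genetic
    covariates) and 1 for standardized SNPs by default; kappa > 0 switches to
    adaptive-lasso weights v_j = |β̂_j|^{-κ} from marginal fits.
    """

    lambdas: np.ndarray | None = None
    nlambda: int = 100
    lambda_min_ratio: float = 0.01
    penalty_factors: np.ndarray | None = None
    kappa: float = 0.0

    def validate(self, q: int) -> np.ndarray:
        if self.penalty_factors is None:
            raise ValueError("penalty_factors must be set (see default_penalty_factors)")
        v = np.asarray(self.penalty_factors, dtype=float)
        if len(v) != q:
            raise ValueError("penalty_factors length must match design columns")
        if (v < 0).any():
            raise ValueError("penalty factors must be nonnegative")
        if not (v == 0).any():
            raise ValueError("unpenalized set is empty (intercept must be unpenalized)")
        if not (v > 0).any():
            raise ValueError("all penalty factors are zero; nothing to penalize")
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, dtype=float)
            if (np.diff(lam) >= 0).any() or (lam <= 0).any():
                raise ValueError("lambdas must be positive and strictly decreasing")
        return v


def default_penalty_factors(m: int, p: int) -> np.ndarray:
    """0 for the m covariate columns, 1 for the p SNP columns."""
    return np.concatenate([np.zeros(m), np.ones(p)])


@dataclass
class RotatedSystem:
    """Design and working quantities in the eigenbasis of K = Σ_s τ̂_s V_s."""

    X: np.ndarray        # (n, q) original full design [covariates, SNPs]
    Xstar: np.ndarray    # Uᵀ X
    U: np.ndarray
    d: np.ndarray        # eigenvalues of K
    w: np.ndarray        # 1 / (c + d_i): profiled working weights
    shrink: np.ndarray   # d_i / (c + d_i): random-effect profile factors
    c_bound: float
    family: str = "binomial"


def build_rotated(null: NullFit, km: KinshipModel, Xfull: np.ndarray,
                  family: str = "binomial") -> RotatedSystem:
    """Rotate the full design once and precompute profile weights.

    family="binomial" uses the curvature bound c = 4; family="gaussian"
    (identity link, W = I/φ) is exact with c = φ.
    """
    Xfull = np.asarray(Xfull, dtype=float)
    if Xfull.shape[0] != km.n:
        raise ValueError("design and kinship dimensions do not match")
    if family == "binomial":
        c = BOUND_BINOMIAL
    elif family == "gaussian":
        c = float(null.phi) if null is not None else 1.0
    else:
        raise ValueError(f"unsupported family '{family}'")
    d = km.eigvals
    w = 1.0 / (c + d)
    shrink = d / (c + d)
    Xstar = km.U.T @ Xfull
    return RotatedSystem(X=Xfull, Xstar=Xstar, U=km.U, d=d, w=w,
                         shrink=shrink, c_bound=c, family=family)


def soft_threshold(z, t):
    """Lasso proximal operator sign(z)·max(|z|-t, 0)."""
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def profile_b(rs: RotatedSystem, ystar: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Closed-form random effects given β: b = U[s ⊙ (Y* - X*β)]."""
    bstar = rs.shrink * (ystar - rs.Xstar @ beta)
    return rs.U @ bstar


@dataclass
class PathFit:
    """Solutions along the regularization path."""

    lambdas: np.ndarray
    coef: np.ndarray        # (q, L)
    b_prof: np.ndarray      # (n, L)
    ytilde: np.ndarray      # (n, L) final working response per λ
    objective: np.ndarray   # penalized objective Q_λ at the solution
    ell_pql: np.ndarray     # quasi-likelihood (model weights) at the solution
    n_active: np.ndarray    # nonzero penalized coefficients per λ
    active: list = field(default_factory=list)
    converged: np.ndarray | None = None
    penalty_factors: np.ndarray | None = None

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)


def _linearize(rs, y, eta, fam):
    if rs.family == "binomial":
        mu = fam.inverse_link(eta)
        return eta + rs.c_bound * (y - mu)
    return y  # gaussian: the working response is the response


def _objective_parts(rs, y, beta_cols, cols, b, bstar, lamv, fam):
    eta = rs.X[:, cols] @ beta_cols + b
    if rs.family == "binomial":
        ll = fam.loglik(y, eta)
    else:
        ll = -0.5 * float(np.sum((y - eta) ** 2)) / rs.c_bound
    pos = rs.d > 1e-12
    ridge = 0.5 * float(np.sum(bstar[pos] ** 2 / rs.d[pos]))
    pen = float(np.sum(lamv * np.abs(beta_cols)))
    ell = ll - ridge
    return -ll + ridge + pen, ell


def _solve_at(rs, y, cols, beta_init, b_init, lamv, fam, inner_tol, max_sweeps,
              outer_tol, max_outer):
    """Bound-IRLS outer loop + CD inner loop on the given columns.

    Returns (beta_cols, b, Q, ell_pql, ytilde, converged).
    """
    Xs = np.asfortranarray(rs.Xstar[:, cols])
    Xw = np.asfortranarray(Xs * rs.w[:, None])
    colnorm = np.einsum("ij,ij->j", Xw, Xs)
    beta = beta_init.copy()
    b = b_init.copy()
    Q_prev = np.inf
    converged = False
    yt = None
    for outer in range(1, max_outer + 1):
        eta = rs.X[:, cols] @ beta + b
        yt = _linearize(rs, y, eta, fam)
        ystar = rs.U.T @ yt
        r = ystar - Xs @ beta
        cd_sweeps(Xw, Xs, r, beta, lamv, colnorm, inner_tol, max_sweeps)
        bstar = rs.shrink * r  # r is the post-CD profiled residual
        b = rs.U @ bstar
        Q, ell = _objective_parts(rs, y, beta, cols, b, bstar, lamv, fam)
        if abs(Q - Q_prev) < outer_tol * max(1.0, abs(Q)):
            converged = True
            break
        Q_prev = Q
        if rs.family == "gaussian" and outer >= 2:
            converged = True
            break
    return beta, b, Q, ell, yt, converged


def _full_gradient(rs, yt, beta):
    """|∂/∂β_j| of the profiled quadratic at the current solution, all j."""
    ystar = rs.U.T @ yt
    r = ystar - rs.Xstar @ beta
    return rs.Xstar.T @ (rs.w * r)


def lambda_grid(rs: RotatedSystem, spec: PenaltySpec, null: NullFit,
                y: np.ndarray) -> np.ndarray:
    """λ_max (all penalized coefficients zero) down to ratio·λ_max, log-spaced."""
    fam = BinomialFamily()
    v = spec.validate(rs.X.shape[1])
    _, _, _, _, _, grad, lam_max = _stage0(rs, y, v, null, fam,
                                           1e-7, 1000, 1e-8, 100)
    return _make_grid(lam_max, spec)


def _make_grid(lam_max, spec):
    if spec.lambdas is not None:
        return np.asarray(spec.lambdas, dtype=float)
    return np.logspace(np.log10(lam_max),
                       np.log10(lam_max * spec.lambda_min_ratio), spec.nlambda)


def _stage0(rs, y, v, null, fam, inner_tol, max_sweeps, outer_tol, max_outer):
    """Converge the unpenalized-only model; return state and λ_max."""
    q = rs.X.shape[1]
    unpen = np.where(v == 0)[0]
    beta = np.zeros(q)
    if null is not None and len(null.alpha) == len(unpen):
        beta[unpen] = null.alpha
    b = null.b_tilde.copy() if null is not None else np.zeros(rs.X.shape[0])
    beta_u, b, Q, ell, yt, conv = _solve_at(
        rs, y, unpen, beta[unpen], b, np.zeros(len(unpen)), fam,
        inner_tol, max_sweeps, outer_tol, max_outer)
    beta[unpen] = beta_u
    grad = _full_gradient(rs, yt, beta)
    pen = v > 0
    lam_max = float(np.max(np.abs(grad[pen]) / v[pen]))
    return beta, b, Q, ell, yt, grad, lam_max


def cd_fit(rs: RotatedSystem, y: np.ndarray, spec: PenaltySpec,
           null: NullFit, inner_tol: float = 1e-7, max_sweeps: int = 1000,
           outer_tol: float = 1e-6, max_outer: int = 50,
           kkt_slack: float = 1e-7, max_active: int | None = None) -> PathFit:
    """Fit the whole λ path with warm starts, strong rules and KKT repair.

    At each λ the strong set (unpenalized ∪ previously active ∪ sequential
    strong-rule survivors) is solved to convergence, then a full KKT sweep
    over all predictors adds any violators and the fit is repeated, so every
    reported solution satisfies the KKT conditions over all columns.

    ``max_active`` truncates the path once a solution exceeds that many
    active SNPs (the usual early exit when only the sparse end is needed).
    """
    fam = BinomialFamily()
    y = np.asarray(y, dtype=float)
    v = spec.validate(rs.X.shape[1])
    q = rs.X.shape[1]
    n = rs.X.shape[0]
    unpen = np.where(v == 0)[0]
    pen_mask = v > 0

    beta, b, Q0, ell0, yt0, grad, lam_max = _stage0(
        rs, y, v, null, fam, inner_tol, max_sweeps, outer_tol, max_outer)
    lambdas = _make_grid(lam_max, spec)
    L = len(lambdas)

    coef = np.zeros((q, L))
    b_prof = np.zeros((n, L))
    ytil = np.zeros((n, L))
    objective = np.zeros(L)
    ell_pql = np.zeros(L)
    n_active = np.zeros(L, dtype=int)
    conv_flags = np.zeros(L, dtype=bool)
    actives: list[np.ndarray] = []

    lam_prev = max(lam_max, lambdas[0])
    n_unconverged = 0
    n_used = L
    for k, lam in enumerate(lambdas):
        if spec.lambdas is None and k == 0:
            # λ = λ_max: the unpenalized-only solution is the path solution
            Q, ell, yt, conv = Q0 + 0.0, ell0, yt0, True
        else:
            screen = pen_mask & (np.abs(grad) >= v * (2.0 * lam - lam_prev))
            strong = np.where((v == 0) | (beta != 0) | screen)[0]
            for repair in range(50):
                lamv = lam * v[strong]
                beta_s, b, Q, ell, yt, conv = _solve_at(
                    rs, y, strong, beta[strong], b, lamv, fam,
                    inner_tol, max_sweeps, outer_tol, max_outer)
                beta = beta.copy()
                beta[strong] = beta_s
                grad = _full_gradient(rs, yt, beta)
                out = pen_mask.copy()
                out[strong] = False
                viol = out & (np.abs(grad) > lam * v + kkt_slack)
                if not viol.any():
                    break
                logger.debug("λ[%d]: %d KKT violators added", k, viol.sum())
                strong = np.union1d(strong, np.where(viol)[0])
            if not conv:
                n_unconverged += 1
                logger.debug("outer loop not converged at λ[%d]=%.4g", k, lam)
        if k == 0 and spec.lambdas is None:
            grad = _full_gradient(rs, yt, beta)
        act = np.where(pen_mask & (beta != 0))[0]
        coef[:, k] = beta
        b_prof[:, k] = b
        ytil[:, k] = yt
        objective[k] = Q
        ell_pql[k] = ell
        n_active[k] = len(act)
        conv_flags[k] = conv
        actives.append(act)
        lam_prev = lam
        if max_active is not None and len(act) > max_active:
            n_used = k + 1
            logger.info("path truncated at λ[%d]: %d active > max_active=%d",
                        k, len(act), max_active)
            break

    if n_unconverged:
        logger.warning("outer loop hit max_outer at %d of %d path points",
                       n_unconverged, n_used)
    s = slice(0, n_used)
    return PathFit(lambdas=lambdas[s], coef=coef[:, s], b_prof=b_prof[:, s],
                   ytilde=ytil[:, s], objective=objective[s],
                   ell_pql=ell_pql[s], n_active=n_active[s],
                   active=actives, converged=conv_flags[s], penalty_factors=v)


def kkt_violation(fit: PathFit, rs: RotatedSystem, tol_active: float = 1e-6):
    """Max KKT residual per λ: inactive excess |g_j| - λv_j and active |g_j| - λv_j.

    Returns an (L,) array of the worst violation at each path point (0 when
    the conditions hold within machine terms).
    """
    v = fit.penalty_factors
    pen = v > 0
    out = np.zeros(fit.n_lambda)
    for k in range(fit.n_lambda):
        grad = _full_gradient(rs, fit.ytilde[:, k], fit.coef[:, k])
        lamv = fit.lambdas[k] * v
        active = pen & (fit.coef[:, k] != 0)
        inactive = pen & ~active
        excess = np.abs(grad[inactive]) - lamv[inactive]
        worst = excess.max(initial=0.0)
        if active.any():
            worst = max(worst, np.abs(np.abs(grad[active]) - lamv[active]).max())
        out[k] = max(worst, 0.0)
    return out


def fit_path(null: NullFit, km: KinshipModel, Xcov: np.ndarray, G: np.ndarray,
             y: np.ndarray, spec: PenaltySpec | None = None,
             family: str = "binomial", **solver_kwargs) -> tuple[PathFit, RotatedSystem]:
    """Assemble [Xcov, G], default penalty factors, rotate and fit the path."""
    spec = spec or PenaltySpec()
    Xfull = np.column_stack([Xcov, G])
    if spec.penalty_factors is None:
        spec = PenaltySpec(lambdas=spec.lambdas, nlambda=spec.nlambda,
                           lambda_min_ratio=spec.lambda_min_ratio,
                           penalty_factors=default_penalty_factors(
                               Xcov.shape[1], G.shape[1]),
                           kappa=spec.kappa)
    rs = build_rotated(null, km, Xfull, family=family)
    fit = cd_fit(rs, y, spec, null, **solver_kwargs)
    return fit, rs


def adaptive_weights(G: np.ndarray, X: np.ndarray, y: np.ndarray,
                     kappa: float, max_iter: int = 50, tol: float = 1e-8,
                     cap: float = 1e6, block: int = 1024) -> np.ndarray:
    """Adaptive-lasso penalty factors v_j = |β̂_j|^{-κ} from marginal fits.

    β̂_j is the SNP coefficient of a univariable logistic regression of y on
    (covariates, g̃_j), fitted by a vectorized Newton solver.  Fits showing
    separation (non-finite or |β̂| > 10) are redone with a ridge stabilizer
    and logged.  Weights are capped at ``cap``.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    p = G.shape[1]
    if kappa == 0:
        return np.ones(p)
    beta = np.empty(p)
    for start in range(0, p, block):
        sl = slice(start, min(start + block, p))
        beta[sl] = _marginal_block(G[:, sl], X, y, max_iter, tol)
    bad = ~np.isfinite(beta) | (np.abs(beta) > 10.0)
    if bad.any():
        logger.warning("ridge-stabilizing %d separated marginal fit(s)", bad.sum())
        beta[bad] = _marginal_block(G[:, bad], X, y, max_iter, tol, ridge=1e-2)
    v = np.abs(beta) ** (-kappa)
    return np.minimum(v, cap)


def _marginal_block(G, X, y, max_iter, tol, ridge=1e-8):
    n, m = X.shape
    p = G.shape[1]
    fam = BinomialFamily()
    A = np.zeros((p, m + 1))
    I = np.eye(m + 1) * ridge
    for _ in range(max_iter):
        eta = X @ A[:, :m].T + G * A[:, m]
        mu = np.clip(fam.inverse_link(eta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        resid = y[:, None] - mu
        gX = X.T @ resid                      # (m, p)
        gg = np.einsum("np,np->p", G, resid)  # (p,)
        grad = np.concatenate([gX, gg[None, :]], axis=0).T - ridge * A
        Hxx = np.einsum("ni,np,nj->pij", X, w, X)
        Hxg = np.einsum("ni,np,np->pi", X, w, G)
        Hgg = np.einsum("np,np,np->p", G, w, G)
        H = np.empty((p, m + 1, m + 1))
        H[:, :m, :m] = Hxx
        H[:, :m, m] = Hxg
        H[:, m, :m] = Hxg
        H[:, m, m] = Hgg
        H += I
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        np.clip(step, -5.0, 5.0, out=step)
        A += step
        if np.max(np.abs(step)) < tol:
            break
    return A[:, m]
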