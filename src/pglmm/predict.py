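"""Out-of-sample prediction for new individuals.

Two predictors are provided: the mixed-model conditional expectation, which
carries the training random effect to the test set through the cross-GRM
(genomic BLUP of the confounding term), and the PC-adjustment GLM baseline,
which projects a fixed number of training PCs onto the test set.  The mixed
predictor shrinks every PC direction smoothly by τ̂₁Λ_i/(c + τ̂₁Λ_i); the PC
GLM keeps the first r directions unshrunk and discards the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinship import KinshipModel
from .nullmodel import BinomialFamily
from .penpath import BOUND_BINOMIAL

_expit = BinomialFamily.inverse_link


@dataclass
class PredictionSet:
    """Aligned test-set design and cross-similarity to the training set."""

    Xs: np.ndarray   # (n_s, q) test design, training standardization
    V12: np.ndarray  # (n_s, n) test-by-train GSM
    mu_hat: np.ndarray | None = None


def predict_mixed(beta: np.ndarray, ytilde: np.ndarray, X_train: np.ndarray,
                  km: KinshipModel, Xs: np.ndarray, V12: np.ndarray,
                  c_bound: float = BOUND_BINOMIAL):
    """Conditional-expectation prediction under the single-GRM mixed model.

    η_s = X̃_s β̂ + τ̂₁ V12 (W⁻¹ + τ̂₁V₁)⁻¹ (Ỹ - X̃β̂) with the bound weights
    W = I/c used throughout the fit, so training-set self-prediction
    reproduces the fitted linear predictor X̃β̂ + b̂ exactly.

    Returns (linear predictor, probabilities).
    """
    if len(km.tau) != 1:
        raise ValueError("mixed-model prediction supports a single GRM component")
    tau1 = float(km.tau[0])
    resid = ytilde - X_train @ beta
    # (cI + τ₁V₁)⁻¹ = U diag(1/(c + τ₁Λ)) Uᵀ
    factor = tau1 / (c_bound + tau1 * km.Lambda)
    blup = km.U @ (factor * (km.U.T @ resid))
    eta_s = Xs @ beta + V12 @ blup
    return eta_s, _expit(eta_s)


def pc_glm_coefficients(Ur: np.ndarray, W: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """GLS coefficients δ̂ = (UrᵀWUr)⁻¹UrᵀW(Ỹ - X̃β̂) for the top-r PCs."""
    if Ur.shape[1] == 0:
        return np.zeros(0)
    Wm = np.diag(W) if W.ndim == 1 else W
    A = Ur.T @ Wm @ Ur
    if np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError("singular UrᵀWUr in PC-GLM solve")
    return np.linalg.solve(A, Ur.T @ (Wm @ resid))


def predict_pc_glm(beta: np.ndarray, ytilde: np.ndarray, X_train: np.ndarray,
                   km: KinshipModel, r: int, Xs: np.ndarray, V12: np.ndarray,
                   W: np.ndarray | None = None):
    """PC-projection GLM prediction: η_s = X̃_s β̂ + V12 U_r δ̂.

    W defaults to the bound weights I/c used in fitting; r = 0 reduces to
    fixed-effects-only prediction.

    Returns (linear predictor, probabilities).
    """
    n = X_train.shape[0]
    if not 0 <= r <= n:
        raise ValueError("number of PCs must be between 0 and n")
    if W is None:
        W = np.full(n, 1.0 / BOUND_BINOMIAL)
    Ur = km.U[:, :r]
    delta = pc_glm_coefficients(Ur, W, ytilde - X_train @ beta)
    eta_s = Xs @ beta + (V12 @ Ur) @ delta if r > 0 else Xs @ beta
    return eta_s, _expit(eta_s)
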