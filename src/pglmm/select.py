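"""Model selection along the λ path: training AIC or validation AUC.

Data splitting is family-aware: connected components of the thresholded
kinship graph are assigned to sets atomically so that no related pair is
split across training/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import roc_auc_score

from .kinship import KinshipModel
from .nullmodel import NullFit
from .penpath import PathFit
from .predict import predict_mixed

# 2 x third-degree kinship coefficient (2^-4), on the GRM scale
RELATEDNESS_THRESHOLD = 0.0884


@dataclass
class SelectionResult:
    criterion: str           # "aic" or "cv_auc"
    best_lambda: float
    best_index: int
    scores: np.ndarray
    model_size: int


def aic(path: PathFit) -> np.ndarray:
    """AIC_l = -2 ℓ_PQL(λ_l) + 2 df_l, df = all nonzero fixed effects."""
    df = np.count_nonzero(path.coef, axis=0)
    return -2.0 * path.ell_pql + 2.0 * df


def aic_select(path: PathFit) -> SelectionResult:
    scores = aic(path)
    best = int(np.argmin(scores))  # first minimum = largest λ on ties
    return SelectionResult(criterion="aic", best_lambda=float(path.lambdas[best]),
                           best_index=best, scores=scores,
                           model_size=int(path.n_active[best]))


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney, ties counted half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes in the labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cv_select(path: PathFit, km: KinshipModel, X_train: np.ndarray,
              y_valid: np.ndarray, Xs_valid: np.ndarray,
              V12: np.ndarray) -> SelectionResult:
    """Pick λ maximizing validation AUC of the mixed-model predictions.

    The path and null model must have been fitted on the training set only;
    an all-zero-SNP model is allowed to win.  Ties break toward larger λ.
    """
    y_valid = np.asarray(y_valid)
    if len(np.unique(y_valid)) < 2:
        raise ValueError("validation set has a single class")
    scores = np.empty(path.n_lambda)
    for k in range(path.n_lambda):
        eta_s, _ = predict_mixed(path.coef[:, k], path.ytilde[:, k],
                                 X_train, km, Xs_valid, V12)
        scores[k] = auc(eta_s, y_valid)
    best = int(np.argmax(scores))  # first maximum = largest λ on ties
    return SelectionResult(criterion="cv_auc",
                           best_lambda=float(path.lambdas[best]),
                           best_index=best, scores=scores,
                           model_size=int(path.n_active[best]))


def split_families(ids, V1: np.ndarray, fractions, seed: int,
                   threshold: float = RELATEDNESS_THRESHOLD):
    """Partition samples into sets, keeping kinship components intact.

    Pairs with V1[i, k] > threshold form edges; connected components are
    assigned atomically, largest first, to the set with the greatest
    remaining deficit (component order randomized by ``seed``).

    Returns a list of index arrays, one per fraction.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    if V1.shape != (n, n):
        raise ValueError("kinship matrix does not match sample count")

    A = (V1 > threshold).astype(np.int8)
    np.fill_diagonal(A, 0)
    n_comp, labels = connected_components(csr_matrix(A), directed=False)
    comp_members = [np.where(labels == c)[0] for c in range(n_comp)]
    sizes = np.array([len(c) for c in comp_members])
    if sizes.max() > fractions.max() * n:
        raise ValueError(
            f"a related component of size {sizes.max()} exceeds the largest "
            "target set; raise the relatedness threshold or merge sets")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_comp)
    # stable big-to-small pass keeps fractions balanced; rng breaks ties
    order = order[np.argsort(-sizes[order], kind="stable")]
    targets = fractions * n
    filled = np.zeros(len(fractions))
    assignment = [[] for _ in fractions]
    for c in order:
        deficit = targets - filled
        g = int(np.argmax(deficit))
        assignment[g].append(comp_members[c])
        filled[g] += sizes[c]
    return [np.sort(np.concatenate(a)) if a else np.array([], dtype=int)
            for a in assignment]
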