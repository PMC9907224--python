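"""Genetic similarity matrices and their spectral decomposition.

The GRM is V = G̃G̃ᵀ/p over standardized genotypes; the combined fitted
random-effect covariance K = Σ_s τ_s V_s is eigendecomposed once, and the
whole penalized fit runs in that rotated basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeData, standardize_genotypes

SYM_TOL = 1e-8


@dataclass
class KinshipModel:
    """Random-effect covariance structure and its eigendecomposition.

    U and eigvals decompose K = Σ_s τ_s V_s (descending).  Lambda holds the
    eigenvalues of V_1 alone, used for the per-component shrinkage factors
    in mixed-model prediction.
    """

    Vs: list[np.ndarray]
    tau: np.ndarray
    U: np.ndarray
    eigvals: np.ndarray
    Lambda: np.ndarray

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def K(self) -> np.ndarray:
        return (self.U * self.eigvals) @ self.U.T


def _check_symmetric(V: np.ndarray, name: str = "matrix") -> None:
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(V, V.T, atol=SYM_TOL):
        raise ValueError(f"{name} is not symmetric (tol {SYM_TOL})")


def estimate_grm(g: GenotypeData, snp_subset=None, min_maf: float = 0.01) -> np.ndarray:
    """GRM from standardized genotypes: V = G̃G̃ᵀ / p_used.

    SNPs with MAF < ``min_maf`` (default 0.01) are excluded; an empty panel
    after filtering is an error.
    """
    if snp_subset is not None:
        g = g.subset_variants(np.asarray(snp_subset))
    f = g.maf
    keep = np.where(np.minimum(f, 1.0 - f) >= min_maf)[0]
    if len(keep) == 0:
        raise ValueError("no SNPs left after MAF filter; cannot build GRM")
    z, _ = standardize_genotypes(g.subset_variants(keep))
    return (z @ z.T) / z.shape[1]


def cross_grm(g_train: GenotypeData, g_test: GenotypeData,
              snp_subset=None, min_maf: float = 0.01) -> np.ndarray:
    """Test-by-train GRM V12 = G̃_test G̃_trainᵀ / p_used.

    Test genotypes are standardized with the *training* allele frequencies
    so the cross-similarity conditions on the training model; variant ids
    and allele orientation must match between the two sets.
    """
    if snp_subset is not None:
        idx = np.asarray(snp_subset)
        g_train = g_train.subset_variants(idx)
        g_test = g_test.subset_variants(idx)
    vt, vs = g_train.variants, g_test.variants
    same = (vt["id"].values == vs["id"].values) & \
           (vt["a1"].values == vs["a1"].values)
    if not same.all():
        raise ValueError("variant id/allele mismatch between train and test sets")
    maf_train = g_train.maf
    keep = np.where(np.minimum(maf_train, 1.0 - maf_train) >= min_maf)[0]
    if len(keep) == 0:
        raise ValueError("no SNPs left after MAF filter; cannot build cross-GRM")
    # train MAFs in [min_maf, 0.5] are never monomorphic, so no columns drop
    z_train, _ = standardize_genotypes(g_train.subset_variants(keep))
    z_test, _ = standardize_genotypes(
        g_test.subset_variants(keep), maf=maf_train[keep])
    return (z_test @ z_train.T) / z_train.shape[1]


def eigendecompose(Vs, tau) -> KinshipModel:
    """Spectral decomposition of K = Σ_s τ_s V_s (eigenvalues descending).

    Small negative eigenvalues (finite-panel GRMs are PSD only numerically)
    are clamped to 0; negative eigenvalues below -1e-8·max(d) are rejected.
    """
    if isinstance(Vs, np.ndarray):
        Vs = [Vs]
    Vs = [np.asarray(V, dtype=float) for V in Vs]
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if len(tau) != len(Vs):
        raise ValueError("need one variance component per matrix")
    if (tau < 0).any():
        raise ValueError("variance components must be nonnegative")
    for i, V in enumerate(Vs):
        _check_symmetric(V, f"V_{i + 1}")

    n = Vs[0].shape[0]
    if len(Vs) == 1:
        Lam, U = np.linalg.eigh(Vs[0])
        Lam, U = Lam[::-1].copy(), U[:, ::-1].copy()
        Lam = _clamp_eigvals(Lam)
        d = tau[0] * Lam
    else:
        K = sum(t * V for t, V in zip(tau, Vs))
        d, U = np.linalg.eigh(K)
        d, U = d[::-1].copy(), U[:, ::-1].copy()
        d = _clamp_eigvals(d)
        Lam = np.linalg.eigvalsh(Vs[0])[::-1].copy()
        Lam = _clamp_eigvals(Lam)
    return KinshipModel(Vs=Vs, tau=tau, U=U, eigvals=d, Lambda=Lam)


def _clamp_eigvals(d: np.ndarray) -> np.ndarray:
    scale = max(d.max(initial=0.0), 1.0)
    if (d < -1e-8 * scale).any():
        raise ValueError("matrix has substantially negative eigenvalues; not PSD")
    return np.clip(d, 0.0, None)


def write_kinship(V: np.ndarray, samples, path) -> None:
    """Write a kinship matrix as dense CSV with a sample-id header row."""
    pd.DataFrame(V, columns=list(map(str, samples))).to_csv(path, index=False)


def read_kinship(path, samples=None) -> np.ndarray:
    """Read a dense-CSV kinship matrix, optionally checking the sample order."""
    df = pd.read_csv(path)
    if samples is not None:
        expected = list(map(str, samples))
        if list(df.columns) != expected:
            raise ValueError("kinship header does not match expected sample order")
    V = df.to_numpy(dtype=float)
    _check_symmetric(V, "kinship matrix")
    return V
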