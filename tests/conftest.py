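import numpy as np
import pandas as pd
import pytest

from pglmm import (GenotypeData, PenaltySpec, eigendecompose, fit_null,
                   fit_path)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_genotypes(counts, ids=None, samples=None):
    counts = np.asarray(counts, dtype=np.int8)
    n, p = counts.shape
    variants = pd.DataFrame({
        "id": ids or [f"snp{j}" for j in range(p)],
        "chrom": 1, "pos": np.arange(1, p + 1), "a1": "A", "a2": "B",
    })
    samples = pd.Index(samples or [f"s{i}" for i in range(n)])
    return GenotypeData(samples, variants, counts)


@pytest.fixture
def small_genotypes():
    # 4 samples x 3 SNPs; column 2 has dosage frequencies (.25, .5, .25)
    return make_genotypes([[0, 1, 0],
                           [1, 2, 1],
                           [2, 1, 1],
                           [0, 0, 2]])


def random_psd(rng, n, rank=None):
    A = rng.normal(size=(n, rank or n))
    return A @ A.T / (rank or n)


@pytest.fixture(scope="session")
def fitted_glmm():
    """A small structured dataset with a converged null fit and lasso path.

    Shared (read-only) across tests that only inspect invariants of a
    converged fit.
    """
    rng = np.random.default_rng(7)
    n, p, m = 120, 60, 2
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    G = rng.normal(size=(n, p))
    A = rng.normal(size=(n, n // 2))
    V = A @ A.T / (n // 2)
    L = np.linalg.cholesky(V + 1e-8 * np.eye(n))
    b = L @ rng.normal(size=n)
    eta = X @ np.array([-0.5, 0.4]) + G[:, :4] @ np.array([.6, -.6, .5, -.5]) + b
    y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    null = fit_null(X, y, [V])
    km = eigendecompose([V], null.tau)
    fit, rs = fit_path(null, km, X, G, y,
                       spec=PenaltySpec(nlambda=25, lambda_min_ratio=0.05))
    return dict(X=X, G=G, V=V, y=y, null=null, km=km, fit=fit, rs=rs)
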