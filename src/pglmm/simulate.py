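"""Synthetic structured-population GWAS experiments.

Genotypes come from the Balding–Nichols / Pritchard–Stephens–Donnelly
(BN-PSD) admixture model: ancestral frequencies drift within each of K
subpopulations (Balding–Nichols beta distribution with drift F_u), and each
individual mixes subpopulation frequencies through admixture proportions —
either a 1D linear-geography kernel or disjoint independent blocks.  Binary
liabilities follow a logistic model whose polygenic confounder b = Uδ is
drawn in the eigenbasis of the realized kinship panel GRM, so the random
effect is correlated with population structure by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeData, standardize_genotypes
from .kinship import KinshipModel, eigendecompose, estimate_grm, cross_grm
from .nullmodel import BinomialFamily, fit_null
from .penpath import PenaltySpec, fit_path
from .predict import predict_mixed
from .select import auc as roc_auc

logger = logging.getLogger(__name__)

_expit = BinomialFamily.inverse_link


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic experiment.

    Defaults are the first-scenario conditions: n = 2500 individuals,
    p = 5000 candidate SNPs of which c = 1% are causal, K = 10 subpopulations
    with 1D linear admixture, fixed-genetic variance fraction h_g² = 0.5,
    random-polygenic fraction h_b² = 0.4, null prevalence π₀ = 0.1, and a
    disjoint 50 000-SNP panel for the kinship matrix.
    """

    n: int = 2500
    p: int = 5000
    p_kinship: int = 50_000
    c: float = 0.01
    K: int = 10
    structure: str = "admix_1d"
    h_g2: float = 0.5
    h_b2: float = 0.4
    pi0: float = 0.1
    F: np.ndarray | None = None
    sigma_geo: float = 1.0
    maf_min: float = 0.01
    sex_beta: float = -np.log(1.3)
    age_beta: float = np.log(1.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.c <= 1:
            raise ValueError("causal fraction must be in (0, 1]")
        if self.h_g2 + self.h_b2 >= 1 or min(self.h_g2, self.h_b2) < 0:
            raise ValueError("variance fractions must be >= 0 and sum below 1")
        if not 0 < self.pi0 < 1:
            raise ValueError("null prevalence must be in (0, 1)")
        if self.structure not in ("admix_1d", "independent"):
            raise ValueError("structure must be 'admix_1d' or 'independent'")
        if self.F is None:
            # per-subpopulation drift ladder, mild to moderate differentiation
            self.F = np.linspace(0.05, 0.2, self.K)
        self.F = np.asarray(self.F, dtype=float)
        if len(self.F) != self.K or ((self.F <= 0) | (self.F >= 1)).any():
            raise ValueError("need K drift values F_u in (0, 1)")
        if self.sigma_geo <= 0:
            raise ValueError("sigma_geo must be positive")

    @property
    def n_causal(self) -> int:
        return int(round(self.p * self.c))


@dataclass
class BnpsdResult:
    genotypes: GenotypeData  # candidates first, kinship panel after
    admixture: np.ndarray    # (n, K)
    candidate_idx: np.ndarray
    kinship_idx: np.ndarray


@dataclass
class SimReplicate:
    """One synthetic dataset with full ground truth."""

    genotypes: GenotypeData
    candidate_idx: np.ndarray
    kinship_idx: np.ndarray
    covariates: pd.DataFrame      # sex, age
    X: np.ndarray                 # (n, 3) intercept, sex, age
    causal_set: np.ndarray        # indices into the candidate SNPs
    beta_true: np.ndarray         # (p,) causal effects on standardized scale
    b_true: np.ndarray
    y: np.ndarray
    V: np.ndarray                 # kinship-panel GRM (the b-generating model)
    km_true: KinshipModel
    admixture: np.ndarray
    audit: dict = field(default_factory=dict)


def admixture_proportions(cfg: SimConfig) -> np.ndarray:
    """Admixture matrix Q (n x K) for the configured structure."""
    if cfg.structure == "admix_1d":
        x = np.linspace(1.0, cfg.K, cfg.n)
        u = np.arange(1, cfg.K + 1, dtype=float)
        Q = np.exp(-((x[:, None] - u[None, :]) ** 2) / (2.0 * cfg.sigma_geo**2))
        return Q / Q.sum(axis=1, keepdims=True)
    # independent subpopulations: one-hot in K (nearly) equal blocks
    labels = np.minimum((np.arange(cfg.n) * cfg.K) // cfg.n, cfg.K - 1)
    Q = np.zeros((cfg.n, cfg.K))
    Q[np.arange(cfg.n), labels] = 1.0
    return Q


def _draw_snps(rng, Q, F, m):
    """Draw m BN-PSD SNPs: returns (counts int8 (n, m), per-SNP freq matrix)."""
    K = Q.shape[1]
    p_anc = rng.uniform(0.01, 0.5, size=m)
    a = p_anc[None, :] * (1.0 - F[:, None]) / F[:, None]
    b = (1.0 - p_anc[None, :]) * (1.0 - F[:, None]) / F[:, None]
    P = rng.beta(a, b)                       # (K, m) subpopulation frequencies
    pi = np.clip(Q @ P, 1e-12, 1 - 1e-12)    # (n, m) individual frequencies
    counts = rng.binomial(2, pi).astype(np.int8)
    return counts, P


def simulate_bnpsd(cfg: SimConfig, rng=None, max_rounds: int = 50) -> BnpsdResult:
    """BN-PSD genotypes for candidates plus the kinship panel.

    SNPs whose realized sample MAF falls below ``cfg.maf_min`` are redrawn
    (fresh ancestral and subpopulation frequencies) until none remain.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    Q = admixture_proportions(cfg)
    m_total = cfg.p + cfg.p_kinship
    counts = np.empty((cfg.n, m_total), dtype=np.int8)

    chunk = 4096
    for start in range(0, m_total, chunk):
        m = min(chunk, m_total - start)
        block, _ = _draw_snps(rng, Q, cfg.F, m)
        for _ in range(max_rounds):
            f = block.mean(axis=0) / 2.0
            bad = np.minimum(f, 1 - f) < cfg.maf_min
            if not bad.any():
                break
            block[:, bad], _ = _draw_snps(rng, Q, cfg.F, int(bad.sum()))
        else:
            raise RuntimeError("could not reach the MAF floor; check F/maf_min")
        counts[:, start:start + m] = block

    ids = [f"cand{j:06d}" for j in range(cfg.p)] + \
          [f"kin{j:06d}" for j in range(cfg.p_kinship)]
    variants = pd.DataFrame({
        "id": ids, "chrom": 1, "pos": np.arange(1, m_total + 1),
        "a1": "A", "a2": "B",
    })
    samples = pd.Index([f"id{i:06d}" for i in range(cfg.n)])
    g = GenotypeData(samples, variants, counts)
    return BnpsdResult(genotypes=g, admixture=Q,
                       candidate_idx=np.arange(cfg.p),
                       kinship_idx=np.arange(cfg.p, m_total))


def simulate_phenotype(g: GenotypeData, candidate_idx, km_true: KinshipModel,
                       cfg: SimConfig, rng) -> dict:
    """Binary liability phenotype with a structure-confounded polygenic term.

    σ² is defined so the logistic residual variance π²/3 is the
    (1 - h_g² - h_b²) share of the liability variance; causal effects act on
    standardized candidate genotypes, and b = Uδ with δ ~ N(0, h_b²σ²·D)
    drawn in the eigenbasis of the kinship-panel GRM.
    """
    n = g.n
    p = len(candidate_idx)
    n_causal = int(round(p * cfg.c))
    sigma2 = (np.pi**2 / 3.0) / (1.0 - cfg.h_g2 - cfg.h_b2)

    causal = np.sort(rng.choice(p, size=n_causal, replace=False))
    beta = np.zeros(p)
    if n_causal:
        beta[causal] = rng.normal(0.0, np.sqrt(cfg.h_g2 * sigma2 / n_causal),
                                  size=n_causal)

    delta = rng.normal(0.0, 1.0, size=n) * np.sqrt(
        np.maximum(cfg.h_b2 * sigma2 * km_true.Lambda, 0.0))
    b = km_true.U @ delta

    age = rng.normal(50.0, 5.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)

    zc, kept = standardize_genotypes(g.subset_variants(candidate_idx))
    genetic = np.zeros(n)
    if n_causal:
        genetic = zc @ beta[kept]

    logit_pi = (np.log(cfg.pi0 / (1 - cfg.pi0)) + cfg.sex_beta * sex
                + cfg.age_beta * age / 10.0 + genetic + b)
    y = rng.binomial(1, _expit(logit_pi)).astype(int)

    audit = {
        "var_genetic": float(np.var(genetic)),
        "var_b": float(np.var(b)),
        "sigma2": sigma2,
        "target_var_genetic": cfg.h_g2 * sigma2,
        "target_var_b": cfg.h_b2 * sigma2,
    }
    return {"causal": causal, "beta": beta, "b": b, "age": age, "sex": sex,
            "y": y, "audit": audit}


def simulate_replicate(cfg: SimConfig, seed: int | None = None) -> SimReplicate:
    """Full replicate: genotypes, panel GRM, eigendecomposition, phenotype."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    bn = simulate_bnpsd(cfg, rng)
    V = estimate_grm(bn.genotypes, snp_subset=bn.kinship_idx,
                     min_maf=cfg.maf_min)
    km_true = eigendecompose([V], [1.0])
    ph = simulate_phenotype(bn.genotypes, bn.candidate_idx, km_true, cfg, rng)
    X = np.column_stack([np.ones(cfg.n), ph["sex"], ph["age"]])
    cov = pd.DataFrame({"sex": ph["sex"], "age": ph["age"]})
    return SimReplicate(
        genotypes=bn.genotypes, candidate_idx=bn.candidate_idx,
        kinship_idx=bn.kinship_idx, covariates=cov, X=X,
        causal_set=ph["causal"], beta_true=ph["beta"], b_true=ph["b"],
        y=ph["y"], V=V, km_true=km_true, admixture=bn.admixture,
        audit=ph["audit"],
    )


def score_replicate(beta_hat: np.ndarray, beta_true: np.ndarray,
                    causal_set: np.ndarray, preds=None, labels=None) -> dict:
    """TPR / RMSE / precision of a SNP coefficient vector, optional AUC."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    if len(beta_hat) != len(beta_true):
        raise ValueError("coefficient vectors differ in length")
    if len(causal_set) == 0:
        raise ValueError("TPR is undefined with an empty causal set")
    selected = np.where(beta_hat != 0)[0]
    tp = len(np.intersect1d(selected, causal_set))
    out = {
        "tpr": tp / len(causal_set),
        "rmse": float(np.sqrt(np.mean((beta_hat - beta_true) ** 2))),
        "precision": tp / len(selected) if len(selected) else np.nan,
        "n_selected": len(selected),
    }
    if preds is not None and labels is not None:
        out["auc"] = roc_auc(preds, labels)
    return out


def _nearest_size_index(n_active: np.ndarray, target: int) -> int:
    # ties break toward the sparser (larger-λ, earlier) path point
    return int(np.argmin(np.abs(n_active.astype(int) - target)))


def run_scenario1(cfg: SimConfig, methods=("pglmm", "lasso_pc", "lasso"),
                  n_reps: int = 10, active_sizes=None, seed: int = 0,
                  r_pcs: int = 10, train_frac: float = 0.8,
                  spec: PenaltySpec | None = None,
                  **solver_kwargs) -> pd.DataFrame:
    """Fixed-model-size comparison of pglmm against lasso baselines.

    For each replicate the sample is split 80/20, each method's lasso path
    is fitted on the training portion, and at every target active-set size
    the nearest path point is scored for TPR/RMSE and test-set AUC.
    `lasso_pc` adds the top ``r_pcs`` kinship PCs as unpenalized covariates
    (test-set PCs are the projections V12·U_r); `lasso` has no adjustment.
    """
    if active_sizes is None:
        top = cfg.n_causal
        active_sizes = tuple(range(5, top + 1, 5)) or (top,)
    # only the sparse end of the path is scored; stop fitting shortly beyond
    solver_kwargs.setdefault("max_active", 2 * max(active_sizes) + 10)
    rows = []
    for rep_i in range(n_reps):
        rep = simulate_replicate(cfg, seed=seed + rep_i)
        rng = np.random.default_rng(seed + rep_i + 1_000_003)
        perm = rng.permutation(cfg.n)
        ntr = int(round(train_frac * cfg.n))
        tr, te = np.sort(perm[:ntr]), np.sort(perm[ntr:])
        rows.extend(_score_one_replicate(
            rep, tr, te, methods, active_sizes, r_pcs, rep_i, spec,
            solver_kwargs))
    return pd.DataFrame(rows)


def _score_one_replicate(rep, tr, te, methods, active_sizes, r_pcs, rep_i,
                         spec, solver_kwargs):
    cfg_spec = spec or PenaltySpec()
    g = rep.genotypes
    g_tr, g_te = g.subset_samples(tr), g.subset_samples(te)
    y_tr, y_te = rep.y[tr], rep.y[te]
    X_tr, X_te = rep.X[tr], rep.X[te]

    V_tr = estimate_grm(g_tr, snp_subset=rep.kinship_idx)
    V12 = cross_grm(g_tr.subset_variants(rep.kinship_idx),
                    g_te.subset_variants(rep.kinship_idx))
    kmV = eigendecompose([V_tr], [1.0])

    cand_tr = g_tr.subset_variants(rep.candidate_idx)
    maf_tr = cand_tr.maf
    Ztr, kept = standardize_genotypes(cand_tr)
    Zte, _ = standardize_genotypes(
        g_te.subset_variants(rep.candidate_idx).subset_variants(kept),
        maf=maf_tr[kept])
    beta_true = rep.beta_true[kept]
    causal = np.where(beta_true != 0)[0]

    fits = {}
    if "pglmm" in methods:
        null = fit_null(X_tr, y_tr, [V_tr])
        km = KinshipModel(Vs=[V_tr], tau=null.tau, U=kmV.U,
                          eigvals=null.tau[0] * kmV.Lambda, Lambda=kmV.Lambda)
        fit, rs = fit_path(null, km, X_tr, Ztr, y_tr, spec=cfg_spec,
                           **solver_kwargs)
        fits["pglmm"] = (fit, rs, km)
    km0 = eigendecompose([np.eye(len(tr))], [0.0])
    if "lasso" in methods:
        fit, rs = fit_path(None, km0, X_tr, Ztr, y_tr, spec=cfg_spec,
                           **solver_kwargs)
        fits["lasso"] = (fit, rs, None)
    if "lasso_pc" in methods:
        Ur = kmV.U[:, :r_pcs]
        fit, rs = fit_path(None, km0, np.column_stack([X_tr, Ur]), Ztr, y_tr,
                           spec=cfg_spec, **solver_kwargs)
        fits["lasso_pc"] = (fit, rs, Ur)

    rows = []
    m = X_tr.shape[1]
    for method, (fit, rs, extra) in fits.items():
        n_cov = m + (r_pcs if method == "lasso_pc" else 0)
        for size in active_sizes:
            k = _nearest_size_index(fit.n_active, size)
            beta_full = fit.coef[:, k]
            snp_beta = beta_full[n_cov:]
            if method == "pglmm":
                Xs_full = np.column_stack([X_te, Zte])
                eta_s, _ = predict_mixed(beta_full, fit.ytilde[:, k], rs.X,
                                         extra, Xs_full, V12)
            elif method == "lasso_pc":
                Xs_full = np.column_stack([X_te, V12 @ extra, Zte])
                eta_s = Xs_full @ beta_full
            else:
                eta_s = np.column_stack([X_te, Zte]) @ beta_full
            sc = score_replicate(snp_beta, beta_true, causal,
                                 preds=eta_s, labels=y_te)
            rows.append({"rep": rep_i, "method": method, "target_size": size,
                         "actual_size": int(fit.n_active[k]),
                         "lambda": float(fit.lambdas[k]), **sc})
    return rows


def summarize_scenario1(results: pd.DataFrame) -> pd.DataFrame:
    """Mean TPR/RMSE/AUC per method and target model size."""
    return (results.groupby(["method", "target_size"])
            [["tpr", "rmse", "auc"]].mean().reset_index())


def plot_scenario1(results: pd.DataFrame, path) -> None:
    """TPR-vs-model-size curves per method (matplotlib optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summ = summarize_scenario1(results)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for metric, ax in zip(["tpr", "rmse", "auc"], axes):
        for method, sub in summ.groupby("method"):
            ax.plot(sub["target_size"], sub[metric], marker="o", label=method)
        ax.set_xlabel("active predictors")
        ax.set_ylabel(metric.upper())
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
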