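"""Genotype/covariate/phenotype I/O and assembly.

Reads PLINK 1 binary filesets (.bed/.bim/.fam), orients alleles so the
counted allele is always the minor one, and aligns covariate tables to the
genotype sample order.  Genotypes are additive minor-allele dosages in
{0, 1, 2}; missing calls are stored as -1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK codes, LSB first within a byte:
#   00 -> 2 copies of allele1, 01 -> missing, 10 -> het, 11 -> 0 copies.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam fileset violates the PLINK 1 format."""


@dataclass
class GenotypeData:
    """Additive genotype counts with sample and variant metadata.

    counts[i, j] is the number of copies of ``variants.a1[j]`` (the minor
    allele after orientation) carried by ``samples[i]``; -1 marks a missing
    call.
    """

    samples: pd.Index
    variants: pd.DataFrame  # columns: id, chrom, pos, a1, a2
    counts: np.ndarray  # (n, p) int8

    def __post_init__(self) -> None:
        self.samples = pd.Index(self.samples)
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            raise ValueError("counts must be an n x p matrix")
        n, p = self.counts.shape
        if n < 1 or p < 1:
            raise ValueError("need at least one sample and one variant")
        if len(self.samples) != n or len(self.variants) != p:
            raise ValueError("metadata does not match counts shape")
        bad = ~np.isin(self.counts, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("counts entries must be in {0,1,2} or missing")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def p(self) -> int:
        return self.counts.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Counted-allele frequency per SNP, ignoring missing entries."""
        c = self.counts
        obs = c != MISSING
        with np.errstate(invalid="ignore"):
            f = np.where(obs, c, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
        return f

    def subset_samples(self, idx) -> "GenotypeData":
        idx = np.asarray(idx)
        return GenotypeData(self.samples[idx], self.variants, self.counts[idx])

    def subset_variants(self, idx) -> "GenotypeData":
        idx = np.asarray(idx)
        return GenotypeData(
            self.samples, self.variants.iloc[idx].reset_index(drop=True),
            self.counts[:, idx],
        )


@dataclass
class CovariateTable:
    """Fixed covariates (with explicit intercept) and a binary response."""

    X: np.ndarray  # (n, m), first column constant 1
    y: np.ndarray  # (n,) in {0, 1}
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if not np.all(self.X[:, 0] == 1.0):
            raise ValueError("first design column must be the intercept")
        if not np.isfinite(self.X).all():
            raise ValueError("covariates contain missing/non-finite values")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("phenotype must be coded {0,1}")


def read_plink(prefix) -> GenotypeData:
    """Read a PLINK 1 binary fileset and orient alleles to the minor allele.

    The .bed must be SNP-major.  Columns whose allele1 is the major allele
    are flipped (dosage 2-d, alleles swapped) so that counts always refer to
    the minor allele; flips are logged.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing {prefix.with_suffix(ext)}")

    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"], dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    n, p = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise PlinkFormatError("not a PLINK 1 .bed file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError("sample-major .bed files are not supported")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * p:
        raise PlinkFormatError(".bed size does not match .bim/.fam")

    codes = body.reshape(p, bytes_per_snp)
    # unpack 4 two-bit codes per byte, LSB first
    expanded = np.empty((p, bytes_per_snp * 4), dtype=np.int8)
    for k in range(4):
        expanded[:, k::4] = _CODE_TO_DOSAGE[(codes >> (2 * k)) & 0b11]
    counts = expanded[:, :n].T.copy()

    g = GenotypeData(pd.Index(fam["iid"]), bim[["id", "chrom", "pos", "a1", "a2"]].copy(), counts)
    return _orient_minor(g)


def _orient_minor(g: GenotypeData) -> GenotypeData:
    """Flip columns so the counted allele is the minor one."""
    freq = g.maf
    flip = freq > 0.5
    if flip.any():
        logger.info("flipping %d SNPs so counts refer to the minor allele", flip.sum())
        c = g.counts.copy()
        miss = c == MISSING
        c[:, flip] = 2 - c[:, flip]
        c[miss] = MISSING
        v = g.variants.copy()
        a1 = v.loc[flip, "a1"].copy()
        v.loc[flip, "a1"] = v.loc[flip, "a2"].values
        v.loc[flip, "a2"] = a1.values
        return GenotypeData(g.samples, v, c)
    return g


def write_plink(g: GenotypeData, prefix) -> None:
    """Write a GenotypeData as a PLINK 1 SNP-major fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = g.n, g.p
    fam = pd.DataFrame({
        "fid": g.samples, "iid": g.samples, "pid": 0, "mid": 0,
        "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    v = g.variants
    bim = pd.DataFrame({
        "chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"],
        "a1": v["a1"], "a2": v["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    code = np.empty_like(g.counts, dtype=np.uint8)
    for dosage, c in _DOSAGE_TO_CODE.items():
        code[g.counts == dosage] = c
    bytes_per_snp = (n + 3) // 4
    padded = np.full((p, bytes_per_snp * 4), _DOSAGE_TO_CODE[0], dtype=np.uint8)
    padded[:, :n] = code.T
    packed = np.zeros((p, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        packed.tofile(fh)


def standardize_genotypes(g: GenotypeData, maf: np.ndarray | None = None):
    """Standardize dosages to g̃ = (g - 2p) / sqrt(2p(1-p)).

    Missing entries are mean-imputed (0 after standardization).  Monomorphic
    SNPs (p = 0 or 1) are dropped with a warning.  ``maf`` overrides the
    frequencies estimated from ``g`` (used to standardize a test set with
    training frequencies).

    Returns (Z, kept) where kept indexes the retained columns of ``g``.
    """
    p_hat = g.maf if maf is None else np.asarray(maf, dtype=float)
    if len(p_hat) != g.p:
        raise ValueError("maf length does not match number of variants")
    if np.isnan(p_hat).any():
        raise ValueError("all-missing genotype column(s): "
                         f"{np.where(np.isnan(p_hat))[0].tolist()}")
    kept = np.where((p_hat > 0.0) & (p_hat < 1.0))[0]
    if len(kept) < g.p:
        warnings.warn(f"dropping {g.p - len(kept)} monomorphic SNP(s)")
    pk = p_hat[kept]
    c = g.counts[:, kept].astype(float)
    miss = c == MISSING
    z = (c - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    z[miss] = 0.0
    return z, kept


_PHENO_MAPS = (
    {0: 0, 1: 1},          # already 0/1
    {1: 0, 2: 1},          # PLINK case/control
    {"control": 0, "case": 1},
)


def _code_phenotype(raw: pd.Series) -> np.ndarray:
    vals = raw.copy()
    if vals.dtype == object:
        vals = vals.astype(str).str.strip().str.lower()
        try:
            vals = vals.astype(float)
        except ValueError:
            pass
    for mapping in _PHENO_MAPS:
        keys = set(mapping)
        uniq = set(vals.unique().tolist())
        try:
            uniq = {int(u) if float(u) == int(float(u)) else u for u in uniq}
            vals_cmp = vals.astype(float).astype(int)
        except (ValueError, TypeError):
            vals_cmp = vals
        if uniq <= keys:
            return vals_cmp.map(mapping).to_numpy()
    raise ValueError(
        f"phenotype values {sorted(map(str, set(raw)))} are not a recognized "
        "binary coding ({0,1}, {1,2} or {control,case})"
    )


def read_covariates(path, pheno: str, covars: list[str],
                    samples: pd.Index | None = None,
                    sample_col: str | None = None) -> CovariateTable:
    """Read a covariate/phenotype CSV and align it to a sample order.

    The phenotype column may be coded {0,1}, {1,2} (PLINK) or
    {control,case}.  If ``samples`` is given, rows are reordered to match
    it using ``sample_col`` (default: first column); unmatched samples are
    an error.  An intercept column is prepended.
    """
    df = pd.read_csv(path)
    if sample_col is None:
        sample_col = df.columns[0]
    df[sample_col] = df[sample_col].astype(str)
    if samples is not None:
        idx = pd.Index(df[sample_col])
        missing = pd.Index(samples).difference(idx)
        if len(missing):
            raise ValueError(f"samples absent from covariate file: {list(missing)}")
        df = df.set_index(sample_col).loc[pd.Index(samples).astype(str)].reset_index()

    for col in [pheno, *covars]:
        if col not in df.columns:
            raise ValueError(f"column '{col}' not in covariate file")
        na = df[col].isna()
        if na.any():
            rows = df.loc[na, sample_col].tolist()
            raise ValueError(f"missing values in '{col}' for rows {rows}")

    y = _code_phenotype(df[pheno])
    X = np.column_stack([np.ones(len(df)), df[covars].to_numpy(dtype=float)])
    return CovariateTable(X=X, y=y, names=["intercept", *covars])


def hwe_chisq_p(g: GenotypeData) -> np.ndarray:
    """Per-SNP Hardy-Weinberg chi-square p-value (1 df), ignoring missing."""
    from scipy import stats

    c = g.counts
    obs = c != MISSING
    n = obs.sum(axis=0).astype(float)
    n2 = ((c == 2) & obs).sum(axis=0)
    n1 = ((c == 1) & obs).sum(axis=0)
    n0 = n - n1 - n2
    p = (2 * n2 + n1) / (2 * n)
    q = 1 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        e2, e1, e0 = n * p**2, 2 * n * p * q, n * q**2
        chi2 = ((n2 - e2) ** 2 / e2 + (n1 - e1) ** 2 / e1 + (n0 - e0) ** 2 / e0)
    chi2 = np.where(np.isfinite(chi2), chi2, 0.0)
    return stats.chi2.sf(chi2, df=1)


def filter_variants(g: GenotypeData, max_missing: float | None = None,
                    min_hwe_p: float | None = None,
                    min_maf: float | None = None) -> GenotypeData:
    """Optional variant QC (all filters off by default)."""
    keep = np.ones(g.p, dtype=bool)
    if max_missing is not None:
        keep &= (g.counts == MISSING).mean(axis=0) < max_missing
    if min_hwe_p is not None:
        keep &= hwe_chisq_p(g) > min_hwe_p
    if min_maf is not None:
        keep &= g.maf >= min_maf
    return g.subset_variants(np.where(keep)[0])
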