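"""Marginal GWAS statistics, logistic-to-linear conversion, SNP selection.

Effect sizes throughout are on the standardized-genotype scale: the
marginal estimate for SNP j is the slope of a simple regression of the
trait on the standardized dosage column.  For binary traits analysed by
logistic regression, the log odds ratio b1 is mapped to the linear-model
slope mu*(1-mu)*b1 where mu is the baseline case probability, so that
binary-trait summary statistics can feed the same least-squares
imputation machinery as quantitative ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .genodata import AlignmentError, GenotypeMatrix, PhenotypeVector, SummaryStats


def _check_aligned(x: GenotypeMatrix, y: PhenotypeVector) -> None:
    if x.sample_ids != y.sample_ids:
        raise AlignmentError("genotype and phenotype sample ids differ")


def marginal_betas(x_std: GenotypeMatrix, y: PhenotypeVector) -> np.ndarray:
    """Marginal association estimates X'Y / (n - 1) on standardized X.

    With unit-variance columns this equals the no-intercept simple-regression
    slope of y on each standardized dosage column.
    """
    if not x_std.standardized:
        raise ValueError("marginal_betas requires standardized genotypes")
    _check_aligned(x_std, y)
    n = x_std.n_samples
    return x_std.dosages.T @ y.values / (n - 1)


def marginal_gwas(x: GenotypeMatrix, y: PhenotypeVector) -> pd.DataFrame:
    """Per-SNP simple linear regression (with intercept) of y on each column.

    Returns a frame with snp_id, beta, se, t, p per SNP; p is two-sided
    from a t distribution with n-2 degrees of freedom.  p-values below
    1e-300 are reported as 0 with ``underflow`` set.
    """
    if not x.standardized:
        raise ValueError("marginal_gwas expects standardized genotypes")
    _check_aligned(x, y)
    n = x.n_samples
    if n <= 2:
        raise ValueError("need more than 2 samples for per-SNP regression")
    d = x.dosages
    yc = y.values - y.values.mean()
    sxx = (d * d).sum(axis=0)  # columns are centered, so this is (n-1)*var
    sxy = d.T @ yc
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    underflow = p < 1e-300
    p = np.where(underflow, 0.0, p)
    return pd.DataFrame({
        "snp_id": x.snp_ids,
        "beta": beta,
        "se": se,
        "t": t,
        "p_value": p,
        "underflow": underflow,
    })


def gwas_to_sumstats(
    x: GenotypeMatrix, gwas: pd.DataFrame, ancestry_label: str = "",
    n_gwas: int | None = None,
) -> SummaryStats:
    """Package a marginal_gwas table as harmonized SummaryStats for ``x``."""
    by_id = {s.snp_id: s for s in x.snps}
    tab = pd.DataFrame({
        "snp_id": gwas["snp_id"],
        "chrom": [by_id[s].chrom for s in gwas["snp_id"]],
        "pos_bp": [by_id[s].pos_bp for s in gwas["snp_id"]],
        "effect_allele": [by_id[s].effect_allele for s in gwas["snp_id"]],
        "other_allele": [by_id[s].other_allele for s in gwas["snp_id"]],
        "beta_lm": gwas["beta"],
        "se": gwas["se"],
        "p_value": gwas["p_value"],
    })
    if n_gwas is not None:
        tab["n_gwas"] = n_gwas
    return SummaryStats(table=tab, ancestry_label=ancestry_label, harmonized=True)


def glm_to_lm(b0: float, b1) -> np.ndarray | float:
    """Convert a logistic log odds ratio to a linear-model slope.

    beta_lm = e^{-b0} / (1 + e^{-b0})^2 * b1 = mu (1 - mu) b1 with
    mu = logistic(b0); b0 is the log odds of being a case in the SNP
    reference group.  The mu(1-mu) form is stable for large |b0|.
    """
    b0 = float(b0)
    b1 = np.asarray(b1, dtype=np.float64)
    if not np.isfinite(b0) or not np.isfinite(b1).all():
        raise ValueError("b0 and b1 must be finite")
    # expit(b0)*expit(-b0) = mu(1-mu), exact under b0 <-> -b0 and stable
    out = expit(b0) * expit(-b0) * b1
    return float(out) if out.ndim == 0 else out


def logit_baseline(n_cases: int, n_controls: int) -> float:
    """Baseline log odds of case status: log(n_cases / n_controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must both be positive")
    return float(np.log(n_cases / n_controls))


@dataclass(frozen=True)
class SnpSelectionSpec:
    """How many SNPs to carry into imputation, and how to pick them.

    All SNPs significant at ``p_threshold`` are preferred; if more are
    significant than ``target_count`` a random subset of them is taken,
    otherwise the shortfall is filled with randomly chosen nonsignificant
    SNPs.  The random draws are reproducible from ``seed``.
    """

    target_count: int
    p_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_count < 1:
            raise ValueError("target_count must be positive")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")


def select_snps(stats: SummaryStats, spec: SnpSelectionSpec) -> list[str]:
    """Choose the SNP panel for imputation; returns ids sorted by (chrom, pos).

    Significant SNPs (p < threshold) always enter first; the remainder of
    the panel is a seeded uniform draw from the nonsignificant SNPs.
    """
    tab = stats.table
    if "p_value" not in tab.columns:
        raise ValueError("summary stats carry no p-values; cannot select SNPs")
    if spec.target_count > len(tab):
        raise ValueError(
            f"target_count {spec.target_count} exceeds {len(tab)} available SNPs"
        )
    rng = np.random.default_rng(spec.seed)
    p = tab["p_value"].to_numpy(dtype=float)
    sig = np.nonzero(p < spec.p_threshold)[0]
    nonsig = np.nonzero(~(p < spec.p_threshold))[0]
    if len(sig) >= spec.target_count:
        chosen = rng.choice(sig, size=spec.target_count, replace=False)
    else:
        extra = rng.choice(nonsig, size=spec.target_count - len(sig), replace=False)
        chosen = np.concatenate([sig, extra])
    sub = tab.iloc[np.sort(chosen)]
    if {"chrom", "pos_bp"} <= set(sub.columns):
        sub = sub.sort_values(["chrom", "pos_bp"], kind="mergesort")
    return sub["snp_id"].tolist()
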