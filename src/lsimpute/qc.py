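"""SNP-level quality control: MAF, missingness, HWE exact test, LD pruning.

Defaults follow standard GWAS practice for biobank-scale cohorts: drop
variants with minor allele frequency below 0.05, more than 10% missing
calls, or a Hardy-Weinberg exact-test p-value below 1e-3; then prune
linkage disequilibrium with a 50-SNP window, step 5 and r^2 cap 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genodata import GenotypeMatrix


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.05
    miss_max: float = 0.10
    hwe_p_min: float = 0.001
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.miss_max <= 1:
            raise ValueError("miss_max must be in [0, 1]")
        if not 0 <= self.hwe_p_min <= 1:
            raise ValueError("hwe_p_min must be in [0, 1]")
        if self.ld_window < 1 or self.ld_step < 1:
            raise ValueError("ld_window and ld_step must be positive")
        if not 0 < self.ld_r2_max <= 1:
            raise ValueError("ld_r2_max must be in (0, 1]")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more likely than the observed one.
    Log-space throughout, so large counts stay stable.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")

    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele count
    # P(het = h | allele counts) ∝ 2^h * n! / (h! * n_hom_r! * n_hom_c!)
    # over h with the parity of n_rare, 0 <= h <= min(n_rare, 2n - n_rare)
    h_max = min(n_rare, 2 * n - n_rare)
    hs = np.arange(n_rare % 2, h_max + 1, 2)

    hom_rare = (n_rare - hs) // 2
    hom_common = n - hs - hom_rare
    lp = (
        hs * log(2.0)
        - gammaln(hs + 1.0)
        - gammaln(hom_rare + 1.0)
        - gammaln(hom_common + 1.0)
    )
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hs, n_het)]
    # tolerance guards against ties broken by rounding
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def snp_metrics(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP MAF, missingness fraction and HWE p-value (raw dosages)."""
    if g.standardized:
        raise ValueError("QC metrics need raw dosages, not standardized values")
    d = g.dosages
    miss = np.isnan(d)
    f_miss = miss.mean(axis=0)
    rows = []
    for j, snp in enumerate(g.snps):
        col = d[~miss[:, j], j]
        if col.size == 0:
            rows.append((snp.snp_id, np.nan, 1.0, np.nan))
            continue
        freq = col.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        p_hwe = hwe_exact_test(n2, n1, n0)
        rows.append((snp.snp_id, maf, f_miss[j], p_hwe))
    return pd.DataFrame(rows, columns=["snp_id", "maf", "f_miss", "p_hwe"])


def apply_qc(
    g: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter SNPs on MAF, missingness and HWE; return survivors + verdicts.

    The verdict table lists every input SNP with its computed metrics, a
    KEEP flag and comma-joined failure reasons.  The three filters commute,
    so the result does not depend on evaluation order.
    """
    metrics = snp_metrics(g)
    reasons = []
    for r in metrics.itertuples():
        why = []
        if not (r.maf >= thresholds.maf_min):
            why.append("maf")
        if r.f_miss > thresholds.miss_max:
            why.append("missingness")
        if not (r.p_hwe >= thresholds.hwe_p_min):
            why.append("hwe")
        reasons.append(",".join(why))
    metrics["keep"] = [w == "" for w in reasons]
    metrics["reasons"] = reasons
    kept_ids = metrics.loc[metrics["keep"], "snp_id"].tolist()
    return g.subset_snps(kept_ids), metrics


def write_verdicts(metrics: pd.DataFrame, path) -> None:
    out = metrics.rename(
        columns={"snp_id": "SNP", "maf": "MAF", "f_miss": "F_MISS",
                 "p_hwe": "P_HWE", "keep": "KEEP", "reasons": "REASONS"}
    )
    out.to_csv(path, sep="\t", index=False)


def _pairwise_r2(x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlations between columns of a complete matrix."""
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = np.inf  # constant columns correlate with nothing
    r = (xc / sd).T @ (xc / sd) / x.shape[0]
    return r**2


def ld_prune(
    g: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> list[str]:
    """Greedy sliding-window LD pruning; returns the kept SNP ids.

    Windows of ``ld_window`` SNPs slide by ``ld_step`` within each
    chromosome.  Inside a window, while any retained pair exceeds the r^2
    cap the pair member with lower MAF (ties: later position) is removed.
    r^2 is computed on mean-imputed, centered dosages; the window is a SNP
    count, not a physical distance.
    """
    if g.standardized:
        raise ValueError("LD pruning needs raw dosages")
    order = sorted(range(g.n_snps), key=lambda i: (g.snps[i].chrom, g.snps[i].pos_bp))
    if order != list(range(g.n_snps)):
        raise ValueError("SNPs must be ordered by (chrom, pos) before LD pruning")

    d = g.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(d))
    if nan_r.size:
        d[nan_r, nan_c] = col_mean[nan_c]
    freq = d.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)

    removed = np.zeros(g.n_snps, dtype=bool)
    chroms = np.array([s.chrom for s in g.snps])
    w, step, cap = thresholds.ld_window, thresholds.ld_step, thresholds.ld_r2_max
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        starts = range(0, max(1, len(idx) - w + 1), step) if len(idx) else []
        for start in starts:
            win = idx[start:start + w]
            while True:
                alive = win[~removed[win]]
                if alive.size < 2:
                    break
                r2 = _pairwise_r2(d[:, alive])
                np.fill_diagonal(r2, 0.0)
                worst = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[worst] <= cap:
                    break
                a, b = alive[worst[0]], alive[worst[1]]
                # drop the lower-MAF member; ties broken toward later position
                if maf[a] < maf[b] or (
                    maf[a] == maf[b] and g.snps[a].pos_bp > g.snps[b].pos_bp
                ):
                    removed[a] = True
                else:
                    removed[b] = True
    return [g.snps[i].snp_id for i in range(g.n_snps) if not removed[i]]
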