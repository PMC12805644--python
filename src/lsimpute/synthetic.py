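"""Two-ancestry synthetic cohorts for exercising trait imputation.

The generator emulates the study design the imputation methods target: a
large auxiliary-ancestry GWAS and a much smaller target-ancestry GWAS,
with allele-frequency divergence between the two populations following
the Balding-Nichols model (parameterized by Fst) and per-SNP causal
effects correlated across ancestries (rho_effects).  Traits are
quantitative (Y = X_std beta + e at heritability h2) or binary via a
liability threshold at the configured prevalence.  SNPs are independent
given their frequencies by default; an optional autoregressive mode adds
local LD purely so pruning code has something to prune.

GWAS summary statistics are genuine marginal regressions on simulated
individual-level panels, computed in SNP blocks with a two-pass scheme
(identical per-block RNG substreams regenerate the genotypes) so the
auxiliary panel never has to be held in memory as floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genodata import (
    GenotypeMatrix,
    PhenotypeVector,
    SnpRecord,
    SummaryStats,
    write_phenotype,
    write_plink,
    write_sumstats,
)

_BLOCK = 512  # SNPs per generation block


@dataclass(frozen=True)
class SimConfig:
    """Synthetic two-ancestry study parameters.

    Defaults reflect the asymmetry the methods are designed for: a 50k
    auxiliary GWAS against a 1k target GWAS, mild divergence (Fst 0.01),
    mostly-shared architecture (rho 0.8) and a moderately polygenic trait
    (500 causal SNPs of 5000, h2 = 0.5).
    """

    p: int = 5000
    n_aux_gwas: int = 50_000
    n_tgt_gwas: int = 1_000
    n_val: int = 500
    n_test: int = 500
    fst: float = 0.01
    rho_effects: float = 0.8
    h2: float = 0.5
    n_causal: int = 500
    prevalence: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 0.5:
            raise ValueError("fst must be in [0, 0.5)")
        if not -1 <= self.rho_effects <= 1:
            raise ValueError("rho_effects must be in [-1, 1]")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if not 1 <= self.n_causal <= self.p:
            raise ValueError("n_causal must be in [1, p]")
        if self.prevalence is not None and not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


@dataclass
class SimulatedStudy:
    """Everything simulate_cohorts produces, ready for the imputation stack."""

    config: SimConfig
    snps: list[SnpRecord]
    aux_stats: SummaryStats
    tgt_stats: SummaryStats
    val_genotypes: GenotypeMatrix
    val_phenotype: PhenotypeVector
    test_genotypes: GenotypeMatrix
    test_phenotype: PhenotypeVector
    beta_aux_true: np.ndarray
    beta_tgt_true: np.ndarray
    val_genetic_value: np.ndarray = field(default=None)
    test_genetic_value: np.ndarray = field(default=None)


def simulate_freqs(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Balding-Nichols allele frequencies for two populations.

    Ancestral q ~ U(0.05, 0.95); each population's frequency is
    Beta(q(1-F)/F, (1-q)(1-F)/F) with F = fst, so E[f] = q and the
    between-population variance is F q(1-q).  fst = 0 returns q for both.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    q = rng.uniform(0.05, 0.95, cfg.p)
    if cfg.fst == 0:
        return q, q.copy(), q.copy()
    c = (1 - cfg.fst) / cfg.fst
    f1 = rng.beta(q * c, (1 - q) * c)
    f2 = rng.beta(q * c, (1 - q) * c)
    eps = 1e-6  # keep frequencies off the boundary
    return q, np.clip(f1, eps, 1 - eps), np.clip(f2, eps, 1 - eps)


def _genotype_block(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    """n x len(freqs) int8 dosages ~ Binomial(2, f) via one uniform draw."""
    f = freqs.astype(np.float32)
    u = rng.random((n, f.size), dtype=np.float32)
    return ((u < f * f).view(np.int8) + (u < f * (2 - f)).view(np.int8))


def _genotypes(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    out = np.empty((n, freqs.size), dtype=np.int8)
    for j in range(0, freqs.size, _BLOCK):
        out[:, j:j + _BLOCK] = _genotype_block(rng, n, freqs[j:j + _BLOCK])
    return out


def _panel_sumstats(
    seed_seq: np.random.SeedSequence,
    n: int,
    freqs: np.ndarray,
    beta_true: np.ndarray,
    h2: float,
    prevalence: float | None,
) -> pd.DataFrame:
    """Marginal GWAS of a simulated panel, without materializing it.

    Pass 1 regenerates each SNP block from its own RNG substream, records
    column moments and accumulates the standardized genetic value; the
    phenotype is then drawn; pass 2 regenerates the identical blocks and
    collects X'y.  The returned (beta, se, t, p) per SNP equal a simple
    linear regression of the trait on each sample-standardized dosage
    column, exactly as marginal_gwas computes on small data.
    """
    p = freqs.size
    n_blocks = (p + _BLOCK - 1) // _BLOCK
    children = seed_seq.spawn(n_blocks + 1)
    block_seeds, noise_seed = children[:n_blocks], children[n_blocks]

    mean = np.empty(p)
    sd = np.empty(p)
    gval = np.zeros(n)
    for k, j in enumerate(range(0, p, _BLOCK)):
        g = _genotype_block(np.random.default_rng(block_seeds[k]), n, freqs[j:j + _BLOCK])
        # column moments from genotype-class counts (dosage^2 = dosage + 2*[dosage==2])
        cnt1 = (g == 1).sum(axis=0)
        cnt2 = (g == 2).sum(axis=0)
        total = cnt1 + 2.0 * cnt2
        sumsq = cnt1 + 4.0 * cnt2
        m = total / n
        var = np.maximum(sumsq - n * m**2, 0.0) / (n - 1)
        s = np.sqrt(var)
        s[s == 0] = np.inf  # monomorphic column contributes nothing
        mean[j:j + _BLOCK] = m
        sd[j:j + _BLOCK] = s
        w = beta_true[j:j + _BLOCK] / s
        gval += g.astype(np.float32) @ w.astype(np.float32) - float(m @ w)

    noise_rng = np.random.default_rng(noise_seed)
    e = noise_rng.standard_normal(n) * np.sqrt(1 - h2)
    liability = gval + e
    if prevalence is None:
        y = liability
    else:
        y = (liability > sps.norm.ppf(1 - prevalence)).astype(np.float64)

    ybar = y.mean()
    syy = float(((y - ybar) ** 2).sum())
    xty = np.empty(p)
    y32 = y.astype(np.float32)
    for k, j in enumerate(range(0, p, _BLOCK)):
        g = _genotype_block(np.random.default_rng(block_seeds[k]), n, freqs[j:j + _BLOCK])
        xty[j:j + _BLOCK] = y32 @ g.astype(np.float32)

    sxy = xty - n * mean * ybar
    sxx = (n - 1) * sd**2
    with np.errstate(invalid="ignore"):
        beta_raw = sxy / sxx
    rss = np.maximum(syy - beta_raw * sxy, 0.0)
    se_raw = np.sqrt(rss / (n - 2) / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_raw / se_raw
    pvals = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    # report on the standardized-genotype scale
    return pd.DataFrame({
        "beta_lm": np.where(np.isfinite(beta_raw), beta_raw * sd, 0.0),
        "se": np.where(np.isfinite(se_raw), se_raw * sd, np.inf),
        "p_value": np.where(np.isfinite(pvals), pvals, 1.0),
    })


def _make_snps(p: int) -> list[SnpRecord]:
    return [
        SnpRecord(f"snp{j:06d}", "1", 1 + 1000 * j, "A", "G") for j in range(p)
    ]


def _stats_for(
    snps: list[SnpRecord], tab: pd.DataFrame, label: str, n_gwas: int
) -> SummaryStats:
    full = pd.DataFrame({
        "snp_id": [s.snp_id for s in snps],
        "chrom": [s.chrom for s in snps],
        "pos_bp": [s.pos_bp for s in snps],
        "effect_allele": [s.effect_allele for s in snps],
        "other_allele": [s.other_allele for s in snps],
        "beta_lm": tab["beta_lm"].to_numpy(),
        "se": tab["se"].to_numpy(),
        "p_value": tab["p_value"].to_numpy(),
        "n_gwas": n_gwas,
    })
    return SummaryStats(table=full, ancestry_label=label, harmonized=True)


def _cohort(
    rng: np.random.Generator,
    n: int,
    freqs: np.ndarray,
    beta_true: np.ndarray,
    h2: float,
    prevalence: float | None,
    snps: list[SnpRecord],
    prefix: str,
) -> tuple[GenotypeMatrix, PhenotypeVector, np.ndarray]:
    g = _genotypes(rng, n, freqs).astype(np.float64)
    mean = g.mean(axis=0)
    sd = g.std(axis=0, ddof=1)
    sd0 = sd.copy()
    sd0[sd0 == 0] = np.inf
    gval = (g - mean) / sd0 @ beta_true
    e = rng.standard_normal(n) * np.sqrt(1 - h2)
    liability = gval + e
    if prevalence is None:
        y = liability
    else:
        y = (liability > sps.norm.ppf(1 - prevalence)).astype(np.float64)
    ids = [f"{prefix}:{i:06d}" for i in range(n)]
    gm = GenotypeMatrix(dosages=g, snps=list(snps), sample_ids=ids)
    pv = PhenotypeVector(sample_ids=ids, values=y, trait_name="SIM")
    return gm, pv, gval


def simulate_cohorts(cfg: SimConfig) -> SimulatedStudy:
    """Simulate the full two-ancestry study.

    Returns auxiliary and target summary statistics (marginal GWAS on
    internally simulated panels of n_aux_gwas and n_tgt_gwas individuals),
    raw validation and test genotype/phenotype splits from the target
    population, and the true per-ancestry effect vectors.  All randomness
    descends from cfg.seed, so output is bit-reproducible.
    """
    root = np.random.SeedSequence(cfg.seed)
    s_freq, s_eff, s_aux, s_tgt, s_val, s_test = root.spawn(6)

    _, f_aux, f_tgt = simulate_freqs(cfg, np.random.default_rng(s_freq))
    snps = _make_snps(cfg.p)

    eff_rng = np.random.default_rng(s_eff)
    causal = np.sort(eff_rng.choice(cfg.p, size=cfg.n_causal, replace=False))
    scale = np.sqrt(cfg.h2 / cfg.n_causal)
    b_shared = eff_rng.standard_normal(cfg.n_causal) * scale
    b_indep = eff_rng.standard_normal(cfg.n_causal) * scale
    rho = cfg.rho_effects
    beta_aux = np.zeros(cfg.p)
    beta_tgt = np.zeros(cfg.p)
    beta_aux[causal] = b_shared
    beta_tgt[causal] = rho * b_shared + np.sqrt(1 - rho**2) * b_indep

    aux_tab = _panel_sumstats(s_aux, cfg.n_aux_gwas, f_aux, beta_aux, cfg.h2, cfg.prevalence)
    tgt_tab = _panel_sumstats(s_tgt, cfg.n_tgt_gwas, f_tgt, beta_tgt, cfg.h2, cfg.prevalence)

    val_g, val_y, val_gv = _cohort(
        np.random.default_rng(s_val), cfg.n_val, f_tgt, beta_tgt,
        cfg.h2, cfg.prevalence, snps, "val",
    )
    test_g, test_y, test_gv = _cohort(
        np.random.default_rng(s_test), cfg.n_test, f_tgt, beta_tgt,
        cfg.h2, cfg.prevalence, snps, "test",
    )
    return SimulatedStudy(
        config=cfg,
        snps=snps,
        aux_stats=_stats_for(snps, aux_tab, "aux", cfg.n_aux_gwas),
        tgt_stats=_stats_for(snps, tgt_tab, "target", cfg.n_tgt_gwas),
        val_genotypes=val_g,
        val_phenotype=val_y,
        test_genotypes=test_g,
        test_phenotype=test_y,
        beta_aux_true=beta_aux,
        beta_tgt_true=beta_tgt,
        val_genetic_value=val_gv,
        test_genetic_value=test_gv,
    )


def simulate_ld_genotypes(
    n: int, p: int, freqs: np.ndarray, ar_rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Dosages with local LD from an AR(1) Gaussian copula over SNPs.

    Each of the two haplotypes per individual carries the alternate allele
    where an AR(1) latent normal falls below the frequency quantile;
    adjacent SNPs then correlate at roughly ar_rho^2 on the dosage scale.
    Exists to give LD pruning realistic input; not used by default.
    """
    if not 0 <= ar_rho < 1:
        raise ValueError("ar_rho must be in [0, 1)")
    thresh = sps.norm.ppf(freqs)
    dos = np.zeros((n, p), dtype=np.int8)
    for _ in range(2):
        z = np.empty((n, p))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, p - 1)) * np.sqrt(1 - ar_rho**2)
        for j in range(1, p):
            z[:, j] = ar_rho * z[:, j - 1] + innov[:, j - 1]
        dos += (z < thresh).astype(np.int8)
    return dos


def write_fixture(out_dir, study: SimulatedStudy) -> dict:
    """Write the study as PLINK triplets + TSVs; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, gm, pv in (
        ("val", study.val_genotypes, study.val_phenotype),
        ("test", study.test_genotypes, study.test_phenotype),
    ):
        bed, bim, fam = write_plink(gm, out / name)
        write_phenotype(pv, out / f"{name}.pheno.tsv")
        paths[name] = {
            "bed": str(bed), "bim": str(bim), "fam": str(fam),
            "pheno": str(out / f"{name}.pheno.tsv"),
        }
    for name, stats in (("aux", study.aux_stats), ("target", study.tgt_stats)):
        path = out / f"{name}.sumstats.tsv"
        write_sumstats(stats, path)
        paths[name] = str(path)
    return paths
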