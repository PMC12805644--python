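"""Genotype, phenotype and summary-statistic containers and I/O.

Genotypes live in PLINK 1 binary triplets (.bed/.bim/.fam); dosages are
counts of the effect allele in {0, 1, 2} with missing entries represented
as NaN.  Summary statistics are per-SNP marginal effect sizes on the
standardized-genotype scale, optionally with SE / p-value / GWAS sample
size, and are harmonized to the genotype data's reference alleles before
any imputation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

_PLINK_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = bytes([0x01])

#: strand complement; used when summary stats were reported on the other strand
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele pairs that cannot be disambiguated from strand flips
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class IntegrityError(ValueError):
    """Mutually inconsistent inputs (shape/sample/SNP mismatches)."""


class AlignmentError(ValueError):
    """Sample or SNP panels that should match do not."""


@dataclass(frozen=True)
class SnpRecord:
    """Identity and allele coding of one biallelic SNP.

    ``effect_allele`` is the counted allele (PLINK bim allele-1); all effect
    sizes in this package are per copy of this allele on the standardized
    genotype scale.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")


@dataclass
class GenotypeMatrix:
    """An n2 x p dosage matrix with per-SNP metadata.

    ``dosages`` holds counts of each SNP's effect allele; missing genotypes
    are NaN.  After :func:`standardize`, columns have mean 0 and sample
    variance 1 (ddof=1) and contain no missing values.
    """

    dosages: np.ndarray
    snps: list[SnpRecord]
    sample_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise IntegrityError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape[1] != len(self.snps):
            raise IntegrityError(
                f"{self.dosages.shape[1]} dosage columns vs {len(self.snps)} SNP records"
            )
        if self.dosages.shape[0] != len(self.sample_ids):
            raise IntegrityError(
                f"{self.dosages.shape[0]} dosage rows vs {len(self.sample_ids)} sample ids"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IntegrityError("duplicate sample ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate snp ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset in the given order (SNPs must all be present)."""
        index = {s.snp_id: i for i, s in enumerate(self.snps)}
        try:
            cols = [index[s] for s in snp_ids]
        except KeyError as e:
            raise AlignmentError(f"SNP {e.args[0]} not in genotype matrix") from e
        return GenotypeMatrix(
            dosages=self.dosages[:, cols],
            snps=[self.snps[i] for i in cols],
            sample_ids=list(self.sample_ids),
            standardized=self.standardized,
        )

    def subset_samples(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        return GenotypeMatrix(
            dosages=self.dosages[rows, :],
            snps=list(self.snps),
            sample_ids=[self.sample_ids[i] for i in rows],
            standardized=self.standardized,
        )


@dataclass
class PhenotypeVector:
    """Trait values aligned to an ordered set of samples."""

    sample_ids: list[str]
    values: np.ndarray
    trait_name: str = "PHENO"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise IntegrityError("phenotype length does not match sample ids")

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())


@dataclass
class SummaryStats:
    """Per-SNP marginal effects for one ancestry's GWAS.

    ``table`` columns: snp_id, effect_allele, other_allele, beta_lm and
    optionally chrom, pos_bp, se, p_value, n_gwas.  ``beta_lm`` is on the
    linear-model, standardized-genotype scale; logistic GWAS output must be
    converted (see :func:`lsimpute.gwas_stats.glm_to_lm`) before use.
    """

    table: pd.DataFrame
    ancestry_label: str = ""
    n_cases: int | None = None
    n_controls: int | None = None
    harmonized: bool = False

    def __post_init__(self) -> None:
        required = {"snp_id", "effect_allele", "other_allele", "beta_lm"}
        missing = required - set(self.table.columns)
        if missing:
            raise IntegrityError(f"summary table missing columns: {sorted(missing)}")
        if not np.isfinite(self.table["beta_lm"].to_numpy(dtype=float)).all():
            raise IntegrityError("non-finite beta_lm in summary table")
        if "p_value" in self.table.columns:
            p = self.table["p_value"].to_numpy(dtype=float)
            ok = np.isnan(p) | ((p >= 0) & (p <= 1))
            if not ok.all():
                raise IntegrityError("p_value outside [0, 1]")
        self.table = self.table.reset_index(drop=True)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta_lm"].to_numpy(dtype=np.float64)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# PLINK 1 binary I/O
# ---------------------------------------------------------------------------

# 2-bit genotype codes in .bed (SNP-major): 00 hom allele-1, 01 missing,
# 10 het, 11 hom allele-2.  Dosage counts allele-1 (the effect allele).
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK 1 triplet into a :class:`GenotypeMatrix`.

    ``bim_path``/``fam_path`` default to the .bed path with the extension
    swapped.  Dosages count the bim allele-1 (effect allele); missing
    genotype codes become NaN.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if raw[:2] != _PLINK_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _SNP_MAJOR:
        raise FormatError(f"{bed_path}: only SNP-major mode is supported")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * p:
        raise IntegrityError(
            f"{bed_path}: payload {payload.size} bytes, expected {bytes_per_snp * p} "
            f"for {n} samples x {p} SNPs"
        )
    blocks = payload.reshape(p, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # n x p

    snps = [
        SnpRecord(r.snp_id, r.chrom, int(r.pos_bp), r.a1, r.a2)
        for r in bim.itertuples()
    ]
    sample_ids = [f"{r.fid}:{r.iid}" for r in fam.itertuples()]
    return GenotypeMatrix(dosages=dosages, snps=snps, sample_ids=sample_ids)


def write_plink(g: GenotypeMatrix, prefix) -> tuple[Path, Path, Path]:
    """Write a raw (unstandardized) :class:`GenotypeMatrix` as .bed/.bim/.fam."""
    if g.standardized:
        raise ValueError("cannot write standardized dosages to PLINK format")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    n, p = g.dosages.shape
    d = g.dosages
    codes = np.full((p, n), 0b01, dtype=np.uint8)  # missing by default
    dt = d.T
    codes[dt == 2] = 0b00
    codes[dt == 1] = 0b10
    codes[dt == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((p, pad), dtype=np.uint8)], axis=1
        )
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    bed_path.write_bytes(_PLINK_MAGIC + _SNP_MAJOR + packed.tobytes())

    with open(bim_path, "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\t{s.effect_allele}\t{s.other_allele}\n")
    with open(fam_path, "w") as fh:
        for sid in g.sample_ids:
            fid, _, iid = sid.partition(":")
            iid = iid or fid
            fh.write(f"{fid}\t{iid}\t0\t0\t0\t-9\n")
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# Phenotype / summary-stat TSV dialects
# ---------------------------------------------------------------------------

def read_phenotype(path, trait_name: str = "PHENO") -> PhenotypeVector:
    """Read a FID/IID/PHENO TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    return PhenotypeVector(
        sample_ids=[f"{f}:{i}" for f, i in zip(df["FID"], df["IID"])],
        values=df["PHENO"].to_numpy(dtype=float),
        trait_name=trait_name,
    )


def write_phenotype(y: PhenotypeVector, path) -> None:
    rows = []
    for sid, v in zip(y.sample_ids, y.values):
        fid, _, iid = sid.partition(":")
        rows.append((fid, iid or fid, v))
    pd.DataFrame(rows, columns=["FID", "IID", "PHENO"]).to_csv(path, sep="\t", index=False)


_SUMSTAT_COLS = {
    "SNP": "snp_id", "CHR": "chrom", "BP": "pos_bp", "A1": "effect_allele",
    "A2": "other_allele", "BETA": "beta_lm", "SE": "se", "P": "p_value",
    "N": "n_gwas",
}


def read_sumstats(path, ancestry_label: str = "") -> SummaryStats:
    """Read a summary-statistic TSV (SNP/CHR/BP/A1/A2/BETA[/SE/P/N])."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    df = df.rename(columns=_SUMSTAT_COLS)
    harmonized = False
    if "ALIGNED" in df.columns:
        harmonized = bool(df["ALIGNED"].all())
        df = df.drop(columns=["ALIGNED"])
    return SummaryStats(table=df, ancestry_label=ancestry_label, harmonized=harmonized)


def write_sumstats(stats: SummaryStats, path) -> None:
    inv = {v: k for k, v in _SUMSTAT_COLS.items()}
    df = stats.table.rename(columns=inv)
    if stats.harmonized:
        df = df.assign(ALIGNED=1)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Standardization and harmonization
# ---------------------------------------------------------------------------

def standardize(g: GenotypeMatrix) -> GenotypeMatrix:
    """Column-standardize dosages: mean 0, sample variance 1 (ddof=1).

    Missing entries are mean-imputed per SNP first, so the output matrix is
    complete.  Constant columns carry no information and are dropped (with a
    warning naming how many).
    """
    if g.standardized:
        raise ValueError("genotype matrix already standardized")
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples to standardize")
    x = g.dosages.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(x))
    if nan_rows.size:
        x[nan_rows, nan_cols] = col_mean[nan_cols]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} constant SNP column(s)", stacklevel=2)
    x = (x[:, keep] - mean[keep]) / sd[keep]
    return GenotypeMatrix(
        dosages=x,
        snps=[s for s, k in zip(g.snps, keep) if k],
        sample_ids=list(g.sample_ids),
        standardized=True,
    )


def harmonize(stats: SummaryStats, snps: Sequence[SnpRecord]) -> SummaryStats:
    """Align summary statistics to the genotype data's reference alleles.

    For each SNP present in both inputs the effect size is kept as is when
    the allele pair matches, sign-flipped when effect/other are swapped, and
    resolved through strand complementation when that is unambiguous.
    Strand-ambiguous (A/T, C/G) and irreconcilable SNPs are dropped; output
    rows follow the order of ``snps``.
    """
    geno_by_id = {s.snp_id: s for s in snps}
    tab = stats.table
    rows_by_id = {r.snp_id: r for r in tab.itertuples()}

    out_rows = []
    n_ambiguous = n_mismatch = 0
    for s in snps:
        r = rows_by_id.get(s.snp_id)
        if r is None:
            continue
        ea, oa = r.effect_allele, r.other_allele
        if frozenset((ea, oa)) in _AMBIGUOUS:
            n_ambiguous += 1
            continue
        flip = None
        if (ea, oa) == (s.effect_allele, s.other_allele):
            flip = 1.0
        elif (ea, oa) == (s.other_allele, s.effect_allele):
            flip = -1.0
        else:
            cea = _COMPLEMENT.get(ea)
            coa = _COMPLEMENT.get(oa)
            if (cea, coa) == (s.effect_allele, s.other_allele):
                flip = 1.0
            elif (cea, coa) == (s.other_allele, s.effect_allele):
                flip = -1.0
        if flip is None:
            n_mismatch += 1
            continue
        d = r._asdict()
        d.pop("Index", None)
        d["effect_allele"] = s.effect_allele
        d["other_allele"] = s.other_allele
        d["beta_lm"] = flip * d["beta_lm"]
        out_rows.append(d)

    if n_ambiguous or n_mismatch:
        logger.info(
            "harmonize: dropped %d strand-ambiguous and %d irreconcilable SNPs",
            n_ambiguous, n_mismatch,
        )
    if not out_rows:
        raise AlignmentError("no SNPs shared between summary stats and genotypes")
    out = pd.DataFrame(out_rows)
    return replace(stats, table=out, harmonized=True)


def align_to_panel(stats: SummaryStats, g: GenotypeMatrix) -> np.ndarray:
    """Return the beta vector of ``stats`` ordered exactly as ``g``'s SNPs.

    Requires harmonized stats covering every SNP in ``g``.
    """
    if not stats.harmonized:
        raise AlignmentError("summary stats must be harmonized first")
    by_id = dict(zip(stats.table["snp_id"], stats.beta))
    try:
        return np.array([by_id[s] for s in g.snp_ids], dtype=np.float64)
    except KeyError as e:
        raise AlignmentError(f"SNP {e.args[0]} missing from summary stats") from e
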