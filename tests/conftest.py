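import numpy as np
import pytest

from lsimpute.genodata import GenotypeMatrix, PhenotypeVector, SnpRecord, standardize


def make_snps(p, chrom="1", alleles=("A", "G")):
    return [
        SnpRecord(f"rs{j}", chrom, 1 + 100 * j, alleles[0], alleles[1])
        for j in range(p)
    ]


def random_genotypes(n, p, seed=0, freqs=None, missing_rate=0.0):
    """Raw dosage GenotypeMatrix with Binomial(2, f) entries."""
    rng = np.random.default_rng(seed)
    f = freqs if freqs is not None else rng.uniform(0.1, 0.9, p)
    d = rng.binomial(2, f, size=(n, p)).astype(float)
    if missing_rate:
        mask = rng.random((n, p)) < missing_rate
        d[mask] = np.nan
    return GenotypeMatrix(
        dosages=d, snps=make_snps(p), sample_ids=[f"s:{i}" for i in range(n)]
    )


def std_genotypes(n, p, seed=0):
    return standardize(random_genotypes(n, p, seed))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
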