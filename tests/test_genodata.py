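"""Genotype container, PLINK round-trips, standardization, harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lsimpute.genodata import (
    AlignmentError,
    FormatError,
    GenotypeMatrix,
    PhenotypeVector,
    SnpRecord,
    SummaryStats,
    harmonize,
    read_phenotype,
    read_plink,
    standardize,
    write_phenotype,
    write_plink,
)
from conftest import make_snps, random_genotypes


class TestPlinkRoundTrip:
    def test_known_matrix_round_trips(self, tmp_path):
        d = np.array([[0, 1, 2], [2, 0, 1], [1, 1, 0], [2, 2, 2]], dtype=float)
        g = GenotypeMatrix(d, make_snps(3), [f"f{i}:i{i}" for i in range(4)])
        write_plink(g, tmp_path / "fix")
        back = read_plink(tmp_path / "fix.bed")
        np.testing.assert_array_equal(back.dosages, d)
        assert back.sample_ids == g.sample_ids
        assert [s.snp_id for s in back.snps] == [s.snp_id for s in g.snps]
        assert [(s.effect_allele, s.other_allele) for s in back.snps] == [
            ("A", "G")
        ] * 3

    def test_missing_genotype_survives_round_trip(self, tmp_path):
        d = np.array([[0.0, 1], [np.nan, 2], [2, 0]])
        g = GenotypeMatrix(d, make_snps(2), ["a:1", "a:2", "a:3"])
        write_plink(g, tmp_path / "m")
        back = read_plink(tmp_path / "m.bed")
        assert np.isnan(back.dosages[1, 0])
        np.testing.assert_array_equal(
            back.dosages[~np.isnan(d)], d[~np.isnan(d)]
        )

    @pytest.mark.parametrize("n,p,miss", [(1, 1, 0), (5, 7, 0.2), (8, 3, 0.5)])
    def test_random_round_trips(self, tmp_path, n, p, miss):
        g = random_genotypes(n, p, seed=n * 31 + p, missing_rate=miss)
        write_plink(g, tmp_path / "r")
        back = read_plink(tmp_path / "r.bed")
        np.testing.assert_array_equal(
            np.isnan(back.dosages), np.isnan(g.dosages)
        )
        ok = ~np.isnan(g.dosages)
        np.testing.assert_array_equal(back.dosages[ok], g.dosages[ok])

    def test_bad_magic_bytes_rejected(self, tmp_path):
        g = random_genotypes(3, 2)
        bed, _, _ = write_plink(g, tmp_path / "b")
        raw = bytearray(bed.read_bytes())
        raw[0] ^= 0xFF
        bed.write_bytes(bytes(raw))
        with pytest.raises(FormatError, match="magic"):
            read_plink(bed)

    def test_truncated_payload_rejected(self, tmp_path):
        g = random_genotypes(9, 4)
        bed, _, _ = write_plink(g, tmp_path / "t")
        bed.write_bytes(bed.read_bytes()[:-1])
        with pytest.raises(Exception, match="payload"):
            read_plink(bed)


class TestPhenotypeIO:
    def test_round_trip(self, tmp_path):
        y = PhenotypeVector(["a:1", "b:2"], [0.5, -1.25], "hdl")
        write_phenotype(y, tmp_path / "y.tsv")
        back = read_phenotype(tmp_path / "y.tsv", "hdl")
        assert back.sample_ids == y.sample_ids
        np.testing.assert_allclose(back.values, y.values)

    def test_binary_detection(self):
        assert PhenotypeVector(["x:1", "x:2"], [0, 1]).is_binary
        assert not PhenotypeVector(["x:1", "x:2"], [0.0, 0.3]).is_binary


class TestStandardize:
    def test_simple_column_moments(self):
        g = GenotypeMatrix(
            np.array([[0.0], [2], [0], [2]]), make_snps(1), ["a:1", "a:2", "a:3", "a:4"]
        )
        s = standardize(g)
        assert abs(s.dosages[:, 0].mean()) < 1e-12
        assert abs(s.dosages[:, 0].var(ddof=1) - 1) < 1e-12

    def test_constant_column_dropped_with_warning(self):
        d = np.array([[1.0, 0], [1, 1], [1, 2], [1, 1]])
        g = GenotypeMatrix(d, make_snps(2), [f"a:{i}" for i in range(4)])
        with pytest.warns(UserWarning, match="constant"):
            s = standardize(g)
        assert s.n_snps == 1
        assert s.snp_ids == ["rs1"]

    def test_random_matrix_moment_invariants(self):
        g = random_genotypes(50, 30, seed=7, missing_rate=0.1)
        s = standardize(g)
        assert s.standardized
        assert not np.isnan(s.dosages).any()
        np.testing.assert_allclose(s.dosages.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(s.dosages.var(axis=0, ddof=1), 1, atol=1e-10)

    def test_mean_imputation_before_scaling(self):
        # missing entry replaced by the column mean of observed values
        d = np.array([[0.0], [2.0], [np.nan], [1.0]])
        g = GenotypeMatrix(d, make_snps(1), [f"a:{i}" for i in range(4)])
        s = standardize(g)
        filled = np.array([0, 2, 1.0, 1.0])
        expect = (filled - filled.mean()) / filled.std(ddof=1)
        np.testing.assert_allclose(s.dosages[:, 0], expect)

    def test_rejects_repeat_and_tiny(self):
        g = random_genotypes(4, 2)
        s = standardize(g)
        with pytest.raises(ValueError, match="already"):
            standardize(s)
        with pytest.raises(ValueError, match="2 samples"):
            standardize(random_genotypes(1, 2))


def _stats(rows):
    return SummaryStats(
        table=pd.DataFrame(
            rows, columns=["snp_id", "effect_allele", "other_allele", "beta_lm"]
        )
    )


class TestHarmonize:
    snps = [
        SnpRecord("rs0", "1", 100, "A", "G"),
        SnpRecord("rs1", "1", 200, "C", "T"),
        SnpRecord("rs2", "1", 300, "A", "C"),
    ]

    def test_exact_match_kept(self):
        out = harmonize(_stats([("rs0", "A", "G", 0.3)]), self.snps)
        assert out.beta.tolist() == [0.3]
        assert out.harmonized

    def test_swapped_alleles_flip_sign(self):
        out = harmonize(_stats([("rs0", "G", "A", 0.3)]), self.snps)
        assert out.beta.tolist() == [-0.3]

    def test_strand_complement_resolved(self):
        # genotype rs1 is C/T; stats report G/A = complement strand, swapped-free
        out = harmonize(_stats([("rs1", "G", "A", 0.4)]), self.snps)
        assert out.beta.tolist() == [0.4]
        out = harmonize(_stats([("rs1", "A", "G", 0.4)]), self.snps)
        assert out.beta.tolist() == [-0.4]

    def test_ambiguous_and_unmatched_dropped(self):
        stats = _stats([
            ("rs0", "A", "T", 0.3),   # strand-ambiguous pair
            ("rs1", "C", "G", 0.1),   # ambiguous pair
            ("rs2", "T", "C", 0.2),   # complement (A,G) still irreconcilable with A/C
        ])
        with pytest.raises(AlignmentError):
            harmonize(stats, self.snps)

    def test_output_ordered_by_genotype_panel(self):
        stats = _stats([
            ("rs2", "A", "C", 0.2), ("rs0", "A", "G", 0.1), ("rs1", "C", "T", 0.3),
        ])
        out = harmonize(stats, self.snps)
        assert out.snp_ids == ["rs0", "rs1", "rs2"]

    def test_idempotent(self):
        stats = _stats([
            ("rs0", "G", "A", 0.3), ("rs1", "T", "C", -0.2), ("rs2", "A", "C", 0.1),
        ])
        once = harmonize(stats, self.snps)
        twice = harmonize(once, self.snps)
        np.testing.assert_array_equal(once.beta, twice.beta)
        assert once.snp_ids == twice.snp_ids

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-2, 2, allow_nan=False), min_size=3, max_size=3))
    def test_swapping_roles_negates_betas(self, betas):
        fwd = _stats([
            ("rs0", "A", "G", betas[0]),
            ("rs1", "C", "T", betas[1]),
            ("rs2", "A", "C", betas[2]),
        ])
        rev = _stats([
            ("rs0", "G", "A", betas[0]),
            ("rs1", "T", "C", betas[1]),
            ("rs2", "C", "A", betas[2]),
        ])
        a = harmonize(fwd, self.snps).beta
        b = harmonize(rev, self.snps).beta
        np.testing.assert_allclose(a, -b)


class TestSummaryStatsInvariants:
    def test_rejects_bad_p_values(self):
        tab = pd.DataFrame({
            "snp_id": ["rs0"], "effect_allele": ["A"], "other_allele": ["G"],
            "beta_lm": [0.1], "p_value": [1.5],
        })
        with pytest.raises(Exception, match="p_value"):
            SummaryStats(table=tab)

    def test_rejects_nonfinite_beta(self):
        tab = pd.DataFrame({
            "snp_id": ["rs0"], "effect_allele": ["A"], "other_allele": ["G"],
            "beta_lm": [np.inf],
        })
        with pytest.raises(Exception, match="beta"):
            SummaryStats(table=tab)
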