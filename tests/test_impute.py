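"""Core imputation algebra: pseudoinverse solve, self-recovery, blending,
transfer descent, sample batching."""

import numpy as np
import pytest

from lsimpute.genodata import GenotypeMatrix, PhenotypeVector, standardize
from lsimpute.gwas_stats import marginal_betas
from lsimpute.impute import (
    DivergenceError,
    ImputeConfig,
    combined_impute,
    gram_solve,
    ls_impute,
    ls_impute_batched,
    safe_learning_rate,
    split_batches,
    transfer_impute,
)
from conftest import random_genotypes, std_genotypes


def rel_err(a, b):
    return np.linalg.norm(a - b) / np.linalg.norm(b)


class TestGramSolve:
    def test_identity(self, rng):
        v = rng.standard_normal(6)
        lam = 1e-6
        np.testing.assert_allclose(gram_solve(np.eye(6), v, lam), v / (1 + lam))

    def test_matches_svd_pseudoinverse_on_rank_deficient(self, rng):
        x = rng.standard_normal((3, 10))
        x[2] = x[0]  # duplicate row -> rank-deficient Gram
        m = x @ x.T
        v = x @ rng.standard_normal(10)
        got = gram_solve(m, v, 1e-6)
        want = np.linalg.pinv(m) @ v
        assert np.linalg.norm(got - want) < 1e-4 * np.linalg.norm(want)

    def test_residual_small_on_random_psd(self, rng):
        a = rng.standard_normal((20, 20))
        m = a @ a.T
        v = rng.standard_normal(20)
        lam = 1e-6
        x = gram_solve(m, v, lam)
        assert np.linalg.norm((m + lam * np.eye(20)) @ x - v) < 1e-8 * np.linalg.norm(v)

    def test_asymmetric_rejected(self, rng):
        m = rng.standard_normal((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            gram_solve(m, np.zeros(4))


class TestLsImpute:
    def test_zero_beta_gives_zero(self):
        x = std_genotypes(20, 100, seed=1)
        imp = ls_impute(x, np.zeros(x.n_snps))
        np.testing.assert_allclose(imp.values, 0.0, atol=1e-12)

    def test_self_recovery(self, rng):
        """beta computed from (X, Y) itself recovers Y when p >> n.

        Marginal equations are location-free (columns of X are centered),
        so recovery is of the centered trait.
        """
        x = std_genotypes(50, 800, seed=6)
        yv = rng.standard_normal(50)
        yv -= yv.mean()
        y = PhenotypeVector(list(x.sample_ids), yv)
        beta = marginal_betas(x, y)
        imp = ls_impute(x, beta)
        assert rel_err(imp.values, y.values) < 1e-3

    def test_linear_in_beta(self, rng):
        x = std_genotypes(15, 60, seed=2)
        beta = rng.standard_normal(60)
        a = ls_impute(x, beta).values
        b = ls_impute(x, 3.5 * beta).values
        np.testing.assert_allclose(b, 3.5 * a, atol=1e-10)

    def test_warns_when_p_not_larger_than_n(self, rng):
        x = std_genotypes(30, 10, seed=3)
        with pytest.warns(UserWarning, match="more SNPs"):
            ls_impute(x, rng.standard_normal(10))

    def test_requires_standardized(self, rng):
        g = random_genotypes(10, 30)
        with pytest.raises(ValueError, match="standardized"):
            ls_impute(g, rng.standard_normal(30))


class TestCombinedImpute:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        g = random_genotypes(25, 200, seed=seed)
        x = standardize(g)
        x1 = x.subset_snps(x.snp_ids[:120])
        x2 = x.subset_snps(x.snp_ids[80:])
        b1 = rng.standard_normal(x1.n_snps) * 0.05
        b2 = rng.standard_normal(x2.n_snps) * 0.05
        return x1, b1, x2, b2

    def test_endpoints_match_single_ancestry(self):
        x1, b1, x2, b2 = self._setup(4)
        at1 = combined_impute(x1, b1, x2, b2, omega=1.0)
        at0 = combined_impute(x1, b1, x2, b2, omega=0.0)
        np.testing.assert_allclose(at1.values, ls_impute(x1, b1).values, atol=1e-10)
        np.testing.assert_allclose(at0.values, ls_impute(x2, b2).values, atol=1e-10)

    def test_identical_inputs_omega_invariant(self):
        x1, b1, _, _ = self._setup(5)
        outs = [
            combined_impute(x1, b1, x1, b1, omega=w).values
            for w in np.linspace(0, 1, 11)
        ]
        spread = max(np.max(np.abs(o - outs[0])) for o in outs)
        assert spread < 1e-8

    def test_linear_in_betas(self):
        x1, b1, x2, b2 = self._setup(6)
        base = combined_impute(x1, b1, x2, b2, omega=0.3).values
        doubled = combined_impute(x1, 2 * b1, x2, 2 * b2, omega=0.3).values
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-10)

    def test_sample_misalignment_rejected(self):
        x1, b1, x2, b2 = self._setup(7)
        x2b = x2.subset_samples(list(range(x2.n_samples))[::-1])
        with pytest.raises(Exception, match="sample"):
            combined_impute(x1, b1, x2b, b2, omega=0.5)


class TestTransferImpute:
    def _problem(self, n=40, p=400, seed=8):
        rng = np.random.default_rng(seed)
        x = std_genotypes(n, p, seed=seed)
        beta = rng.standard_normal(x.n_snps) * 0.05
        # realistic initializer: an imputation from other (auxiliary) stats,
        # which is automatically mean-zero like any ls_impute output
        init = ls_impute(x, rng.standard_normal(x.n_snps) * 0.05)
        return x, beta, init

    def test_zero_epochs_returns_init(self):
        x, beta, init = self._problem()
        cfg = ImputeConfig(max_epochs=0)
        out = transfer_impute(x, beta, init, cfg)
        np.testing.assert_array_equal(out.values, init.values)
        assert len(out.trajectory) == 1
        assert out.trajectory[0]["epoch"] == 0

    def test_full_batch_converges_to_closed_form(self):
        x, beta, init = self._problem(n=40, p=400, seed=9)
        lr = safe_learning_rate(x, margin=0.9)
        cfg = ImputeConfig(learning_rate=lr, max_epochs=600, full_batch=True)
        out = transfer_impute(x, beta, init, cfg)
        target = ls_impute(x, beta).values
        assert rel_err(out.values, target) < 1e-3

    def test_full_batch_objective_monotone(self):
        x, beta, init = self._problem(seed=10)
        lr = safe_learning_rate(x, margin=0.5)
        cfg = ImputeConfig(learning_rate=lr, max_epochs=100, full_batch=True)
        out = transfer_impute(x, beta, init, cfg)
        objs = [t["objective"] for t in out.trajectory]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_trajectory_epoch0_matches_init_objective(self):
        x, beta, init = self._problem(seed=11)
        out = transfer_impute(x, beta, init, ImputeConfig(max_epochs=3))
        n = x.n_samples
        r = beta - x.dosages.T @ init.values / (n - 1)
        assert out.trajectory[0]["objective"] == pytest.approx(float(r @ r))

    def test_minibatch_deterministic_given_seed(self):
        x, beta, init = self._problem(seed=12)
        cfg = ImputeConfig(learning_rate=1.0, max_epochs=5, sgd_batch_snps=64, seed=42)
        a = transfer_impute(x, beta, init, cfg).values
        b = transfer_impute(x, beta, init, cfg).values
        np.testing.assert_array_equal(a, b)

    def test_divergence_detected(self):
        x, beta, init = self._problem(seed=13)
        huge = 1e4 * safe_learning_rate(x, margin=1.0)
        cfg = ImputeConfig(learning_rate=huge, max_epochs=50, full_batch=True)
        with pytest.raises(DivergenceError, match="epoch"):
            transfer_impute(x, beta, init, cfg)

    def test_metric_recorded_every_epoch(self):
        x, beta, init = self._problem(seed=14)
        cfg = ImputeConfig(learning_rate=0.5, max_epochs=4)
        out = transfer_impute(x, beta, init, cfg, metric_fn=lambda y: float(y.sum()))
        assert [t["epoch"] for t in out.trajectory] == [0, 1, 2, 3, 4]
        assert all("metric" in t for t in out.trajectory)


class TestSplitBatches:
    def test_no_split_needed(self):
        g = random_genotypes(100, 5)
        parts = split_batches(g, 2000)
        assert len(parts) == 1
        assert parts[0].sample_ids == g.sample_ids

    def test_partition_arithmetic(self):
        g = random_genotypes(50, 3)
        parts = split_batches(g, 20)
        assert [p.n_samples for p in parts] == [20, 20, 10]
        flat = [sid for p in parts for sid in p.sample_ids]
        assert flat == g.sample_ids

    def test_small_batch_rejected(self):
        with pytest.raises(ValueError):
            split_batches(random_genotypes(10, 2), 1)

    def test_batched_imputation_tracks_unbatched(self, rng):
        # external summary statistics, p much larger than each batch:
        # per-sample values stay highly correlated at this fixed seed (not
        # identical: each batch recenters and solves its own Gram system,
        # which costs roughly the 1/n_batch between-batch mean share)
        g = random_genotypes(200, 12000, seed=15)
        x = standardize(g)
        beta_ext = dict(zip(x.snp_ids, rng.standard_normal(x.n_snps) * 0.05))
        beta_raw = np.array([beta_ext.get(s.snp_id, 0.0) for s in g.snps])
        full = ls_impute(x, np.array([beta_ext[s] for s in x.snp_ids])).values
        batched = ls_impute_batched(g, beta_raw, sample_batch_max=100).values
        assert np.corrcoef(full, batched)[0, 1] > 0.99  # observed: 0.9954
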