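"""Least-squares trait imputation from GWAS summary statistics.

Given standardized genotypes X (n2 samples, p SNPs, p >> n2) and marginal
effect estimates beta*, the imputed trait solves

    Yhat = argmin_Y || beta* - X'Y/(n2-1) ||^2
         = (n2-1) (XX')^+ X beta*,

with the Moore-Penrose pseudoinverse realized as a ridge-regularized
symmetric solve, (XX' + lambda I)^{-1}, lambda = 1e-6.  Two multi-ancestry
extensions are provided: an omega-weighted blend of two ancestries'
objectives with a closed form, and a transfer-learning variant that starts
from the auxiliary-ancestry solution and refines it toward the target
ancestry's summary statistics by (mini-batch) gradient descent with early
stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .genodata import AlignmentError, GenotypeMatrix

DEFAULT_RIDGE = 1e-6


class NumericalError(RuntimeError):
    pass


class DivergenceError(NumericalError):
    pass


@dataclass
class ImputeConfig:
    """Tuning knobs for the imputation methods.

    ridge_lambda  ridge term approximating the pseudoinverse (1e-6).
    omega         mixing weight for the combined method, in [0, 1].
    learning_rate transfer-method step size.
    max_epochs    transfer-method epoch budget (one epoch = one full pass
                  over the SNP equations).
    sgd_batch_snps  SNP equations per mini-batch.
    sample_batch_max  samples per batch when splitting large cohorts.
    full_batch    if True, deterministic full-gradient descent.
    """

    ridge_lambda: float = DEFAULT_RIDGE
    omega: float = 0.5
    learning_rate: float = 0.1
    max_epochs: int = 100
    sgd_batch_snps: int = 512
    sample_batch_max: int = 2000
    seed: int = 0
    full_batch: bool = False

    def __post_init__(self) -> None:
        if self.ridge_lambda <= 0:
            raise ValueError("ridge_lambda must be positive")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must be in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be non-negative")
        if self.sgd_batch_snps < 1:
            raise ValueError("sgd_batch_snps must be positive")


@dataclass
class ImputedTrait:
    """An imputed trait vector with its provenance."""

    sample_ids: list[str]
    values: np.ndarray
    method: str  # single | combined | transfer
    config: dict = field(default_factory=dict)
    snp_panel: list[str] = field(default_factory=list)
    trajectory: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("imputed trait contains non-finite values")


def _require_std(x: GenotypeMatrix, name: str = "x") -> None:
    if not x.standardized:
        raise ValueError(f"{name} must be standardized before imputation")


def _check_beta(x: GenotypeMatrix, beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape != (x.n_snps,):
        raise AlignmentError(
            f"beta has {beta.shape} entries for a {x.n_snps}-SNP panel"
        )
    return beta


def gram_solve(m: np.ndarray, v: np.ndarray, ridge_lambda: float = DEFAULT_RIDGE) -> np.ndarray:
    """Solve (m + lambda I) x = v for symmetric PSD m via Cholesky.

    This is the ridge approximation to applying the pseudoinverse of m,
    exact in the limit lambda -> 0+.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("m must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("m must be symmetric (within 1e-8)")
    if ridge_lambda <= 0:
        raise ValueError("ridge_lambda must be positive")
    a = m + ridge_lambda * np.eye(m.shape[0])
    try:
        c = cho_factor(a, lower=True)
    except np.linalg.LinAlgError as e:
        eigs = np.linalg.eigvalsh(m)
        raise NumericalError(
            f"Cholesky failed: eig range [{eigs.min():.3e}, {eigs.max():.3e}], "
            f"lambda={ridge_lambda:.1e}"
        ) from e
    return cho_solve(c, np.asarray(v, dtype=np.float64))


def ls_impute(
    x_std: GenotypeMatrix,
    beta: np.ndarray,
    ridge_lambda: float = DEFAULT_RIDGE,
) -> ImputedTrait:
    """Single-ancestry least-squares imputation.

    Yhat = (n2-1) (XX' + lambda I)^{-1} X beta.  Warns if p <= n2, where
    the system of marginal equations is under-determined in the wrong
    direction for this method.
    """
    _require_std(x_std, "x_std")
    beta = _check_beta(x_std, beta)
    n = x_std.n_samples
    x = x_std.dosages
    if x_std.n_snps <= n:
        import warnings

        warnings.warn(
            f"p={x_std.n_snps} <= n2={n}: imputation expects many more SNPs "
            "than samples", stacklevel=2,
        )
    yhat = (n - 1) * gram_solve(x @ x.T, x @ beta, ridge_lambda)
    return ImputedTrait(
        sample_ids=list(x_std.sample_ids),
        values=yhat,
        method="single",
        config={"ridge_lambda": ridge_lambda},
        snp_panel=x_std.snp_ids,
    )


def combined_impute(
    x1: GenotypeMatrix,
    beta1: np.ndarray,
    x2: GenotypeMatrix,
    beta2: np.ndarray,
    omega: float,
    ridge_lambda: float = DEFAULT_RIDGE,
) -> ImputedTrait:
    """Two-ancestry blended imputation with mixing weight omega.

    Minimizes omega ||beta1 - X1'Y/(n2-1)||^2 + (1-omega) ||beta2 -
    X2'Y/(n2-1)||^2 over Y, whose closed form is

        Yhat = (n2-1) (w G1 + (1-w) G2)^+ (w X1 b1 + (1-w) X2 b2),

    Gk = Xk Xk'.  At omega in {0, 1} this reduces exactly to the
    corresponding single-ancestry imputation.  X1 and X2 must be column
    subsets of one sample-aligned genotype source.
    """
    _require_std(x1, "x1")
    _require_std(x2, "x2")
    if x1.sample_ids != x2.sample_ids:
        raise AlignmentError("x1 and x2 must cover the same samples in order")
    if not 0 <= omega <= 1:
        raise ValueError("omega must be in [0, 1]")
    beta1 = _check_beta(x1, beta1)
    beta2 = _check_beta(x2, beta2)
    n = x1.n_samples
    a, b = x1.dosages, x2.dosages
    gram = omega * (a @ a.T) + (1 - omega) * (b @ b.T)
    rhs = omega * (a @ beta1) + (1 - omega) * (b @ beta2)
    yhat = (n - 1) * gram_solve(gram, rhs, ridge_lambda)
    return ImputedTrait(
        sample_ids=list(x1.sample_ids),
        values=yhat,
        method="combined",
        config={"omega": omega, "ridge_lambda": ridge_lambda},
        snp_panel=sorted(set(x1.snp_ids) | set(x2.snp_ids)),
    )


def _objective(x: np.ndarray, beta: np.ndarray, y: np.ndarray, n: int) -> float:
    r = beta - x.T @ y / (n - 1)
    return float(r @ r)


def transfer_impute(
    x2: GenotypeMatrix,
    beta2: np.ndarray,
    y_init: ImputedTrait,
    cfg: ImputeConfig,
    metric_fn: Callable[[np.ndarray], float] | None = None,
) -> ImputedTrait:
    """Transfer-learning imputation: refine an auxiliary-ancestry start.

    Minimizes f(Y) = ||beta2 - X2'Y/(n2-1)||^2 by (mini-batch) gradient
    descent from ``y_init`` (typically the auxiliary-ancestry imputation).
    Each epoch shuffles the SNP equations (seeded), partitions them into
    batches of ``cfg.sgd_batch_snps`` and steps

        Y <- Y + lr * (2/(n2-1)) * sum_{j in B} x_j (beta_j - x_j'Y/(n2-1)),

    so one full pass applies approximately lr * 2 XX'/(n2-1)^2 regardless
    of batch size.  The objective is convex, so running to convergence
    recovers the target-only closed form and forgets the initialization;
    early stopping (see tune_eval.select_epochs) preserves it.  The full
    objective — and ``metric_fn(Y)`` if given — is recorded every epoch,
    including epoch 0 at the initial value.
    """
    _require_std(x2, "x2")
    beta2 = _check_beta(x2, beta2)
    if y_init.sample_ids != x2.sample_ids:
        raise AlignmentError("y_init is not sample-aligned with x2")
    n = x2.n_samples
    p = x2.n_snps
    x = x2.dosages
    rng = np.random.default_rng(cfg.seed)
    y = y_init.values.copy()

    def record(epoch: int) -> dict:
        entry = {"epoch": epoch, "objective": _objective(x, beta2, y, n)}
        if metric_fn is not None:
            entry["metric"] = float(metric_fn(y))
        return entry

    trajectory = [record(0)]
    f0 = max(trajectory[0]["objective"], 1e-300)
    scale = 2.0 * cfg.learning_rate / (n - 1)
    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.full_batch:
            r = beta2 - x.T @ y / (n - 1)
            y = y + scale * (x @ r)
        else:
            order = rng.permutation(p)
            for start in range(0, p, cfg.sgd_batch_snps):
                b = order[start:start + cfg.sgd_batch_snps]
                xb = x[:, b]
                r = beta2[b] - xb.T @ y / (n - 1)
                y = y + scale * (xb @ r)
        entry = record(epoch)
        obj = entry["objective"]
        if not np.isfinite(obj) or obj > 1e6 * f0:
            raise DivergenceError(
                f"objective diverged at epoch {epoch} "
                f"({obj:.3e} vs initial {f0:.3e}); reduce the learning rate"
            )
        trajectory.append(entry)
    return ImputedTrait(
        sample_ids=list(x2.sample_ids),
        values=y,
        method="transfer",
        config={
            "learning_rate": cfg.learning_rate,
            "max_epochs": cfg.max_epochs,
            "sgd_batch_snps": cfg.sgd_batch_snps,
            "full_batch": cfg.full_batch,
            "seed": cfg.seed,
        },
        snp_panel=x2.snp_ids,
        trajectory=trajectory,
    )


def safe_learning_rate(x_std: GenotypeMatrix, margin: float = 0.5) -> float:
    """A stable step size for transfer_impute on this genotype matrix.

    Full-batch descent on the quadratic objective is stable for
    lr < (n2-1)^2 / lambda_max(XX'); returns that bound times ``margin``.
    """
    _require_std(x_std)
    n = x_std.n_samples
    x = x_std.dosages
    lam_max = float(np.linalg.eigvalsh(x @ x.T)[-1])
    return margin * (n - 1) ** 2 / lam_max


def split_batches(g: GenotypeMatrix, sample_batch_max: int = 2000) -> list[GenotypeMatrix]:
    """Contiguous, disjoint, exhaustive partition of samples into batches."""
    if sample_batch_max < 2:
        raise ValueError("sample_batch_max must be at least 2")
    n = g.n_samples
    return [
        g.subset_samples(range(i, min(i + sample_batch_max, n)))
        for i in range(0, n, sample_batch_max)
    ]


def ls_impute_batched(
    g_raw: GenotypeMatrix,
    beta: np.ndarray,
    ridge_lambda: float = DEFAULT_RIDGE,
    sample_batch_max: int = 2000,
) -> ImputedTrait:
    """Memory-bounded imputation of a large cohort in sample batches.

    Each batch is re-standardized over its own samples (the marginal-
    equation algebra holds per solved system) and imputed independently;
    results concatenate in the original sample order.
    """
    from .genodata import standardize

    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape != (g_raw.n_snps,):
        raise AlignmentError("beta does not match the SNP panel")
    parts = []
    for batch in split_batches(g_raw, sample_batch_max):
        xb = standardize(batch)
        keep = [i for i, s in enumerate(batch.snps) if s.snp_id in set(xb.snp_ids)]
        parts.append(ls_impute(xb, beta[keep], ridge_lambda))
    return ImputedTrait(
        sample_ids=[sid for p_ in parts for sid in p_.sample_ids],
        values=np.concatenate([p_.values for p_ in parts]),
        method="single",
        config={"ridge_lambda": ridge_lambda, "sample_batch_max": sample_batch_max},
        snp_panel=g_raw.snp_ids,
    )
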