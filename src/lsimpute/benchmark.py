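"""End-to-end synthetic benchmark of the four imputation strategies.

For one simulated two-ancestry study this module runs the full protocol
the methods are meant for: select SNP panels per ancestry, impute the
validation cohort, tune omega (combined) and the stopping epoch
(transfer) on it, then impute the test cohort with the selected
parameters and score against the held-out truth.  The test split never
influences tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genodata import GenotypeMatrix, SummaryStats, align_to_panel, standardize
from .gwas_stats import SnpSelectionSpec, select_snps
from .impute import DEFAULT_RIDGE, ImputeConfig, ls_impute, transfer_impute
from .synthetic import SimConfig, SimulatedStudy, simulate_cohorts
from .tune_eval import DEFAULT_OMEGA_GRID, metric_for, select_epochs, tune_omega


@dataclass(frozen=True)
class BenchmarkConfig:
    """Protocol parameters around the simulated study.

    Panels of 2000 SNPs per ancestry keep p well above the 500-sample
    cohorts, as the least-squares system requires.  The transfer step size
    of 0.1 with a 400-epoch budget puts the early-stopping peak well
    inside the budget at this problem scale (one epoch applies roughly
    lr * 2 XX' / (n2-1)^2 of the residual).
    """

    panel_size: int = 2000
    p_threshold: float = 0.05
    learning_rate: float = 0.1
    max_epochs: int = 400
    sgd_batch_snps: int = 512
    ridge_lambda: float = DEFAULT_RIDGE
    omega_grid: tuple = tuple(DEFAULT_OMEGA_GRID)


def _std_panel(
    g_raw: GenotypeMatrix, stats: SummaryStats, panel: list[str]
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Standardize the panel columns of a raw cohort and align betas."""
    x = standardize(g_raw.subset_snps(panel))
    return x, align_to_panel(stats, x)


def run_study(
    study: SimulatedStudy, bench: BenchmarkConfig = BenchmarkConfig(), seed: int = 0
) -> dict:
    """Run all four strategies on one simulated study; return the metrics.

    The returned dict carries validation-selected parameters
    (omega_selected, epoch_selected) and test-set metrics for the
    aux-only, target-only, combined and transfer imputations.
    """
    binary = study.config.prevalence is not None
    spec_aux = SnpSelectionSpec(bench.panel_size, bench.p_threshold, seed=seed * 2 + 1)
    spec_tgt = SnpSelectionSpec(bench.panel_size, bench.p_threshold, seed=seed * 2 + 2)
    panel_aux = select_snps(study.aux_stats, spec_aux)
    panel_tgt = select_snps(study.tgt_stats, spec_tgt)

    val_aux, beta_aux_v = _std_panel(study.val_genotypes, study.aux_stats, panel_aux)
    val_tgt, beta_tgt_v = _std_panel(study.val_genotypes, study.tgt_stats, panel_tgt)
    test_aux, beta_aux_t = _std_panel(study.test_genotypes, study.aux_stats, panel_aux)
    test_tgt, beta_tgt_t = _std_panel(study.test_genotypes, study.tgt_stats, panel_tgt)

    y_val = study.val_phenotype.values
    y_test = study.test_phenotype.values
    metric_name, val_metric = metric_for(y_val, binary)
    _, test_metric = metric_for(y_test, binary)

    out = {"metric": metric_name}

    # single-ancestry baselines
    single_aux = ls_impute(test_aux, beta_aux_t, bench.ridge_lambda)
    single_tgt = ls_impute(test_tgt, beta_tgt_t, bench.ridge_lambda)
    out["test_single_aux"] = test_metric(single_aux.values)
    out["test_single_tgt"] = test_metric(single_tgt.values)

    # combined: tune omega on validation, apply to test
    tune = tune_omega(
        val_aux, beta_aux_v, val_tgt, beta_tgt_v, y_val,
        binary=binary, grid=bench.omega_grid, ridge_lambda=bench.ridge_lambda,
    )
    w = tune.selected
    out["omega_selected"] = w
    out["val_combined"] = dict(tune.grid)[w]
    from .impute import combined_impute

    comb = combined_impute(test_aux, beta_aux_t, test_tgt, beta_tgt_t, w, bench.ridge_lambda)
    out["test_combined"] = test_metric(comb.values)

    # transfer: aux-initialized SGD with early stopping tuned on validation
    cfg = ImputeConfig(
        ridge_lambda=bench.ridge_lambda,
        learning_rate=bench.learning_rate,
        max_epochs=bench.max_epochs,
        sgd_batch_snps=bench.sgd_batch_snps,
        seed=seed,
    )
    init_val = ls_impute(val_aux, beta_aux_v, bench.ridge_lambda)
    traj = transfer_impute(val_tgt, beta_tgt_v, init_val, cfg, metric_fn=val_metric)
    sel = select_epochs(traj.trajectory, metric_name)
    e_star = int(sel.selected)
    out["epoch_selected"] = e_star
    out["val_transfer"] = dict(sel.grid)[sel.selected]

    init_test = ls_impute(test_aux, beta_aux_t, bench.ridge_lambda)
    cfg_test = ImputeConfig(
        ridge_lambda=bench.ridge_lambda,
        learning_rate=bench.learning_rate,
        max_epochs=e_star,
        sgd_batch_snps=bench.sgd_batch_snps,
        seed=seed + 1,
    )
    transfer = transfer_impute(test_tgt, beta_tgt_t, init_test, cfg_test)
    out["test_transfer"] = test_metric(transfer.values)
    return out


def run_benchmark(
    n_seeds: int = 20,
    base_seed: int = 0,
    sim: SimConfig | None = None,
    bench: BenchmarkConfig = BenchmarkConfig(),
) -> dict:
    """Replicate the study over seeds and average the test metrics."""
    from dataclasses import replace as _replace

    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        cfg = _replace(sim, seed=seed) if sim is not None else SimConfig(seed=seed)
        rows.append(run_study(simulate_cohorts(cfg), bench, seed=seed))
    keys = ("test_single_aux", "test_single_tgt", "test_combined", "test_transfer")
    summary = {f"mean_{k}": float(np.mean([r[k] for r in rows])) for k in keys}
    interior = [0.0 < r["omega_selected"] < 1.0 for r in rows]
    summary["interior_omega_fraction"] = float(np.mean(interior))
    summary["replicates"] = rows
    return summary


def lr_robustness(
    study: SimulatedStudy,
    bench: BenchmarkConfig = BenchmarkConfig(),
    lrs: tuple = (0.1, 0.01, 0.001),
    seed: int = 0,
) -> dict:
    """Max validation metric over epochs for several learning rates.

    Epoch budgets scale inversely with the step size so each run covers
    the same stretch of the optimization path; the attainable peak should
    be nearly identical across rates.
    """
    binary = study.config.prevalence is not None
    spec_aux = SnpSelectionSpec(bench.panel_size, bench.p_threshold, seed=seed * 2 + 1)
    spec_tgt = SnpSelectionSpec(bench.panel_size, bench.p_threshold, seed=seed * 2 + 2)
    val_aux, beta_aux_v = _std_panel(
        study.val_genotypes, study.aux_stats, select_snps(study.aux_stats, spec_aux)
    )
    val_tgt, beta_tgt_v = _std_panel(
        study.val_genotypes, study.tgt_stats, select_snps(study.tgt_stats, spec_tgt)
    )
    _, val_metric = metric_for(study.val_phenotype.values, binary)
    init = ls_impute(val_aux, beta_aux_v, bench.ridge_lambda)
    ref_lr = max(lrs)
    out = {}
    for lr in lrs:
        cfg = ImputeConfig(
            ridge_lambda=bench.ridge_lambda,
            learning_rate=lr,
            max_epochs=int(round(bench.max_epochs * ref_lr / lr)),
            sgd_batch_snps=bench.sgd_batch_snps,
            seed=seed,
        )
        traj = transfer_impute(val_tgt, beta_tgt_v, init, cfg, metric_fn=val_metric)
        out[lr] = max(t["metric"] for t in traj.trajectory)
    return out
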