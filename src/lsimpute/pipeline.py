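"""One-configuration workflow: QC -> harmonize -> select -> impute -> tune -> evaluate.

A YAML run configuration names the genotype/phenotype/summary inputs and
all tuning parameters; :func:`run_workflow` executes the stages in order
and writes a JSON manifest recording every artifact, parameter, seed and
metric.  Tuning uses only the validation split; the test split is imputed
once, with the validation-selected parameters, and never feeds back.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genodata import (
    align_to_panel,
    harmonize,
    read_phenotype,
    read_plink,
    read_sumstats,
    standardize,
)
from .gwas_stats import SnpSelectionSpec, glm_to_lm, logit_baseline, marginal_gwas, select_snps
from .impute import DEFAULT_RIDGE, ImputeConfig, combined_impute, ls_impute, transfer_impute
from .qc import QcThresholds, apply_qc, ld_prune, write_verdicts
from .tune_eval import metric_for, select_epochs, tune_omega

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (see examples/ for the YAML layout)."""

    val_bed: str
    val_pheno: str
    test_bed: str
    aux_sumstats: str
    tgt_sumstats: str
    out_dir: str
    test_pheno: str | None = None
    binary_trait: bool = False
    aux_cases: int | None = None
    aux_controls: int | None = None
    tgt_cases: int | None = None
    tgt_controls: int | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    run_ld_prune: bool = False
    panel_size: int = 1000
    p_threshold: float = 0.05
    ridge_lambda: float = DEFAULT_RIDGE
    learning_rate: float = 0.1
    max_epochs: int = 200
    sgd_batch_snps: int = 512
    omega_grid_step: float = 0.01
    run_gwas_on_imputed: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        qc_raw = raw.pop("qc", None)
        try:
            cfg = cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e
        if qc_raw:
            cfg.qc = QcThresholds(**qc_raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("val_bed", "val_pheno", "test_bed", "aux_sumstats", "tgt_sumstats"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name}: {p} does not exist")
        if self.test_pheno is not None and not Path(self.test_pheno).exists():
            raise ConfigError(f"test_pheno: {self.test_pheno} does not exist")


def _convert_if_binary(stats, cases, controls):
    """GLM -> LM conversion for logistic summary statistics, if counts known."""
    if cases is None or controls is None:
        return stats
    b0 = logit_baseline(cases, controls)
    tab = stats.table.copy()
    tab["beta_lm"] = glm_to_lm(b0, tab["beta_lm"].to_numpy())
    from dataclasses import replace

    return replace(stats, table=tab, n_cases=cases, n_controls=controls)


def run_workflow(cfg: RunConfig) -> dict:
    """Execute the full imputation workflow; returns (and writes) the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(cfg).items()}, "stages": {}}
    stage = "load"
    try:
        val_raw = read_plink(cfg.val_bed)
        test_raw = read_plink(cfg.test_bed)
        y_val = read_phenotype(cfg.val_pheno)
        if val_raw.sample_ids != y_val.sample_ids:
            raise ConfigError("validation phenotype is not aligned to genotypes")
        aux = _convert_if_binary(
            read_sumstats(cfg.aux_sumstats, "aux"), cfg.aux_cases, cfg.aux_controls
        )
        tgt = _convert_if_binary(
            read_sumstats(cfg.tgt_sumstats, "target"), cfg.tgt_cases, cfg.tgt_controls
        )

        stage = "qc"
        val_qc, verdicts = apply_qc(val_raw, cfg.qc)
        write_verdicts(verdicts, out / "qc_verdicts.tsv")
        kept = val_qc.snp_ids
        if cfg.run_ld_prune:
            kept = ld_prune(val_qc, cfg.qc)
            val_qc = val_qc.subset_snps(kept)
        test_qc = test_raw.subset_snps(kept)
        manifest["stages"]["qc"] = {
            "n_input_snps": val_raw.n_snps,
            "n_kept_snps": len(kept),
            "verdicts": str(out / "qc_verdicts.tsv"),
        }

        stage = "harmonize"
        aux_h = harmonize(aux, val_qc.snps)
        tgt_h = harmonize(tgt, val_qc.snps)
        manifest["stages"]["harmonize"] = {
            "aux_snps": len(aux_h), "tgt_snps": len(tgt_h),
        }

        stage = "select_snps"
        panel_aux = select_snps(
            aux_h, SnpSelectionSpec(min(cfg.panel_size, len(aux_h)), cfg.p_threshold, cfg.seed)
        )
        panel_tgt = select_snps(
            tgt_h, SnpSelectionSpec(min(cfg.panel_size, len(tgt_h)), cfg.p_threshold, cfg.seed + 1)
        )
        manifest["stages"]["select_snps"] = {
            "panel_aux": len(panel_aux), "panel_tgt": len(panel_tgt), "seed": cfg.seed,
        }

        stage = "tune"
        val_aux = standardize(val_qc.subset_snps(panel_aux))
        val_tgt = standardize(val_qc.subset_snps(panel_tgt))
        b_aux_v = align_to_panel(aux_h, val_aux)
        b_tgt_v = align_to_panel(tgt_h, val_tgt)
        metric_name, val_metric = metric_for(y_val.values, cfg.binary_trait)
        tune = tune_omega(
            val_aux, b_aux_v, val_tgt, b_tgt_v, y_val.values,
            binary=cfg.binary_trait,
            grid=np.round(np.arange(0.0, 1.0 + 1e-9, cfg.omega_grid_step), 6),
            ridge_lambda=cfg.ridge_lambda,
        )
        icfg = ImputeConfig(
            ridge_lambda=cfg.ridge_lambda, learning_rate=cfg.learning_rate,
            max_epochs=cfg.max_epochs, sgd_batch_snps=cfg.sgd_batch_snps, seed=cfg.seed,
        )
        init_val = ls_impute(val_aux, b_aux_v, cfg.ridge_lambda)
        traj = transfer_impute(val_tgt, b_tgt_v, init_val, icfg, metric_fn=val_metric)
        epochs = select_epochs(traj.trajectory, metric_name)
        manifest["stages"]["tune"] = {
            "metric": metric_name,
            "omega_selected": tune.selected,
            "omega_val_metric": dict(tune.grid)[tune.selected],
            "epoch_selected": int(epochs.selected),
            "epoch_val_metric": dict(epochs.grid)[epochs.selected],
        }

        stage = "impute_test"
        test_aux = standardize(test_qc.subset_snps(panel_aux))
        test_tgt = standardize(test_qc.subset_snps(panel_tgt))
        b_aux_t = align_to_panel(aux_h, test_aux)
        b_tgt_t = align_to_panel(tgt_h, test_tgt)
        results = {
            "single_aux": ls_impute(test_aux, b_aux_t, cfg.ridge_lambda),
            "single_tgt": ls_impute(test_tgt, b_tgt_t, cfg.ridge_lambda),
            "combined": combined_impute(
                test_aux, b_aux_t, test_tgt, b_tgt_t, tune.selected, cfg.ridge_lambda
            ),
        }
        init_test = ls_impute(test_aux, b_aux_t, cfg.ridge_lambda)
        from dataclasses import replace

        results["transfer"] = transfer_impute(
            test_tgt, b_tgt_t, init_test,
            replace(icfg, max_epochs=int(epochs.selected), seed=cfg.seed + 1),
        )
        from .genodata import PhenotypeVector, write_phenotype

        for name, imp in results.items():
            write_phenotype(
                PhenotypeVector(imp.sample_ids, imp.values, name), out / f"imputed_{name}.tsv"
            )
            sidecar = {
                "method": imp.method, "config": imp.config,
                "n_panel_snps": len(imp.snp_panel), "seed": cfg.seed,
            }
            (out / f"imputed_{name}.json").write_text(json.dumps(sidecar, indent=1))
        manifest["stages"]["impute_test"] = {
            name: str(out / f"imputed_{name}.tsv") for name in results
        }

        stage = "evaluate"
        if cfg.test_pheno is not None:
            y_test = read_phenotype(cfg.test_pheno)
            _, test_metric = metric_for(y_test.values, cfg.binary_trait)
            manifest["stages"]["evaluate"] = {
                name: test_metric(imp.values) for name, imp in results.items()
            }
            if cfg.binary_trait:
                from .tune_eval import delong_test

                _, _, z, pval = delong_test(
                    results["transfer"].values, results["single_aux"].values,
                    y_test.values.astype(int),
                )
                manifest["stages"]["evaluate"]["delong_transfer_vs_aux_p"] = pval

        if cfg.run_gwas_on_imputed:
            stage = "marginal_gwas"
            gw = marginal_gwas(
                test_tgt,
                type(y_val)(results["transfer"].sample_ids, results["transfer"].values),
            )
            gw_path = out / "gwas_imputed_transfer.tsv"
            gw.to_csv(gw_path, sep="\t", index=False)
            manifest["stages"]["marginal_gwas"] = {"table": str(gw_path)}
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
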