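# lsimpute

Trait imputation for genotyped cohorts from GWAS summary statistics,
including two multi-ancestry extensions that borrow strength from a
larger auxiliary-ancestry GWAS to improve imputation in a smaller target
cohort.

## The problem

Large biobanks genotype far more people than they phenotype, and GWAS
power is concentrated in a few ancestries. Given only per-SNP marginal
effect estimates `β*` (no individual-level GWAS data) and a standardized
genotype matrix `X` (`n2` samples, `p` SNPs, `p ≫ n2`), the missing trait
values solve the least-squares inversion of the marginal-association map:

    Ŷ = argmin_Y ‖β* − X′Y/(n2−1)‖²  =  (n2−1) (XX′)⁺ X β* ,

with the pseudoinverse realized as a ridge solve `(XX′ + λI)⁻¹`,
`λ = 10⁻⁶`. Binary-trait (logistic) summary statistics are first mapped
to the linear scale via `β = μ(1−μ)·b₁`, `μ = logistic(log(cases/controls))`.

Two ways to use a second ancestry's GWAS:

* **Combined** — minimize `ω‖β₁* − X̃′Y/(n2−1)‖² + (1−ω)‖β₂* − X̃̃′Y/(n2−1)‖²`
  (closed form; `ω` tuned on a validation cohort).
* **Transfer** — start from the auxiliary-ancestry imputation and refine
  toward the target ancestry's statistics by mini-batch SGD on the convex
  target objective, with early stopping at the validation-optimal epoch
  (running to convergence would reproduce the target-only solution and
  discard the auxiliary start).

The package also provides the surrounding machinery: PLINK 1 bed/bim/fam
and summary-statistic TSV I/O, allele harmonization, SNP-level QC (MAF,
missingness, Hardy–Weinberg exact test, LD pruning), SNP-panel selection,
Pearson/AUC/ROC evaluation with DeLong's paired AUC test, marginal GWAS
on imputed traits, a two-ancestry synthetic-study generator, a YAML-driven
pipeline, and a CLI (`lsimpute run|simulate|qc|harmonize|select-snps|
impute|tune|eval|gwas`).

## Worked example

`examples/03_transfer_early_stopping.py` simulates a two-ancestry study
(1000 SNPs; 8000-sample auxiliary GWAS vs 500-sample target GWAS), imputes
a 300-sample validation cohort starting from the auxiliary solution,
early-stops on the validation correlation, and applies the selected epoch
to the test cohort:

```
validation metric peaks at epoch 189 (r = 0.486; epoch 0, the pure
auxiliary start, gives r = 0.432)
test correlation at the selected epoch: 0.422
```

The rise from 0.432 to 0.486 is the value of refining the auxiliary start
with target-ancestry statistics; stopping early rather than converging is
what keeps it. The other examples cover single-ancestry imputation,
ω-tuning for the combined method, and QC + harmonization on files.

See `docs/methods.md` for the model, the SGD convention, the synthetic
generator's assumptions, and known limitations.

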