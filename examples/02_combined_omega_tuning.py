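"""Blend two ancestries' summary statistics and tune the mixing weight.

The combined method minimizes an omega-weighted sum of the two ancestries'
marginal-equation objectives; omega is chosen on a validation cohort and
then applied to the test cohort.
"""

from lsimpute import SimConfig, simulate_cohorts, standardize, align_to_panel
from lsimpute.impute import combined_impute
from lsimpute.tune_eval import pearson_corr, tune_omega

study = simulate_cohorts(
    SimConfig(p=1000, n_aux_gwas=8000, n_tgt_gwas=500, n_val=300, n_test=300,
              n_causal=100, seed=11)
)

val = standardize(study.val_genotypes)
test = standardize(study.test_genotypes)
b_aux_val = align_to_panel(study.aux_stats, val)
b_tgt_val = align_to_panel(study.tgt_stats, val)

tuned = tune_omega(val, b_aux_val, val, b_tgt_val, study.val_phenotype.values)
print(f"validation-selected omega: {tuned.selected:.2f} "
      f"(validation r = {dict(tuned.grid)[tuned.selected]:.3f})")

imp = combined_impute(
    test, align_to_panel(study.aux_stats, test),
    test, align_to_panel(study.tgt_stats, test),
    omega=tuned.selected,
)
r = pearson_corr(imp.values, study.test_phenotype.values)
print(f"test correlation at the selected omega: {r:.3f}")
# omega near 1 leans on the (large) auxiliary GWAS, omega near 0 on the
# (small) target GWAS; an interior optimum means both carry usable signal.
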