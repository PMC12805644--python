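# Methods

## The imputation model

Given a cohort of `n2` genotyped individuals and per-SNP marginal effect
estimates from an external GWAS, the package imputes the cohort's missing
trait values by inverting the marginal-association map. Let `X` be the
`n2 x p` genotype matrix, column-standardized to mean 0 and sample
variance 1 (denominator `n2-1`). If the trait vector `Y` were observed,
its marginal estimates would be `βhat = X'Y/(n2-1)`; substituting external
estimates `β*` for `βhat` and solving the (under-determined, `p >> n2`)
system in the least-squares sense gives

    Yhat = argmin_Y || β* − X'Y/(n2−1) ||²  =  (n2−1) (XX')⁺ X β* ,

with `⁺` the Moore–Penrose pseudoinverse. In code the pseudoinverse is a
ridge-regularized symmetric solve `(XX' + λI)⁻¹` with `λ = 1e-6`, exact in
the limit `λ → 0⁺`; the solve is an `n2 x n2` Cholesky factorization, so
cost scales with the cohort, not the SNP panel.

Two facts shape everything downstream:

* **Location invariance.** Standardized columns are centered, so `X'1 = 0`
  and `XX'` is singular along the all-ones vector: marginal statistics
  carry no information about the trait mean, and `Yhat` is always
  mean-zero. Self-recovery and convergence statements therefore hold for
  the centered trait; correlation/AUC evaluation is unaffected.
* **p >> n2 is required.** With fewer SNPs than samples the system of
  marginal equations cannot pin down individual values; the code warns
  when `p <= n2`.

### Binary traits

Logistic-regression GWAS effect sizes (log odds ratios `b1`) are mapped to
the linear-model scale by `β = μ(1−μ)·b1` with `μ = logistic(b0)` and `b0`
the baseline log odds of case status, estimated as `log(n_cases /
n_controls)`. This is the first-order equivalence of the logistic and
linear-probability fits for small effects; at a balanced baseline
(`b0 = 0`) the multiplier is exactly 1/4. The implementation uses
`expit(b0)·expit(−b0)`, which is numerically stable for large `|b0|` and
exactly symmetric under `b0 ↔ −b0`. Imputed values for binary traits are
continuous risk scores, evaluated by AUC, never thresholded internally.

## Multi-ancestry extensions

**Combined.** With summary statistics `β1*` (auxiliary ancestry, panel
`X1`) and `β2*` (target ancestry, panel `X2`, both column subsets of the
same cohort's genotypes), the blended objective

    ω ||β1* − X1'Y/(n2−1)||² + (1−ω) ||β2* − X2'Y/(n2−1)||²

has the closed form `Yhat = (n2−1)(ωX1X1' + (1−ω)X2X2')⁺(ωX1β1* +
(1−ω)X2β2*)`. At `ω ∈ {0,1}` this reduces bit-for-bit to the
single-ancestry solution. `ω` is chosen by grid search (step 0.01 by
default, ties toward smaller `ω`) on a validation cohort.

**Transfer.** Minimize the target-only objective `f(Y) = ||β2* −
X2'Y/(n2−1)||²` by (mini-batch) gradient descent, started from the
auxiliary-ancestry imputation. Because `f` is convex and quadratic,
running to convergence reproduces the target-only solution and forgets
the start; early stopping — the epoch maximizing the validation metric —
preserves the auxiliary information. The stopping epoch (and the learning
rate, if desired) tuned on validation is then applied to the test cohort.

### SGD convention

The batch update is

    Y ← Y + lr · (2/(n2−1)) · Σ_{j∈B} x_j (β*_j − x_j'Y/(n2−1)),

i.e. the gradient of the batch's *sum* of squared residuals. One full
epoch then applies approximately `lr · 2XX'/(n2−1)²` of the residual
regardless of batch size, which makes "epochs" the natural tuning unit
and keeps learning-rate scales comparable across batch sizes; full-batch
descent is stable for `lr < (n2−1)²/λmax(XX')` (`safe_learning_rate`
computes this bound). A batch-*mean* convention was considered and
rejected: it makes the per-epoch step depend on batch size and renders
learning rates in the conventional 0.1–0.001 range inert at realistic
problem sizes. Under the sum convention, trajectories at learning rates
scaled by `c` with epoch budgets scaled by `1/c` are near-exact
reparameterizations of each other, which is why the attainable validation
peak is insensitive to the learning rate (the spread observed on the
benchmark is < 1e-6).

The divergence guard aborts when the objective exceeds 1e6 x its initial
value, naming the epoch.

### Sample batching

Cohorts larger than `sample_batch_max` (default 2000) are split into
contiguous batches, each re-standardized over its own samples (the
marginal-equation algebra is per solved system) and imputed
independently. Batched and unbatched runs are not identical: each batch
solves its own Gram system and loses its between-batch mean component
(roughly a `1/n_batch` variance share), so per-sample outputs correlate
highly but not perfectly.

## Quality control

Per-SNP filters with the standard defaults: minor allele frequency
< 0.05, missing fraction > 0.10, Hardy–Weinberg exact-test p < 1e-3. The
HWE test is the exact conditional test on allele counts (two-sided, no
mid-p correction, matching the common genotype-QC default), computed in
log space and evaluated on complete calls only. The three filters
commute; verdicts record each SNP's metrics and failure reasons.

LD pruning is greedy within sliding windows of 50 SNPs, step 5, r² cap
0.8. The window is a SNP count, not a physical distance (the 50/5 idiom;
the alternative kb reading is noted as unresolved upstream). r² is
computed on mean-imputed centered dosages; within a window the worse
member of the worst pair is removed — lower MAF first, later position on
ties — until no retained pair exceeds the cap. The pruning variant and
tie-break are this package's choice; published pipelines differ in
detail.

Missing genotypes are mean-imputed per SNP before standardization, which
keeps the imputation algebra exact on a complete matrix; variants with
heavy missingness should have been removed by QC first. Strand-ambiguous
SNPs (A/T, C/G) are dropped during harmonization rather than resolved by
frequency, since frequency matching needs population references the
package does not assume.

## SNP-panel selection

Panels for imputation take every SNP significant at the configured
threshold (0.05) first; if significant SNPs exceed the target count a
seeded uniform subset is taken, otherwise the shortfall is filled by a
seeded uniform draw from the nonsignificant remainder. Output is ordered
by (chromosome, position) and reproducible from the seed.

## Synthetic two-ancestry studies

The generator emulates the asymmetric design the methods target:

| parameter | default | meaning |
|---|---|---|
| `p` | 5000 | SNPs |
| `n_aux_gwas` | 50 000 | auxiliary-ancestry GWAS panel |
| `n_tgt_gwas` | 1 000 | target-ancestry GWAS panel |
| `n_val`, `n_test` | 500 | target-cohort splits |
| `fst` | 0.01 | Balding–Nichols divergence |
| `rho_effects` | 0.8 | cross-ancestry effect correlation |
| `h2` | 0.5 | heritability of the liability |
| `n_causal` | 500 | causal SNPs (10% of panel — a moderately polygenic trait) |
| `prevalence` | none | liability-threshold case fraction (binary traits) |

Allele frequencies follow the Balding–Nichols model (ancestral `q ~
U(0.05, 0.95)`, population frequencies `Beta(q(1−F)/F, (1−q)(1−F)/F)`).
Causal effects are Gaussian with variance `h2/n_causal`; target effects
are `ρ·β_aux + √(1−ρ²)·independent`. Traits are `Y = X_std β + e` with
`e ~ N(0, 1−h2)`, thresholded at the `1−prevalence` normal quantile for
binary traits. GWAS summary statistics are genuine per-SNP regressions on
simulated individual-level panels, computed in SNP blocks with a two-pass
scheme that regenerates each block from its own RNG substream so the
50 000-sample panel is never materialized in floating point; the blocked
path is tested to agree with the reference per-SNP regression.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent given frequencies; an AR(1)-copula mode exists only to give
LD pruning realistic input), admixture, population stratification within
a cohort, genotyping error, and covariates. Two consequences matter for
interpreting benchmark results. First, passing tests show the estimators
behave correctly under the generative model, not that real-data
correlations will match. Second, without LD both panels' Gram matrices
are near-isotropic, so the combined method's ω-path and the transfer
method's SGD path span nearly the same family of solutions; the two
multi-ancestry methods are then equivalent up to validation-selection
noise (~0.005 in test correlation) rather than separated as they can be
on real, LD-structured data.

## Benchmark protocol

`lsimpute.benchmark.run_study` runs the full protocol per replicate: 2000
SNPs selected per ancestry (keeping `p` well above the 500-sample
cohorts), validation-cohort imputation across the ω grid and the epoch
trajectory, parameter selection on validation only, then one test-cohort
imputation per method. The transfer step size is 0.1 with a 400-epoch
budget; at this problem scale one epoch applies roughly `lr·2XX'/(n2−1)²`
of the residual, putting the early-stopping peak (typically epochs
30–110) well inside the budget. The learning-rate robustness check runs
0.1/0.01/0.001 with budgets 400/4000/40000. Replicated runs use 20 seeds;
`scripts/acceptance.py` reports the means.

## Numerical choices and degenerate inputs

* Ridge `λ = 1e-6` on the Gram solve; an SVD-pseudoinverse path is used
  as an independent oracle in tests, never in production code.
* Pearson correlation refuses constant inputs; AUC and ROC refuse
  single-class labels; ties in scores get half credit (Mann–Whitney).
* DeLong's paired test returns `z = 0, p = 1` for identical score
  vectors, and raises on a zero-variance difference with unequal AUCs.
* Tuning argmaxes break ties toward the smaller ω / earlier epoch.
* p-values below 1e-300 in the marginal GWAS are reported as 0 with an
  `underflow` flag.
* Constant genotype columns are dropped (with a warning) at
  standardization; monomorphic columns contribute nothing to simulated
  genetic values.

## Known limitations

* Exactly two ancestries per run; no covariate adjustment or mixed-model
  summary statistics.
* The trait scale of `Yhat` follows the scale implied by the supplied
  summary statistics (whether the upstream GWAS standardized its
  phenotype is unknowable from the statistics alone); rank-based metrics
  are unaffected.
* Hard-call dosages only ({0,1,2} + missing); no VCF/BGEN, no
  multi-allelic sites.
* LD pruning is quadratic in window size and meant for panels up to a few
  hundred thousand SNPs, not whole-genome sequencing sites.
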