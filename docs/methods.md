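# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices and the known limitations of `poemod`.

## Genotype coding and phase convention

A biallelic SNP with parent-of-origin information has four ordered genotypes.
With paternal haplotype dosage `dp` and maternal `dm` (alternate-allele
counts, 0/1), the design columns are

    Add = dp + dm        (0, 1, 1, 2)
    Dom = dp XOR dm      (0, 1, 1, 0)
    POE = dp − dm        (0, −1, +1, 0)

so `|POE| = Dom` always. The phase convention — first VCF allele paternal —
is arbitrary but must be fixed once: flipping it flips only the sign of the
POE and POE×Mod coefficients, never their p-values. The writer stamps the
convention into the VCF header and the reader assumes it.

Parental origin in duos/trios is resolved by a deterministic Mendelian
argument: an assignment (paternal, maternal) is accepted only when it is the
unique one compatible with the parents' transmissible alleles. Ambiguous
configurations (e.g. all three members heterozygous) are left missing, and
Mendelian-inconsistent families are flagged rather than raised, matching the
complete-case handling of the scan. This resolver does not perform
population-scale statistical phasing; genotypes whose origin it cannot force
are simply excluded from the affected trio tests.

## The interaction model

Per mQTL-modifier-CpG trio, ordinary least squares on the M-value scale:

    M = b_add·Add + b_dom·Dom + b_poe·POE
        + b_mod·Mod + b_axm·Add×Mod + b_pxm·POE×Mod
        + covariates + e

Modifiers are mean-centered before products are formed. Centering is a
design choice (not forced by the model): it decorrelates main-effect and
interaction columns, which stabilizes the sequential variance decomposition
and leaves the interaction t-statistic unchanged. The Dom×Mod product is
excluded from the default scan and available behind a flag for sensitivity
fits. Covariates are age, sex, cell proportions (one simplex column dropped
against the intercept), smoking (dropped when smoking itself is the tested
modifier) and optionally ORM-PCs. Designs are checked for rank via pivoted
QR, and rank-deficiency errors name the dependent columns. Fits require at
least 10 more complete cases than parameters.

### ORM-PCs

The omics relationship matrix is `W·Wᵀ/p` over standardized probes
(constant probes dropped with a warning). The top 20 eigenvector scores are
candidate covariates; any PC with a per-SNP simple-regression p below 5e-8
against any supplied SNP is removed, so genetic signal of interest is not
absorbed into the covariates. The 5e-8 threshold is the conventional
genome-wide significance level; it is configurable.

### Variance decomposition

Incremental R² is sequential over ordered blocks, by default
base → Mod → Add → Dom → POE → Add×Mod → POE×Mod. Increments are R²
differences between nested OLS fits, so they sum to `r2_full − r2_base`
exactly (to ~1e-15; the test suite asserts 1e-10). The block order is
configurable because with correlated predictors sequential increments are
order-dependent; the default places the interaction last so its increment is
the term's unique contribution.

### SNP localization and conditional fits

A genetic modifier built as a weighted allele score can be decomposed by
refitting the interaction model with each contributing SNP's dosage in place
of the score (`poe_by_snp_scan`, Bonferroni over the SNPs tested), and by
conditioning the score-level fit on POE×SNP terms
(`conditional_interaction_fit`). When the score is built from exactly the
conditioning SNPs, the POE×Mod column becomes linearly dependent on the
conditioning columns; this is detected and reported as "fully explained"
rather than raised, since exact collinearity here is the scientifically
expected outcome.

## Permutation inference

The permutation scheme is Freedman–Lane on reduced-model residuals: fit the
interaction model without POE×Mod, permute its residuals, add them back to
the reduced fitted values, refit the full model, and record the POE×Mod
t-statistic. This preserves covariate and main-effect structure while
nulling only the interaction, which is the standard construction for
permutation tests of a single term in the presence of nuisance covariates.
Empirical p-values use the plus-one rule, `p = (#{|t*| ≥ |t|} + 1)/(B + 1)`,
so they are never zero and are bounded below by the resolution `1/(B+1)`.
Refits are vectorized across permutations (the hat matrix is fixed), so 10⁴
draws at n = 1663 take well under a second.

Two tiers:

* **Global screen** — per whole-scan permutation replicate, each trio's null
  t is converted to a parametric p, and the permutation FDR at threshold p
  is the mean null count at or below p divided by the observed count,
  monotonized to be nondecreasing in p. A min-p family-wise variant is
  available behind a switch; pooled-p FDR is the default.
* **Trio-specific tests** — large-B permutation tests for the trios passing
  the screen, Bonferroni-multiplied by the number of trios entering this
  stage (configurable, since that multiplier is a study-design choice).

Replication requires both BH-FDR ≤ q in the replication sample and
direction-of-effect agreement for POE and POE×Mod between samples; failures
report which criterion broke.

## Downstream stages

* `rank_enrichment_test` — one-sided Mann–Whitney U on −log10(p) ranks
  (scipy; exact enumeration for n1·n2 ≤ 400 without ties, tie-corrected
  normal approximation otherwise).
* `lmm_adjust` — single-variance-component REML (`y = μ + g + e`,
  `g ~ N(0, σ²_g K)`) via the spectral decomposition of K; the variance
  ratio is optimized by bounded scalar minimization of the restricted
  likelihood in log-space over e^±12. Residuals subtract the fixed mean and
  the BLUP of g. `K ∝ I` makes the two components jointly unidentifiable;
  the routine then returns centered values with a warning instead of a
  spurious split.
* `association_scan` — per CpG × variable OLS with two-sided t-tests;
  Bonferroni denominator is the full planned family (n_cpgs × n_variables)
  even when zero-variance variables are skipped, so the correction never
  becomes anti-conservative through data-dependent family shrinkage.
* `dl_meta` — DerSimonian–Laird moment estimator with Wald intervals, no
  Knapp–Hartung correction. With k = 2 strata (discovery, replication) τ²
  frequently truncates to zero, in which case the estimator reduces exactly
  to the inverse-variance fixed-effect pool; this is expected behaviour, not
  a defect.
* `lognormalize` / `spearman_filtered` — the standard single-cell
  global-scaling transform `ln(1 + count/total × 10⁴)` and Spearman
  correlation over cells where both genes are detected (>0), with the
  retained n reported.

## The synthetic cohort generator

The generator emulates the statistical structure of a family-based
methylation cohort, not its molecular detail:

* **Families.** One offspring per family; a configurable fraction of
  families have both parents genotyped (trios), the rest one parent (duos).
  Parental alleles are drawn at per-SNP MAFs (uniform in a configurable
  range within (0, 0.5]); each offspring receives one allele per parent with
  the transmission recorded, so offspring phase is known by construction and
  the transmission invariant (every offspring haplotype is carried by the
  matching parent) is assertable exactly.
* **Imprinting patterns.** Presets constrain the genotype coefficients:
  *parental* (b_add and b_poe nonzero), *bipolar dominance* (only b_poe —
  homozygotes share a mean, reciprocal heterozygotes split symmetrically),
  *polar dominance* (b_dom and b_poe), *none*. Defaults b_add = 0.3,
  b_poe = 0.5, b_dom = 0.2 on the M-value scale with unit noise SD give
  per-term variance shares of a few percent, the regime reported for real
  POE-mQTLs.
* **Background bimodality.** Non-POE CpGs receive a latent per-individual
  binary epigenetic state (±2 M-units), reproducing the bimodal M-value
  distribution of ordinary genomic CpGs, against which POE CpGs sit at
  intermediate, unimodal levels. Sarle's bimodality coefficient with the
  0.555 uniform-reference threshold separates the two in tests at n ≥ 1000.
* **Modifiers.** Binary (Bernoulli, default p = 0.25), ordinal three-level
  smoking-like codes 0/1/2 with default probabilities (0.5, 0.3, 0.2),
  standard-normal continuous variables, and allele scores over unlinked SNPs
  with Gaussian weights (weights recorded in the truth dictionary). The
  source study does not publish its modifier distributions, so these
  defaults were chosen once as field-plausible and are configurable rather
  than inferred.
* **Interaction calibration.** When a target variance fraction `f` is
  requested, the interaction coefficient solves the quadratic
  `f·[Var(L0) + b²Var(c) + 2b·Cov(L0, c) + σ²] = b²Var(c)` (with `L0` the
  linear predictor without the interaction and `c = POE × Mod_centered`)
  using the realized component variances, so the interaction column's
  variance share equals `f` for that cohort draw up to the noise draw.
* **Covariates.** Age uniform over 18–58 years, sex with 40% male fraction,
  Dirichlet cell proportions (3 types, concentration 5), smoking as above.
  Each CpG receives small random covariate coefficients, recorded in truth.
* **Seeding.** A single root seed spawns per-stage child streams
  (genotypes, modifiers, covariates, pedigree, noise) through
  `numpy.random.SeedSequence`, so any configuration is bit-reproducible.

What the generator does **not** emulate: linkage disequilibrium,
recombination, multi-generation pedigrees, array probe intensities and their
measurement error model, cell-type deconvolution error, missing genotype
calls, and relatedness between analysis individuals. Passing tests therefore
demonstrate correctness of the estimators and the inference machinery under
a faithful generative version of the interaction model — not robustness to
every artefact of real array data.

## Simulation experiments and problem sizes

The packaged experiments run at the emulated study's discovery size,
n = 1663 unrelated individuals, with 200 replicates for calibration and
bias (Monte-Carlo SE of the mean interaction-R² estimate ≈ 0.1 percentage
points) and 1000 replicates at n = 400 for the type-I error check (binomial
95% half-width ≈ 1.4 percentage points). These sizes give tight Monte-Carlo
error at interactive runtimes; all experiments derive their per-replicate
seeds from a single root seed.

## Known limitations

* The global-permutation statistic of the original two-tier scheme is not
  publicly specified; pooled-p permutation FDR (with a min-p alternative) is
  a deliberate reconstruction of the standard approach.
* The discovery scan assumes unrelated individuals (OLS); kinship adjustment
  is available only as the downstream `lmm_adjust` residualization step, not
  inside the trio fits.
* `infer_parental_origin` is a per-SNP Mendelian resolver; it cannot use
  linkage information across SNPs, so duo heterozygote × heterozygote
  configurations stay unresolved that full pedigree phasing could recover.
* DerSimonian–Laird with two strata has essentially no power to estimate τ²;
  pooled estimates should be read as fixed-effect-like in that regime.
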