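# poemod

Detection of genetic and environmental **modifiers of parent-of-origin
effects (POE)** on DNA methylation.

## The problem

A POE-mQTL is a SNP whose effect on a nearby CpG's methylation depends on
which parent transmitted the allele: the hallmark is a methylation difference
between the two *reciprocal heterozygotes* (paternal-alt `aA` vs maternal-alt
`Aa`). Genomic imprinting is established and maintained by a delicate,
environment-sensitive machinery, so that heterozygote contrast need not be
constant — smoking, or genetically predicted expression of methylation
machinery genes (writers, erasers, imprinting factors), can amplify or dampen
it. `poemod` implements the full analysis needed to find such *modifiable
POE*: genotype coding, the interaction model, two-tier permutation multiple
testing, replication assessment, and downstream association/meta-analysis —
together with a synthetic family-cohort generator with known ground truth, so
every stage is testable.

It is aimed at statistical geneticists and epigenomics analysts who have
parent-of-origin phased genotypes (from parent-offspring duos/trios), a CpG
methylation matrix (M-values) and candidate modifier variables.

## The model

Genotypes are coded with the paternal allele first (`p|m` in the phased VCF):

| genotype | Add | Dom | POE |
|----------|-----|-----|-----|
| `AA` (0\|0) | 0 | 0 | 0 |
| `Aa` (0\|1) | 1 | 1 | −1 |
| `aA` (1\|0) | 1 | 1 | +1 |
| `aa` (1\|1) | 2 | 0 | 0 |

Per mQTL-modifier-CpG trio, two OLS models are fitted:

```
non-interaction:  M = Add + Dom + POE + covariates + e
interaction:      M = Add + Dom + POE + Mod + Add×Mod + POE×Mod + covariates + e
```

The POE×Mod coefficient is the quantity of interest: a nonzero value means
the reciprocal-heterozygote contrast changes with the modifier. Covariates
are age, sex, cell proportions, smoking (dropped when smoking is the tested
modifier) and SNP-screened principal components of a methylation-based omics
relationship matrix (ORM-PCs). Significance is assessed by Freedman–Lane
residual permutation: a global permutation FDR across all trios, then
trio-specific permutation tests with Bonferroni adjustment. Replication
requires FDR ≤ 0.05 in the held-out sample *and* direction-of-effect
consistency for both POE and POE×Mod. Strata are combined with
DerSimonian–Laird random-effects meta-analysis.

## Worked example

```python
from poemod import (SimulationConfig, ModifierSpec, TrioSpec,
                    simulate_cohort, simulate_methylation,
                    fit_poe_model, variance_decomposition)

cfg = SimulationConfig(
    n_families=1663, trio_fraction=1.0, n_snps=1, n_cpgs=1,
    poe_patterns=["parental"], beta_add=0.3, beta_poe=0.5,
    modifiers=[ModifierSpec(name="mod", kind="continuous", main_beta=0.2,
                            target_variance_fraction=0.022, target_cpg=0)],
    noise_sd=1.0, seed=7,
)
data = simulate_methylation(simulate_cohort(cfg), cfg)
trio = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="mod")
fit = fit_poe_model(trio, data)
print(fit.terms.loc[["POE", "POE:Mod"]].round(4))
dec = variance_decomposition(trio, data)
print(f"POE x Mod incremental R^2: {dec['increments']['POE:Mod']:.4f}")
```

prints

```
         estimate      se        t    p
POE        0.5242  0.0358  14.6328  0.0
POE:Mod    0.2669  0.0359   7.4295  0.0
POE x Mod incremental R^2: 0.0255
```

The POE estimate (0.52) recovers the generative per-allele parent-of-origin
effect of 0.5; the interaction coefficient was calibrated so the POE×Mod
column explains 2.2% of methylation variance, and the sequential variance
decomposition estimates 2.6% for this particular cohort draw (the mean over
200 draws is 2.2%).

A full pipeline run (simulate → scan → permute → replicate → meta) is driven
by a YAML config:

```bash
poemod run-all --config run.yaml
```

which writes result TSVs, a plain-text summary and a manifest with seeds and
file hashes under the configured output directory.

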