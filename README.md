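# gemscan

Fast, memory-bounded association scans for epigenome-wide studies
(EWAS): methylation vs environment, genome-wide methQTL mapping
(methylation vs genotype), and genotype-by-environment interaction
effects on methylation.

## Who this is for

EWAS studies routinely need millions to billions of small linear
regressions: every CpG against every exposure, every SNP, or every
SNP-exposure combination, adjusted for covariates such as sex or cell
composition. Fitting each model with a general-purpose regression
routine is prohibitively slow at that scale. `gemscan` is for
researchers who want those scans to run on an ordinary machine in
minutes, with output they can trust because every number is checkable
against an explicit per-pair least-squares fit.

## The statistical core

All three scans test the slope β in

    M = α + β·X + γ·cvrt + ε

where M is a CpG methylation row (β-values in [0, 1]), X is an
environment row (Emodel), an additive genotype dosage row coded 0/1/2
(Gmodel), or the genotype-environment product G∘E with G and E main
effects absorbed (GxEmodel), and cvrt are nuisance covariates.

Rather than fitting each model separately, every row of M and X is
projected onto the orthogonal complement of span{1, cvrt} and scaled to
unit norm. The correlation r = ⟨x̃, ỹ⟩ then carries the complete slope
test:

    t = r·√(df / (1 − r²)),  df = n − n_cvrt − 2,

identical to the t statistic of β in the explicit fit. A whole scan is
therefore one matrix of inner products, evaluated in predictor blocks so
peak memory is bounded by `block_size × n_samples` whatever the scan
size. The interaction test reduces the same way to a partial
correlation of the residualized outcome and product term given the
genotype, with df = n − n_cvrt − 4 (see `docs/methods.md`).

Missing cells are mean-imputed per feature before projection. Results
are Benjamini–Hochberg corrected over the number of tests *computed*
(not just those emitted below the output p threshold), SNP–CpG pairs
are classified cis / trans / disrupting from BED annotations, and a QQ
plot with the genomic-inflation factor λ and a genotype-segregation
scatter plot are available as diagnostics.

A deliberately slow oracle module (`gemscan.oracle`) fits each pair
explicitly by least squares; on complete data the fast path reproduces
it to ~1e-11 relative, which the test suite and acceptance script
verify end to end.

## Worked example

```python
from gemscan import simulate, models

spec = simulate.SimulationSpec(
    n_samples=237, n_cpgs=300, n_snps=800, n_envs=3,
    g_effects={(0, 10): 0.6},          # CpG 0 gets a methQTL at SNP 10
    gxe_effects={(5, 20, 1): 0.7},     # CpG 5: SNP 20 x env 1 interaction
    noise_sd=0.2, seed=11,
)
study = simulate.simulate_study(spec)

gm = models.run_gmodel(study.M, study.G, study.cvrt,
                       models.ScanConfig(p_output_threshold=1e-5),
                       cpg_ann=study.cpg_ann, snp_ann=study.snp_ann)
print(f"methQTL scan: {gm.summary.tests_attempted} models, "
      f"{gm.summary.records_emitted} emitted, lambda={gm.summary.lambda_gc:.3f}")
top = gm.records[0]
print(f"top pair: {top.outcome_id} ~ {top.predictor_id} "
      f"beta={top.beta:.4f} p={top.p_value:.3e} q={top.fdr:.3e} [{top.pair_class}]")
```

prints

```
methQTL scan: 240000 models, 2 emitted, lambda=0.999
top pair: cg0000001 ~ rs0000011 beta=0.1227 p=2.270e-65 q=5.448e-60 [cis]
```

240,000 models were enumerated (300 CpGs × 800 SNPs); λ ≈ 1 says the
null tests are calibrated; the top emitted record is the planted
methQTL, recovered as a cis pair at q ≪ 0.05 (`beta` is the methylation
change per dosage allele; the one other record below the 1e-5 output
threshold is a null pair at p ≈ 1e-6, as expected among 240,000 tests).
The same study's interaction scan ranks the planted CpG 5 / SNP 20 /
env 2 triplet first at p ≈ 2e-75.

## Command line

Each subcommand writes its result TSV, a summary side-car with test
counts and λ, and a `manifest.json` recording inputs, configuration and
seed, so runs are reproducible bit for bit:

```bash
gemscan simulate --out demo --seed 7 --samples 150 --cpgs 200 --snps 400 --envs 3
gemscan gmodel  --meth demo/methylation.tsv --geno demo/genotype.tsv \
                --cvrt demo/covariate.tsv \
                --cpg-ann demo/cpg_annotation.bed --snp-ann demo/snp_annotation.bed \
                --pv-threshold 1e-3 --out gscan
gemscan emodel  --meth demo/methylation.tsv --env demo/environment.tsv --out escan
gemscan gxemodel --meth demo/methylation.tsv --geno demo/genotype.tsv \
                 --env demo/environment.tsv --out xscan
gemscan qqplot  --results escan/emodel_results.tsv --out qq.png
gemscan segplot --meth demo/methylation.tsv --geno demo/genotype.tsv \
                --env demo/environment.tsv \
                --cpg cg0000001 --snp rs0000001 --env-id env01 --out seg.png
```

Input matrices are tab-separated, features × samples, with a sample-ID
header row (an optional leading `id` cell is tolerated) and `NA`/empty
for missing; annotations are BED4 (0-based half-open).

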