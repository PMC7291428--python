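# decon2

Predict circulating immune-cell proportions from bulk blood RNA-seq
(Decon-cell) and decompose bulk cis-eQTL effects into cell-type interaction
(CTi) eQTLs (Decon-eQTL).

## What it does

**Decon-cell** fits per-cell-type elastic-net models on TMM-normalized,
log2-transformed, z-scaled bulk expression against measured cell
proportions. Predictability is assessed by 100 repeated 70/30 train/test
splits (a cell type is *predictable* at mean Spearman R >= 0.5); *signature
genes* are those selected in >= 80% of iterations. Trained models predict
proportions for new cohorts from bulk expression alone.

**Decon-eQTL** models a gene's bulk expression as a proportion-weighted sum
of per-cell-type contributions with genotype interactions,

    y = sum_k beta_k * c_k + sum_k gamma_k * (g_k x c_k) + e,

fit by non-negative least squares with no intercept and no genotype main
effect, on covariate-corrected re-exponentiated expression and proportions
rescaled to sum to 100. Because negative allelic effects would be truncated
at zero, each interaction term may use either dosage orientation (g or 2-g,
at most one term deviating from the rest), giving (2k)+2 model
configurations; the one with the lowest residual sum of squares wins. Each
cell type's interaction is tested by an F test of the full model against the
reduced model without that term (df 1, n-2k), with Benjamini-Hochberg FDR
per cell type.

Also included: a minimal cis-eQTL mapper (MAF >= 0.01, call rate 1, HWE
p >= 1e-4, 250 kb window around the gene center, FDR 0.05 top effects), the
single-cell-type interaction comparator with its sign-restriction rule,
validation statistics (allelic concordance, Fisher and effect-size
comparisons, gene-set enrichment), and a fully seeded synthetic-data
generator with exported ground truth.

## Command line

```bash
# generate a coherent synthetic cohort (TSVs + truth.json + run_config.yaml)
decon2 simulate --config sim.yaml --out simdir/

# run the staged workflow: prep -> cell -> cis -> eqtl -> eval
decon2 run --config simdir/run_config.yaml --out results/

# or run stages individually
decon2 prep --counts expr.tsv --covariates covs.tsv --mode eqtl --out corrected.tsv
decon2 cell train --expr prep.tsv --counts facs.tsv --out models/ --seed 42
decon2 cell crossval --expr prep.tsv --counts facs.tsv --out report.tsv
decon2 cell predict --models models/ --expr prep.tsv --out predicted.tsv
decon2 cis --expr corrected.tsv --geno dosages.tsv --snp-pos snps.tsv \
       --gene-pos genes.tsv --out top_effects.tsv
decon2 eqtl --expr corrected.tsv --geno dosages.tsv --props predicted.tsv \
       --pairs top_effects.tsv --out decon_results.tsv
decon2 westra --expr corrected.tsv --geno dosages.tsv --props predicted.tsv \
       --pairs top_effects.tsv --celltype granulocyte \
       --rule opposite_signs_null --out westra.tsv
decon2 eval concordance --decon directions.tsv --reference purified.tsv
```

All tabular inputs are TSV (first column the row identifier); positions are
1-based inclusive. Every stochastic step takes an explicit seed and reruns
are byte-identical.

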