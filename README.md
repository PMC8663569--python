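# becdistill

Patient stratification and gene-signature distillation from bulk airway
(bronchial-epithelial-cell) transcriptomes.

Severe asthma is heterogeneous: patients with indistinguishable clinical
biomarkers can carry very different epithelial transcriptional programs.
`becdistill` implements, as a tested and reusable pipeline, an analysis
pattern for such cohorts:

1. **Covariate-adjusted differential expression** with empirical-Bayes
   variance moderation (limma-style). Each gene is fitted by OLS; residual
   variances s² are shrunk toward a prior, s̃² = (d₀s₀² + d·s²)/(d₀ + d),
   where (d₀, s₀²) are estimated by matching the first two moments of
   log s² to a scaled log-F distribution. Moderated t/F statistics use
   d₀ + d degrees of freedom; significance is controlled per contrast with
   Benjamini–Hochberg FDR.
2. **Unsupervised patient clustering** on the differential genes:
   k-means (z-scored genes as features) with the cluster number chosen by
   the gap statistic, Gap(k) = E*[log Wₖ] − log Wₖ against uniform
   reference data, using the one-standard-error rule.
3. **Cluster-specific gene calls** under the all-pairwise rule: a gene is
   cluster-c-up only if it is significantly higher in c than in *every*
   other cluster.
4. **Enrichment**: upper-tail hypergeometric over-representation against
   a typed gene-set library (biological-process and TF-target sets), and
   preranked GSEA (weighted Kolmogorov–Smirnov running sum, gene-label
   permutation null, NES = ES / mean |null ES| of matching sign).
5. **Term-overlap networks**: biological processes and TF-target sets are
   linked when their enriched genes overlap more than hypergeometrically
   expected (p < 10⁻⁸); edge communities are found by link-community
   clustering with the partition-density criterion.
6. **Signature distillation**: candidate gene lists from the top-loading
   genes of the leading principal components feed a sparse PLS
   discriminant classifier; the balanced error rate (BER — the mean of
   per-class error rates) is cross-validated over the candidate grid, and
   the final list is picked at the elbow of the LOESS-smoothed
   BER-versus-gene-count curve. The model then classifies an external
   cohort after per-gene re-standardization, which absorbs affine
   platform shifts (e.g. microarray-trained, RNA-seq-applied).
7. **Lung-function modeling**: elastic net,
   (1/2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²), of FEV₁ %predicted on the
   signature genes, with λ chosen by leave-one-out MSE and validated by
   Spearman correlation of LOO predictions against measurement.

Because the real cohorts behind this design are not redistributable, the
package ships a first-class **synthetic-cohort generator** that emulates
their statistical structure — severity classes (HC/MMA/SA), four latent
patient clusters, planted discriminative genes, sex/corticosteroid
covariate effects, gene-set libraries with recoverable overlap structure,
an external platform-shifted validation cohort, and FEV₁ generated as a
sparse linear function of a few genes — together with the ground truth
needed to score every stage for parameter recovery.

## Worked example

```python
from becdistill import (CohortConfig, generate_cohort, generate_external_cohort,
                        severity_de_genes, select_k_gap, kmeans_cluster,
                        cluster_specific_genes, compare_partitions,
                        fit_elastic_net, validate_predictions)
from becdistill.distill import distill_signature, predict_clusters

cfg = CohortConfig(seed=42)                    # 160 participants x 2,000 genes
expr, meta, truth = generate_cohort(cfg)

sev = severity_de_genes(expr, meta)            # HC/MMA/SA, adjusted for sex + CS
sub = expr.subset_genes(sorted(sev.union))
k, curve = select_k_gap(sub, range(1, 9), n_refs=50, seed=42)
assign = kmeans_cluster(sub, k, seed=42)

sets = cluster_specific_genes(expr, assign.labels, meta)
genes = sorted(set().union(*[v["up"] | v["down"] for v in sets.values()]))
model, trace, chosen = distill_signature(expr, assign.labels, genes, seed=42)

ext_expr, ext_meta, ext_truth = generate_external_cohort(truth, cfg)
pred = predict_clusters(model, ext_expr)
conc, ari = compare_partitions(pred.labels, ext_truth.cluster_labels,
                               sample_ids=ext_expr.sample_ids)

en = fit_elastic_net(expr, meta.table["fev1_pct"], genes=model.genes, seed=42)
rho, p = validate_predictions(en, meta.table["fev1_pct"])
```

Output:

```
severity-differential genes: 59 of 2000 tested
gap statistic selects k=4; inertia=6469.4
cluster-specific genes: 99
elbow keeps 29 genes (grid point n_per_pc=3)
external cohort concordance=0.985, ARI=0.958
FEV1 elastic net: 26 genes retained, LOO Spearman rho=0.79 (p=5.7e-35)
```

Reading: the severity contrast finds 59 differential genes; clustering
them recovers the four planted patient groups exactly (the gap statistic
picks k = 4). The distillation stage reduces the 99 cluster-specific
genes to a 29-gene signature whose sparse classifier reassigns an
independent, platform-shifted cohort with 98.5% concordance, and an
elastic net on those genes predicts lung function with leave-one-out
Spearman ρ = 0.79.

## Command line

Every stage is also a `bec-distill` subcommand over TSV/GMT/JSON files:

```bash
bec-distill simulate --out data/ --seed 1
bec-distill cluster  --expr data/expression.tsv --k auto --seed 1 --out run/
bec-distill run-all  --config pipeline.yaml     # full pipeline + manifest
```

`run-all` writes every stage artifact plus `manifest.json` (config hash,
seed, versions, per-stage counts, artifact checksums); reruns with the
same config reproduce the manifest bit for bit.

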