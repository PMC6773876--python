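# pinora

Active-subnetwork-oriented pathway enrichment analysis for
class-comparison omics experiments.

Conventional over-representation analysis (ORA) tests a flat list of
differentially expressed genes (DEGs) against pathway gene sets,
ignoring how those genes interact. pinora instead maps each gene's
significance onto a protein–protein interaction network (PIN), finds
**active subnetworks** — connected subgraphs that predominantly consist
of significantly altered genes, possibly bridged by non-significant
connector nodes — and performs pathway enrichment on those subnetworks.
It then reduces the resulting pathway list by kappa-statistic
clustering and can score each pathway's activity per sample. It is
aimed at anyone analysing a two-group comparison (disease vs control
expression, methylation, proteomics) who has gene-level adjusted p
values and wants interaction-aware pathway results.

## Method in brief

Gene p values become z scores, z_i = Φ⁻¹(1 − p_i). A subnetwork A with
|A| = k genes scores

    z_A = k^{-1/2} Σ_{i∈A} z_i ,      s_A = (z_A − μ_k) / σ_k ,

where μ_k, σ_k are the mean and standard deviation of z_A over 2,000
random k-subsets of PIN nodes (Monte-Carlo calibration). Subnetworks
are found by a greedy seed expansion (default), simulated annealing, or
a genetic algorithm. Per search iteration, subnetworks passing a score
quantile (0.80) and a minimum of 10 significant genes are tested
against every gene set by a one-sided hypergeometric test with the PIN
as the background pool, Bonferroni-adjusted, and aggregated by lowest
adjusted p; over 10 iterations the per-pathway extremes, occurrence
counts and up-/down-regulated genes form the result table. Pathways
are clustered on distance 1 − κ (pairwise Cohen's kappa of input-gene
membership) with the cluster count picked by average silhouette width,
and per-sample pathway scores are means of z-standardized expression
over pathway genes. Details and all defaults: `docs/methods.md`.

## Worked example

Everything runs on synthetic data generated by the package itself — a
300-node PIN with a planted 15-gene significant module and a gene-set
collection in which one 25-gene `TARGET` set contains the module:

```python
from pinora import *
from pinora.enrichment import EnrichmentConfig

spec = FixtureSpec(seed=1)
pin, deg, gene_sets, em = generate_all(spec)
processed = map_to_pin(filter_significant(deg), pin)
zmap = build_zscore_map(processed.p_values)
calib = CalibrationTable(pin=pin, zmap=zmap, seed=1)
subs = greedy_search(pin, zmap, processed.significant_genes,
                     SearchConfig(seed=1), calib)
top = max(subs, key=lambda s: s.score)
print(f"{len(subs)} subnetworks; top: {len(top)} genes, "
      f"{top.n_significant} significant, s_A = {top.score:.2f}")

result = run_active_enrichment(processed, pin, gene_sets,
                               SearchConfig(seed=1),
                               EnrichmentConfig(iterations=10, seed=1))
print(result[["ID", "Fold_Enrichment", "occurrence", "lowest_p"]].to_string(index=False))
```

prints

```
7 subnetworks; top: 15 genes, 15 significant, s_A = 15.78
    ID  Fold_Enrichment  occurrence     lowest_p
TARGET             12.0          10 2.168437e-17
```

The greedy search recovered the planted module exactly (15 of 15
significant genes; its calibrated score of 15.8 means it sits ~16
background standard deviations above a random same-size subnetwork),
and across all 10 iterations only the planted `TARGET` pathway — not
any of the 50 decoy sets — was significantly enriched, at 12-fold
enrichment over its PIN-background expectation.

The same pipeline is available from the shell:

```sh
pinora make-fixtures --out fixtures --seed 1
pinora run --pin fixtures/pin.sif --deg fixtures/deg.tsv \
           --gene-sets fixtures/gene_sets.gmt \
           --expression fixtures/expression.tsv --out results --seed 1
```

which writes `enrichment_results.tsv`, `clusters.tsv`,
`pathway_scores.tsv`, a static `report.html` and a `manifest.json`
echoing the configuration and run counts.

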