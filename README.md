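# telomark

Confounder-adjusted multi-omics screening of telomerase-associated
molecular signatures in tumor cohorts.

Most tumors reactivate telomerase; comparing TERT-expressing (TERT-high)
against TERT-silent (TERT-low) tumors across omics layers is confounded by
age, sex, purity and other clinical covariates. `telomark` implements the
full analysis chain for this comparison on expression, methylation, miRNA,
mutation and copy-number data, together with a synthetic multi-omics cohort
generator with planted ground truth for validating every stage.

## What it computes

**Matching-weight differential screen.** A logistic propensity model
e(x) = P(Z=1 | x) is fit on the clinical confounders (Z = 1 for TERT-high);
each sample receives the matching weight

    w_i = min(e_i, 1 - e_i) / (Z_i e_i + (1 - Z_i)(1 - e_i)),

covariate balance is checked by the weighted standardized difference
(< 10% = balanced), and each feature Y is screened with

    Δ_MW = Σ w_i Z_i Y_i / Σ w_i Z_i  −  Σ w_i (1−Z_i) Y_i / Σ w_i (1−Z_i)

plus a weighted least-squares p-value (BH-FDR corrected) and a conditional
label-permutation test. A feature is significant when FDR q < 0.05 **and**
permutation p < 0.05.

**Co-expression networks.** Unsigned WGCNA-style networks: adjacency
|r|^β, topological overlap, hierarchical module detection with a kME
rescue pass, module eigengenes, intramodular connectivity K, top-5% hub
flags, hub tiers across conditions (strong ≥ 5, median 3–4, weak 1–2), and
a permutation Zsummary preservation statistic (< 2 not preserved, ≥ 10
highly preserved).

**miRNA regulation.** Targets merged as (miRanda ∩ miRDB) ∪ miRtarBase,
multi-hit filtering (≥ 2 up- / ≥ 4 down-regulated miRNAs per gene), PC1
anti-correlation between miRNA sets and their targets, and the miR-17-92
cluster score (mean member log2 expression) tested against groups
(Wilcoxon) and the tumor/normal telomere-length ratio (Pearson).

**Random-forest subtyping.** A mixed-type marker profile is contrasted
with a synthetic dataset drawn from the product of its empirical marginals;
a random forest separating observed from synthetic yields the similarity
S_ij = fraction of trees in which samples i and j share a terminal node,
dissimilarity sqrt(1 − S_ij), PAM clustering into two subtypes (cluster 1 =
higher telomerase-activity score), and Wilcoxon / log-rank / Cox
comparisons between them.

## Worked example

```python
import telomark as tm

cohort = tm.generate_cohort(tm.CohortConfig(seed=7))   # n=200, planted effects
model = tm.MatchingWeightDifferential.from_cohort(
    cohort.layers["mrna"], cohort.clinical)
result = model.fit(n_perm=200, seed=3)
print(result.summary())
```

```
Matching-weight differential screen
===================================
layer: mrna   features: 600   samples: 200
propensity converged: True (4 IRLS iterations)
max post-weighting standardized difference: 3.85% (balanced: True)
significant (q < 0.05, perm p < 0.05): 88
top significant features by |dMW|:
          delta_mw         fdr_q    perm_p      direction
feature
GENE0449 -1.813868  2.466985e-33  0.004975   low-specific
GENE0145 -1.736209  9.083064e-23  0.004975   low-specific
...
```

The cohort plants 60 differential genes at a 1.5 SD shift; the screen calls
88 features significant — the 60 planted genes, the miRNA-cluster-coupled
target genes (genuinely group-dependent by construction), and a handful of
borderline calls — with every confounder balanced below 4% standardized
difference after weighting (49%/42%/33% before).

The same stages run from the shell:

```bash
telomark simulate --outdir cohort --seed 7
telomark run --config pipeline.yaml --outdir results
```

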