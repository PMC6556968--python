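# Methods

## Propensity scores and matching weights

Group membership Z (1 = TERT-high, 0 = TERT-low; direction labels are
always derived from weighted group means, never from a raw sign convention)
is modeled by maximum-likelihood logistic regression on the clinical
confounders, fit by iteratively reweighted least squares (tolerance 1e-8,
at most 100 iterations). Constant covariate columns are dropped (they are
absorbed by the intercept); any remaining rank deficiency is an error that
names the collinear columns. Under complete separation the iteration stops
at the cap and the fitted scores are clipped into [1e-6, 1 − 1e-6] with a
warning, so weighting can still proceed. Fitted scores are always clipped
to that interval.

The matching weight w = min(e, 1−e) / (Ze + (1−Z)(1−e)) targets the
subpopulation where the two groups overlap; with e = 0.5 everywhere all
weights are 1 and every weighted statistic reduces to its unweighted form.
Balance is assessed by the absolute standardized difference
100·|m₁−m₀| / sqrt((s₁²+s₀²)/2), with weighted means and
reliability-weight variances (denominator V₁ − V₂/V₁); below 10% counts as
balanced. Zero pooled variance with unequal means reports +inf.

## Differential screen

Per feature, three quantities: (1) the matching-weight effect Δ_MW
(difference of weighted group means); (2) a weighted least-squares
regression of the feature on intercept + Z with the matching weights as
regression weights, two-sided t-tail p on n − 2 degrees of freedom,
BH-FDR corrected (constant features get p = 1 with a degenerate flag so
feature indices stay aligned across layers); (3) a permutation p-value.
Significance requires q < 0.05 AND permutation p < 0.05, both strict.

The permutation test defaults to conditional randomization: samples are
ranked by fitted propensity score, and labels — carrying their matching
weights with them — are shuffled within consecutive strata of 10. This
preserves the label–covariate structure under the null, which is what keeps
the test calibrated when features themselves depend on the confounders. Two
alternative schemes are selectable and documented in the API: an
unrestricted pair-carrying shuffle (slightly conservative for
confounder-driven features) and a per-shuffle refit of the propensity model
(anti-conservative under confounding: weights refit on randomized labels
collapse toward uniform while the observed estimator carries the true
weight dispersion). Measured null rejection at α = 0.05 over 50 confounded
null cohorts × 100 features: stratified ≈ 0.043–0.046, carry ≈ 0.036–0.043,
refit ≈ 0.074. The add-one estimate (1 + #extreme)/(n_perm + 1) bounds p
away from zero. Degenerate single-group shuffles are resampled.

Robustness follows the resampling design: repeatedly draw more than 30
samples per group, rerun propensity → weights → Δ_MW, and correlate the
resampled effect vector with the full-data one.

## Co-expression networks

Unsigned adjacency a_ij = |Pearson r|^β with zero diagonal. The soft power
is chosen as the smallest candidate whose signed scale-free-topology fit
R² (log10 bin frequency regressed on log10 mean bin connectivity, ten
equal-width bins, sign of −slope) exceeds 0.9, falling back to the largest
candidate with a warning. The synthetic cohorts' planted blocks
(within-module |r| ≈ 0.3) are not globally scale-free, so the planted-truth
analyses fix β = 4: at β ≥ 6 the topological-overlap dendrogram compresses
(all dissimilarities ≈ 1) and the static cut becomes unstable.

Topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
diagonal 1. Modules come from average-linkage clustering of 1 − TOM with a
static cut at a fraction (default 0.995) of the maximum merge height —
a deliberate simplification of the dynamic tree cut — followed by a kME
rescue pass: unassigned genes join the module whose eigengene they
correlate with best when that correlation reaches 0.3 (the analogue of the
dynamic cut's assignment stage; without it weak-loading members stay
unassigned). Clusters below the minimum size are unassigned (label 0);
modules are renumbered by decreasing size, ties by smallest member gene ID.

The module eigengene is the first principal component of the per-gene
z-scored submatrix, scaled to unit variance and oriented to correlate
positively with the module's genes (orientation is deterministic; negating
all genes therefore yields the exact mirror eigengene). Modules whose
eigengene dissimilarity 1 − r falls below 0.25 merge with single-linkage
(chain) semantics. Intramodular connectivity K sums in-module adjacency;
hubs are the ceil(5% × module size) highest-K genes per module (at least
one, ties by gene ID); unassigned genes get whole-network K and are never
hubs. Hub tiers across conditions: hubs in ≥ 5 conditions are strong, 3–4
median, 1–2 weak.

Preservation of reference modules in a test matrix is a permutation Z
composite: density (mean intramodular adjacency in the test network) and
connectivity (correlation of in-module connectivity vectors between the
networks), each Z-scored against random same-size gene sets;
Zsummary = median of the two, read against the 2 / 10 cutoffs. When a
component's permutation null is degenerate (e.g. reference and test are the
same matrix, where every connectivity correlation is exactly 1) that
component is undefined and excluded from the composite.

## miRNA regulation

miRNA names are matched after lower-casing, species-prefix and version
stripping. Database merge: (miRanda ∩ miRDB) ∪ miRtarBase per miRNA.
Multi-hit filter: genes targeted by ≥ 2 up-regulated miRNAs, or ≥ 4
down-regulated ones (the stricter bar reflects that group's larger size).
Set-level coupling uses the first principal component of each per-feature
z-scored set, oriented positively to the set's mean profile. The miR-17-92
score is the plain mean of member log2 expression per sample; group
comparison uses the Wilcoxon rank-sum test (exact when both groups ≤ 10,
normal approximation with tie correction otherwise), and the
telomere-length-ratio association uses Pearson correlation on
pairwise-complete observations.

## Random-forest subtyping

The marker profile stacks, per layer, significant features ranked by
|Δ_MW| (top 20 genes and methylation probes, top 5 miRNAs, mutations and
copy-number genes; all of them with a warning when fewer are available),
plus TERT, the consensus hub genes, and the miR-17-92 members. Missing
marker values are imputed by column median (numeric) or mode (binary)
before synthesis. The synthetic contrast dataset draws every column
independently, with replacement, from its own observed values; a random
forest (2000 trees, sqrt(p) features per split, unlimited depth, leaf size
1) separates observed from synthetic, all observed samples are propagated
down every tree, and S_ij is the fraction of trees in which i and j share
a terminal node; D_ij = sqrt(1 − S_ij), zero diagonal.

PAM: when the medoid search space C(n, k) is at most 50,000 the k-medoids
objective is minimized exactly by enumeration — for k = 2 this covers any
realistic cohort at O(n³) cost and avoids the 1-exchange local optima that
the classic BUILD+SWAP heuristic (including the R reference
implementation) can fall into; larger spaces use greedy BUILD followed by
best-improvement SWAP. Everything is deterministic given the dissimilarity;
only the forest consumes the seed.

The telomerase-activity score is the mean of per-gene z-scored (population
SD) log2 expression over a supplied signature gene list — the simplest
transparent estimator, since the signature source publication specifies
the gene list but not the aggregation. Cluster 1 is, by convention, the
cluster with the higher median score. Subtypes are compared by Wilcoxon on
the score, the two-group log-rank test, and a univariate Cox model
(Breslow tie handling, via lifelines); a constant covariate is an error and
|coefficient| > 15 is flagged as suspected monotone likelihood.

## Synthetic cohorts

The generator emits log2-scale matrices directly. Group labels follow a
logistic model on n standard-normal confounders (default 3, log-odds 0.5
each), so groups are genuinely confounded; 30% of the non-differential,
non-module genes additionally depend on the first confounder (coefficient
0.6), creating the spurious associations the weighting must remove.
Differential features shift by `effect_size` (default 1.5) residual SDs in
the TERT-high group, half up and half down, TERT itself always up.
Methylation is generated on the logit scale and squashed through a sigmoid;
planted probes load negatively on differential genes' expression, making
them anti-correlated and group-differential with the opposite sign.
Mutations are Bernoulli (per-gene base rate 0.05–0.15; differential genes
+0.25 in TERT-high); copy-number calls sit in {−2..2} with planted
amplification in the high group. Hypermutated exomes are produced only by
the MAF writer (filler rows past the 1000-mutation threshold) so matrix
shapes stay aligned.

Modules are factor blocks: gene = λ·latent + sqrt(1−λ²)·noise, hubs at
λ = 0.9, other members λ ~ U(0.4, 0.7); module 1's latent doubles as the
telomerase-activity axis, shifted +1 SD in subtype 1, and the signature
gene list is a 12-gene subset of module 1. The miR-17-92 members (canonical
names at cluster size 6) share a latent that is shifted +0.75 in TERT-high
and couples into designated mRNA targets with coefficient −0.8 and into the
telomere-length ratio; cluster members and targets are therefore genuinely
group-dependent, and recovery metrics count them as true rather than false
discoveries. Two subtypes (fair coin) shift a mixed-type marker panel
(15 genes at 2 SD, 5 methylation probes, 3 mutations, 3 copy-number genes)
and drive exponential survival: subtype 2's event rate is multiplied by the
hazard ratio (default 3), with per-arm exponential censoring whose rate is
chosen so the expected censored fraction equals `censor_rate` in each arm
(censoring stays independent of the event time, keeping the log-rank and
Cox analyses valid).

What the generator does *not* emulate: real marginal distributions, batch
effects, cancer-type heterogeneity, measurement error structure, missing
data, or linked multi-omic copies of the same underlying biology. Passing
tests therefore demonstrate statistical correctness of the machinery under
the assumed model, not performance on real tumor data.

## Problem sizes and numerical choices

Validation experiments use n = 200 samples (100 for subtyping runs),
600-gene expression layers with three 30-gene modules, 200 permutations for
both the label-permutation test and the preservation Z, and 2000 trees for
the subtyping forest — sizes at which every planted structure is
comfortably identifiable while a full validation sweep completes in tens of
seconds. All stage seeds derive deterministically from one top-level seed
(CRC-based stream splitting), so a pipeline rerun is byte-identical.
Strict inequalities are used at every printed threshold (expression filter
mean > 1, mutation count < 1000, FDR and permutation cutoffs); the mutation
frequency filter is inclusive (≥ 5%). Silent/non-coding MAF rows are
excluded from both mutation thresholds by default (configurable), a choice
the source text leaves open.

## Known limitations

The static-cut module detection is a simplification of dynamicTreeCut and
depends on β through the dendrogram's height scale. The preservation
Zsummary aggregates two statistics rather than WGCNA's full set, and with
moderate factor loadings planted modules score near the "highly preserved"
boundary (Zsummary ≈ 10–25). The propensity model assumes the confounders
enter linearly; a misspecified model leaves residual imbalance the balance
report will reveal but the screen will not correct. The subtyping chain
recovers subtypes only insofar as the marker profile carries
subtype-informative columns; markers selected purely for group specificity
need not separate subtypes.
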