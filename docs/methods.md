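# Methods

This note documents the statistical machinery implemented in
`becdistill`, the choices made where the design was genuinely open, and
what the synthetic-cohort tests do and do not establish about real data.

## Moderated differential expression (`becdistill.diffexpr`)

Every gene g is fitted with the same linear model y_g = Xβ_g + ε,
ε ~ N(0, σ_g²I), where X contains the class or cluster structure plus
covariates (sex coded M = 1, ordinal inhaled-corticosteroid dose 0–4,
binary oral-corticosteroid use). Group structure enters as cell-means
indicators so arbitrary between-group contrasts are directly
expressible. Residual variances are moderated by empirical Bayes:
writing z_g = log s_g² and d for the residual degrees of freedom, the
prior (d₀, s₀²) solves the moment equations of a scaled log-F
distribution — trigamma(d₀/2) = Var(e) − trigamma(d/2) with
e_g = z_g − digamma(d/2) + log(d/2) — and the posterior variance is
s̃_g² = (d₀s₀² + d·s_g²)/(d₀ + d). Moderated t and omnibus moderated F
statistics use d₀ + d degrees of freedom. When the observed variances
are underdispersed relative to pure chi-square noise, d₀ = ∞ and all
genes share s₀². Genes with exactly zero residual variance are assigned
the smallest positive residual variance so t stays finite. On a frozen
12-sample fixture the implementation agrees with the reference
empirical-Bayes implementation in R to 14 decimal places (prior df,
coefficients, t, p); that check is baked into the test suite as frozen
constants.

Two gene-call rules sit on top of the fits:

* **Severity genes** — an omnibus moderated F over the class effects
  gates significance (p < α and BH q < α, α = 0.05); a gated gene joins
  a class's up/down set when its one-vs-rest contrast is itself
  significant, with direction from the contrast sign. Sign alone (the
  laxest reading of "assign by contrast sign") would place every gated
  gene in all three class sets and collapse the three-set Venn, so
  per-class membership also requires per-class significance.
* **Cluster-specific genes** — cluster-c-up requires q < 0.05,
  p < 0.05 and a positive estimate in *all* contrasts c − c′. This
  all-pairwise rule deliberately excludes genes elevated in two
  clusters at once.

BH-FDR is applied within each contrast separately, matching per-analysis
FDR semantics. The hand-rolled step-up is cross-checked against
`statsmodels.multipletests` on a thousand random vectors.

## Clustering (`becdistill.cluster`)

Samples are observations; genes are z-scored before the Euclidean
metric so high-variance transcripts do not dominate (whether the
original analyses standardized is not documented; standardizing is the
defensible default). k-means uses k-means++ initialization, best of 25
starts, 300 Lloyd iterations, tolerance 1e-6. The gap statistic
compares log Wₖ to its expectation under 50 reference datasets drawn
uniformly over each feature's observed range; k* is the smallest k with
Gap(k) ≥ Gap(k+1) − se(k+1). Partition agreement is reported two ways:
the adjusted Rand index, and "concordance" — the agreeing fraction
under the optimal label bijection found by the Hungarian algorithm on
the k×k contingency table (with unequal label counts the smaller side
is matched and unmatched labels count as disagreement).

## Enrichment (`becdistill.enrich`)

Over-representation is the upper-tail hypergeometric test against a
universe fixed to all genes tested for differential expression; gene
sets are intersected with the universe first. The implementation is
validated against exhaustive enumeration of every possible query draw
for universes up to 12 genes (agreement to 1e-12).

Preranked GSEA sorts genes by a score (the pipeline uses the moderated
t of cluster-vs-rest; the original analyses do not document their
ranking statistic), then walks the list adding |score|^p normalized by
the in-set total at hits and subtracting 1/(N − N_hit) at misses; ES is
the signed maximum deviation (ties between positive and negative
excursions resolve positive). The null is gene-label permutation
(n = 1000 by default); NES divides ES by the mean |null ES| of matching
sign and p is the matching-sign tail fraction with a +1 pseudocount.
Null permutations are computed with a closed form for the running-sum
value at and before each hit (the walk's extrema can occur nowhere
else), which matches the naive O(N) trace to 1e-12 and makes a
thousand permutations cheap. Effective set-size bounds are 5–500.

## Term-overlap networks (`becdistill.network`)

Nodes are enriched biological-process and TF-target terms; the gene
membership used for overlap testing is each term's *enriched* genes
(query ∩ set), per the interpretation that edges represent overlap in
enriched genes rather than full set membership. Every term pair is
tested (BP–BP, BP–TFT, TFT–TFT) with the upper-tail hypergeometric
against the enrichment universe; edges require p < 10⁻⁸ and carry
−log₁₀ p as weight. Link communities follow the edge-clustering
construction: edges sharing node k are scored by the Jaccard index of
the inclusive neighborhoods of their non-shared endpoints; edges are
single-linkage clustered (non-adjacent pairs at similarity 0) and the
dendrogram is cut at the height maximizing the partition density
D = (2/M) Σ_c m_c (m_c − (n_c−1)) / ((n_c−2)(n_c−1)), communities on
two nodes contributing zero. Cuts are swept over all merge heights;
ties resolve to the finest partition, and single-linkage components at
a threshold are merge-order invariant, so the result is deterministic.

## Signature distillation (`becdistill.distill`)

PCA runs on the gene-standardized clustering-gene submatrix (running it
on the full p ≫ n matrix would bury a small planted signal under
Marchenko–Pastur noise eigenvalues, which is why candidate selection
starts from the genes already implicated by differential expression).
Component signs are fixed so the largest-|loading| entry is positive.
Candidate lists are unions of the top-n genes per component over the
components covering 80% of variance (capped at 10), for n = 1…25.

The classifier is sparse PLS-DA: classes one-hot encoded, each
component's weight vector the dominant singular vector of the deflated
X'Y cross-covariance, optionally soft-thresholded to a per-component
keep count, unit-normalized, with X and Y deflated by the regression
loadings. Components default to (number of classes − 1). Prediction
projects standardized data through W(P'W)⁻¹ and assigns the class with
the largest predicted score ("max.dist"); a class-centroid distance rule
is available as an option. For cross-cohort prediction the new cohort
is z-scored with *its own* per-gene statistics, which cancels affine
platform differences; within-cohort cross-validation uses the training
fold's statistics.

Model quality is the balanced error rate (mean of per-class error
rates) under stratified 5-fold cross-validation repeated 10 times. The
candidate size is chosen at the elbow of the LOESS-smoothed (span 0.75)
BER-versus-gene-count curve: the inflection is the first sign change of
the second differences of the fitted values (falling back to the
curvature peak when the second difference never crosses zero, and to
the global minimum with a warning when the curve is flat); among grid
points at or after the inflection within tolerance (default: the BER SD
at the inflection) of the post-inflection minimum, the smallest gene
count wins. Grid points mapping to the same effective gene list are
collapsed before smoothing.

A consequence worth knowing: when several discriminative genes carry
the same cluster pattern, the BER curve saturates before all of them
are included, and the elbow — by design — stops at the smaller list.
The selected signatures on synthetic cohorts are almost entirely
composed of planted genes, but they are minimal rather than exhaustive.

## Lung-function model (`becdistill.fev1`)

Elastic net on z-scored signature-gene expression with the objective
(1/2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²), α = 0.5 by default (the
L1/L2 mix is not documented in the source analyses; α = 1 and α = 0 are
covered by tests). The coordinate-descent solver is scikit-learn's
`enet_path`, whose objective matches this parameterization exactly. The
λ grid is 100 log-spaced values from λ_max (the smallest λ zeroing all
coefficients) down by 10⁻⁴; λ is chosen at the minimum leave-one-out
MSE, each fold standardized on its own training samples, and the
per-sample LOO predictions are retained for validation. Validation is
Spearman (tie-averaged ranks, two-sided t-approximation p) of LOO
predictions against measured FEV₁, plus per-gene marginal Spearman
checks that each retained coefficient's sign matches the raw
expression–FEV₁ association.

## Signature scores (`becdistill.scores`)

Composite scores are the arithmetic mean of log2 expression or the
geometric mean on the linear scale; the two coincide
(GM(2^x) = 2^mean(x)), and the pipeline default is the geometric mean,
which is well defined because expression is floored above zero. A
Spearman helper correlates scores with scores or single genes.

## The synthetic-cohort generator (`becdistill.cohort`)

The generator emulates a bronchial-brushing cohort: 160 participants,
2,000 genes, log2 intensities with per-gene baselines N(7, 1.5), unit
log2 noise, floored at 2.0 (the background/negative-control level, set
below the expressed range so planted effects are never censored). Four
equal latent clusters carry 25 discriminative genes each, shifted ±1.5
log2 units in their cluster. Severity maps noisily onto clusters
(cluster 1 → HC, cluster 4 → SA, middle → MMA, 15% confusion) — the
classes are enriched for, not identical to, clusters, so
severity-contrast power for middle-cluster genes is deliberately
diluted, as in real cohorts where MMA spans several molecular groups.
Sex is Bernoulli(0.5); OCS use concentrates in the severe cluster (0.6
vs 0.05); ICS dose is ordinal 0–4, rising with severity but overlapping
between classes (a class-deterministic dose would be collinear with the
class indicators and artificially destroy contrast power). Fifty
covariate-responsive genes (half sex, half OCS, +1.0 log2 when active)
are disjoint from the discriminative genes. FEV₁ %predicted is
85 − 15·[severe cluster] + Σ β_g z(x_g) + N(0, 8.6), with five planted
coefficients (±6.3…±4.65, i.e. standardized effects ≈ 0.31–0.42,
explaining ≈ 70% of variance) placed on discriminative genes of the
severe and T2-like clusters. The gene-set library seeds one
biological-process set per cluster with that cluster's up-genes (padded
to 50), one TF-target set sharing 20 members with it (so network edges
are analytically recoverable), and ten random null sets. The external
cohort redraws 65 samples from the same archetypes through an affine
platform shift (scale 1.1, offset −0.5) with fresh noise. One integer
seed drives everything through fixed sub-streams.

What passing on this generator does *not* show: robustness to
count-based RNA-seq noise, batch effects, probe-level artifacts,
missing values, non-affine platform distortions, or correlated gene
modules beyond the planted block structure. The log-scale Gaussian
model is sufficient to exercise the pipeline's contracts, not to
benchmark it against real-data pathologies.

## Numerical and degenerate-input choices

* Cyclic loess: span 0.7, up to 3 cycles, convergence at max shift
  < 1e-3, lowess fit subsampled to 5,000 genes with interpolation to
  the rest. The default "fast" variant adjusts each sample against the
  mean array (O(n) fits per cycle); the classical pairwise sweep is
  available (`method="pairwise"`) and satisfies the same contracts, at
  O(n²) fits per cycle. Missing values are rejected.
* Constant genes: z-scoring maps them to zero (never NaN); Spearman on
  constant input returns NaN with a warning; constant genes among
  elastic-net validations are flagged `defined=False`.
* Trigamma inversion for the variance prior is Newton iteration with
  the standard large/small-argument guards.
* Permutation p-values carry a +1 pseudocount; empty matching-sign
  nulls give p = 1 and NES = NaN.
* All k-means/CV/permutation seeds are required or defaulted
  explicitly; the pipeline fans one top-level seed out to stages by
  fixed offsets, and manifests record config hash and artifact
  checksums so reruns are verifiably identical.

## Problem sizes used by the test and acceptance runs

Unit tests run on 60 × 300 cohorts; recovery and acceptance checks use
the default 160 × 2,000 conditions with 20-seed repetitions where a
distributional claim is made, 1,000 GSEA permutations, and 50 gap
references — sizes chosen so the full suite exercises the same code
paths as a real cohort while remaining comfortable on a laptop.

## Known limitations

* The severity-gene Venn partition depends on the one-vs-rest
  membership rule documented above; other reasonable readings (pairwise
  contrasts, sign-only assignment) would shift the partition counts.
* The elbow rule favors parsimony; see the distillation section.
* GO-graph-aware enrichment (parent-child elimination) and phenotype
  permutation GSEA are out of scope.
* Gene identifiers are opaque strings; no probe/symbol mapping or
  cross-platform ID translation is attempted.
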