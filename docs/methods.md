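# Methods

This note documents the models, numerical choices and known limitations of
`tissuemod`. It describes what the code computes and why the open design
choices were resolved the way they were; every empirical statement here is
checked by the test suite or recomputed by `scripts/acceptance.py`.

## Bulk coexpression network

Input is a genes x samples matrix tagged `counts`, `tpm` or `log`; network
construction requires complete data (no missing values) — pairwise-complete
correlation is deliberately unsupported, as tissue RNA-seq matrices are
complete after quantification.

**Filtering.** Genes with zero counts in strictly more than half of the
samples are removed; survivors are transformed `log(x + pseudocount)`.
The pseudocount defaults to 1 and the log is natural; both are conventions
of this package (any fixed positive pseudocount only shifts low-expression
values, and the base cancels out of Pearson correlations).

**Adjacency and TOM.** The signed adjacency `a_ij = ((1+r_ij)/2)^beta` maps
r = −1 to 0, r = 0 to 2^−beta and r = +1 to 1, so anticorrelated genes are
disconnected rather than connected as in an unsigned network. The soft power
beta is chosen by the scale-free topology scan: for each candidate power the
whole-network connectivity `k_i = sum_{j != i} a_ij` is computed, log10(k)
is split into 10 equal-width bins, and log10(bin frequency) is regressed on
log10(mean k); the signed fit index is −sign(slope)·R². The smallest power
reaching 0.8 is chosen (argmax otherwise), and an explicit override — e.g.
the conventional beta = 9 for signed tissue networks — always wins. The
topological overlap matrix divides shared-neighbour adjacency by
`min(k_i, k_j) + 1 − a_ij`; an exact triple-loop oracle in the test suite
pins the implementation to 1e−12.

**Module detection.** Average linkage on `1 − TOM` is the clustering
substrate. Flat clusters below the minimum module size (default 30 genes)
are left unassigned (label 0); surviving modules are labelled M1..MK by
decreasing size.

The tree-cut rule is the one genuinely open design in this stage, and it is
chosen from the geometry of the dendrogram rather than as a fixed height or
quantile. With a signed TOM, background genes attach to module clusters at
*lower* heights than they merge with each other — the `min(k)` denominator
inflates the overlap between a low-connectivity background gene and a
high-connectivity module gene — so any fixed-quantile cut either truncates
modules or chains noise onto them, and measured planted-module recovery never
exceeds Jaccard ≈ 0.84. Instead, the merges are replayed bottom-up while
counting flat clusters of at least the minimum size; among the height
intervals attaining the maximal count, the *widest* is selected (modules are
complete, chaining has not started) and the cut placed at its midpoint. If
the widest such gap is no wider than 10x the mean merge spacing, the
"modules" exist only by quasi-continuous chaining and nothing is assigned.
This rule is deterministic, parameter-free given the minimum size, and
recovers planted modules exactly (Jaccard 1.0 at 200 samples, 50-gene
modules, loading 1, noise sd 0.5). A quantile cut remains available as an
explicit `cut_quantile` argument for users who want the fixed-height
behaviour.

**Eigengenes.** Each gene of a module is standardized across samples (mean
0, sd 1 with the n−1 denominator); the eigengene is the unit-norm first
right singular vector over samples of this standardized submatrix — i.e. the
first principal component of the module — with variance explained
`sigma_1² / sum sigma²`. Standardized (not raw log) expression is used so
that highly expressed genes do not dominate the component. The sign is fixed
by requiring non-negative correlation with the module's mean standardized
expression ("align along average"); projection and all trait statistics
depend on this convention, so it is part of the contract. Modules whose
eigengene dissimilarity `1 − cor` falls below the merge cut (default 0.1)
are merged greedily closest-pair-first, recomputing eigengenes after each
merge until a fixed point.

## Cohort statistics

**Correlation.** `pearson_with_p` uses the Student-t transform
`t = r sqrt(n−2)/sqrt(1−r²)` with a two-sided tail; |r| = 1 returns p = 0.
The module x trait grid is BH-adjusted as one family (flagged at FDR < 0.05);
the paired inflamed/uninflamed comparison is a two-sided paired t-test per
module, BH-adjusted across modules, with per-pair differences exported.

**Projection.** Module definitions travel as gene sets; on a replication
matrix, each set is restricted to mapped genes (coverage = mapped/defined is
reported; below 50% a warning is logged; below 2 genes the module is
skipped) and the eigengene is recomputed with the same standardization and
sign convention. Projection onto the defining data reproduces the original
eigengenes to 1e−10.

**Response testing.** Pretreatment eigengenes are compared between
responders and nonresponders with a two-sided Mann–Whitney U test: exact by
enumeration when the smaller group has ≤ 8 samples and no ties, otherwise
the normal approximation with tie and continuity corrections (the switch
point is a convention of this package). BH adjustment is across modules
within a dataset (and within regimen when regimen labels are supplied —
multi-regimen designs are handled as per-regimen two-group tests; no omnibus
ANOVA is computed). The reported direction is the sign of (mean nonresponder
− mean responder).

**Meta-analysis.** Per-study effects are exact Hedges-g estimates:
`d = (mean_A − mean_B)/s_pooled`, `J(m) = Gamma(m/2)/(sqrt(m/2) Gamma((m−1)/2))`
with m the pooled degrees of freedom, `g = J d`, and
`v = (n_A+n_B)/(n_A n_B) + g²/(2(n_A+n_B))`. Pooling is DerSimonian–Laird:
method-of-moments tau² truncated at zero, random-effects weights
`1/(v_i + tau²)`, a 95% normal (1.96) confidence interval and a two-sided
normal p-value. The Knapp–Hartung small-k adjustment is not applied; at k = 3
homogeneous studies the measured coverage of the 95% CI is ~96%, within the
expected band for this estimator.

**Per-gene AUROC.** In a univariate logistic model the fitted predictions
are a monotone function of the predictor, so the AUC of the predictions
equals the AUC of the predictor oriented by the fitted slope's sign — which,
for the univariate model with intercept, equals the sign of the case/control
mean difference. The implementation therefore computes
`(wins + 0.5·ties)/(n1·n0)` on the oriented gene without fitting anything;
the test suite verifies equality against actual logistic fits. Constant
genes get AUC 0.5 by convention. Per-study ranks are 1..n by descending AUC
with ties broken by gene identifier; combined ranks are sums of per-study
ranks over the shared gene universe (re-ranked within the intersection so
each summand is a permutation of 1..n), and per-module combined-rank
distributions are compared pairwise by Mann–Whitney with BH adjustment.

**Patient grouping.** Selected module eigengenes are standardized per column
and patients clustered with Ward linkage on Euclidean distance, cut into k
groups. Each group is annotated high/low per module by comparing the group
mean to the overall mean — a threshold-free rule that reproduces
"M4/M5-high"-style labels. Percentages are rounded to one decimal (sizes
5/6/6/6 of 23 give 21.7/26.1/26.1/26.1).

## Single-cell arm

QC thresholds are strict inequalities exactly as stated: a cell is removed
if it has *fewer than* 500 detected genes or *more than* 20% mitochondrial
counts; cells exactly at either threshold are retained. Normalization is the
exact per-cell formula `y_gi = log(1 + 1e4 · UMI_gi / total_i)` (natural
log) applied to nonzero entries only, so sparsity and zeros are preserved
and the result is depth-invariant. Gene-set scores sum per-gene z-scores of
normalized expression across *all* cells (sd with n−1); absent and
zero-variance genes are dropped and counted. Scores are exactly centered
(sum zero over cells) and linear in the set. Pseudobulk sums raw UMIs per
(donor, cluster), conserving totals exactly.

**Trajectory.** Clustering and the 2-D embedding are inputs, not
computations. The principal curve is Hastie–Stuetzle: initialize at the
first principal-component line, then alternate orthogonal projection onto
the current polyline, per-coordinate smoothing against arc length, and
arc-length reparameterization. The smoother is local-linear with tricube
weights over a fixed span (default 0.5 of the points) — a simpler stand-in
for the smoothing-spline smoother of the classical formulation; the
behaviour contract is rank-correlation recovery of the generating parameter,
not vertex-for-vertex equality with any other implementation. A smoothing
step is accepted only if it does not increase the total squared projection
distance, making the per-iteration error sequence non-increasing by
construction; iteration stops at relative improvement < 1e−4 or 30
iterations. Arc-length positions are scaled to [0, 100]. The curve is
direction-blind; when cluster labels are supplied, pseudotime is oriented so
the first cluster (category order) sits at the low end. Pseudotime is
discretized into equal-cell-count ("uniform-density") windows — any
remainder goes to the earliest windows, so window sizes differ by at most
one cell — and per-cluster window densities and modal positions are
reported. Principal curves inherit the usual caveat that recovery degrades
when the embedding's across-trajectory variance rivals the along-trajectory
variance (the PC initialization then starts orthogonal to the signal).

## Synthetic data

The generators exist to give every stage planted ground truth.

* **Bulk cohort** (default 200 samples x 2,000 genes, ten 50-gene modules,
  ~25% of genes in modules): gene g of module m follows
  `exp(base_g + loading_g · F_m + noise)` with `F_m ~ N(0,1)` per sample,
  `base_g ~ N(2,1)`, `loading_g ~ N(1, 0.1)` and noise sd 0.5 — on the log
  scale, a one-factor model per module whose eigengene is recoverable at
  r > 0.99. A Poisson layer converts the continuous (TPM-like) matrix to
  integer counts behind a flag, since replication cohorts mix array and
  count data. The continuous inflammation trait is a linear combination of
  module factors plus N(0, 0.5) noise.
* **Response cohorts**: same gene universe and module structure, loadings
  and factors redrawn per study; nonresponders' latent factors are shifted
  by the planted SMD (latent sd is 1); each study retains
  `floor(overlap · n_genes)` randomly chosen genes, emulating platform
  differences (defaults: 3 studies, 50/50 groups, SMD 0.87 on one module,
  90% overlap).
* **Single cells** (default 3,000 cells x 1,000 genes, 4 clusters, 3
  donors): per-cell library sizes are lognormal (mu 8, sigma 0.3 — a few
  thousand UMIs); counts are multinomial over gene proportions built from
  lognormal base weights, per-cluster marker-gene blocks (logFC 1), a
  gradient-gene block tilted by the cell's latent trajectory position in
  [0, 1], and mitochondrial genes renormalized to a per-cell target
  fraction (mean 5%, sd 2%). Trajectory clusters are laid end to end along
  the position axis, and a gentle parabolic 2-D embedding of the position
  (plus isotropic noise) stands in for a reduced-dimension embedding.

Randomness discipline: one root seed, with each sub-draw taken from a named
child stream (seed sequence keyed by a CRC of the stream name), so adding a
feature never shifts existing draws; identical parameters give bitwise
identical output.

What the generators do *not* emulate: real pathway content or gene-gene
causal structure, batch and ambient-RNA artifacts, doublets, zero inflation
beyond the multinomial, between-donor expression shifts, or heavy-tailed
library-size outliers. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated generative models,
not robustness to every artifact of real tissue data.

## Pipeline and formats

Stages (simulate → filter → network → modules → eigengenes → traits →
project → response → meta → aucrank → scscore → trajectory) each read their
inputs from the output directory and write their tables back to it, so any
stage can be re-run from on-disk intermediates; a missing upstream artifact
raises an error naming the stage and file. Dense matrices travel as TSV with
a version-stamped header comment, sparse counts as a Matrix Market triplet
directory (features x barcodes with `features.tsv`/`barcodes.tsv`), gene
sets as GMT (members deduplicated, duplicate set names rejected), and the
manifest as JSON with per-stage SHA-256 output checksums. On reading
expression tables, duplicate gene rows are summed (the standard treatment of
multiple probes per symbol) with a logged warning; duplicate sample columns,
missing values and non-numeric cells are errors with row/column context.
Floats are parsed with round-trip precision so write∘read is bitwise.

## Problem sizes

Simulation-heavy checks run at desk scale chosen to keep the full suite
fast while leaving the statistical conclusions meaningful: module recovery
at 200 samples with two 50-gene planted modules over 10 seeds; calibration
of the response test with 2,000 null and 500 powered replicates on
four-module, 80-gene cohorts; meta-analysis coverage with 500 three-study
replicates; trajectory recovery on 500-point arcs. The acceptance script
re-runs the discovery pipeline at the full 200 x 2,000 default.

## Known limitations

* No block-wise network construction: matrices are dense, so gene counts
  beyond ~30k will exhaust memory.
* Bicor/Spearman networks, signed-TOM variants and dynamic hybrid tree
  cutting are not implemented; the gap cut above is this package's own
  detection rule.
* The meta-analysis offers only DerSimonian–Laird with a normal CI.
* The trajectory smoother is local-linear, not a smoothing spline, and the
  principal curve is fit in 2-D only.
* Cluster labels and embeddings for single-cell data are consumed, never
  computed (no graph clustering, no batch integration).
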