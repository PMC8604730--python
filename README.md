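# tissuemod

Inflamed tissue — in inflammatory bowel disease (IBD) and beyond — is not one
thing: different patients carry different tissular configurations of
inflammation ("pathotypes"), and those configurations predict who will fail
which therapy. `tissuemod` is a Python package for the transcriptomic side of
that analysis. From bulk expression data it discovers coexpressed gene
modules, summarizes each module per sample as an eigengene, relates module
expression to histology and to therapy nonresponse across cohorts, and scores
the same modules in single-cell data along a differentiation trajectory.
It is aimed at computational biologists analysing bulk + single-cell tissue
cohorts, and it ships synthetic-data generators with known planted structure
so every stage can be validated without access to patient data.

## What it computes

**Coexpression modules (signed WGCNA-style network).** Genes with zero counts
in more than half of the samples are removed and expression is
log-transformed with a pseudocount. Pairwise Pearson correlations `r_ij`
give a signed adjacency

    a_ij = ((1 + r_ij) / 2) ** beta

(`beta` chosen by a scale-free-topology scan, or fixed, e.g. 9), from which
the topological overlap matrix is built:

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

Average-linkage clustering of `1 − TOM` with a minimum module size (default
30) yields modules M1..MK; modules whose eigengenes are nearly identical
(dissimilarity `1 − cor` below a merge cut, default 0.1) are merged. The
**module eigengene** is the first principal component of the gene-standardized
module submatrix, sign-aligned with mean module expression.

**Cohort statistics.** Module–trait association uses Pearson correlation with
the Student-t p-value `t = r sqrt(n−2)/sqrt(1−r²)` and Benjamini–Hochberg
adjustment; paired inflamed/uninflamed tissue is compared with a paired
t-test. Module definitions project onto replication cohorts by gene-symbol
mapping (with per-module coverage reporting), responder/nonresponder
differences use two-sided Mann–Whitney U tests, and per-study effects are
pooled as exact Hedges-g standardized mean differences under a
DerSimonian–Laird random-effects meta-analysis. Per-gene predictive power for
nonresponse is the AUROC of a univariate logistic model (computed rank-wise
via the monotone-link equivalence), combined across studies by rank sums.
Patients are grouped by Ward clustering of selected module eigengenes.

**Single-cell arm.** QC removes droplets with <500 detected genes or >20%
mitochondrial reads; normalization is `log(1 + 1e4 · UMI_gi / Σ_h UMI_hi)`;
a module's per-cell score is the sum of per-gene z-scores of normalized
expression; pseudobulk sums UMIs per (donor, cluster); a Hastie–Stuetzle
principal curve on a 2-D embedding yields pseudotime in [0, 100], summarized
over 100 equal-cell-count windows.

## Worked example

```python
import tissuemod as tm

# a 200-sample x 2,000-gene cohort with ten planted 50-gene modules
params = tm.BulkSimParams(seed=0)
expr, traits, truth, latent = tm.simulate_bulk_cohort(params)

logged = tm.filter_and_log(expr)                       # zero filter + log1p
tom = tm.tom_similarity(tm.signed_adjacency(logged, beta=9))
modules = tm.merge_close_modules(
    logged, tm.detect_modules(tom, min_module_size=30), merge_cut=0.1)
eig = tm.compute_eigengenes(logged, modules)
corr = tm.correlate_eigengenes_with_traits(eig, traits)

print(modules.module_sizes())
print(corr.sort_values("fdr").head(1)[["module", "trait", "r", "fdr"]])
```

prints

```
{1: 50, 2: 50, 3: 50, 4: 50, 5: 50, 6: 50, 7: 50, 8: 50, 9: 50, 10: 50}
  module         trait         r           fdr
0     M1  inflammation  0.899499  3.968633e-72
```

— all ten planted modules are recovered at their exact sizes, and the module
whose latent factor drives the simulated inflammation trait shows the
strongest eigengene–trait correlation (r ≈ 0.9, the planted signal-to-noise
ceiling at trait noise sd 0.5).

The same stages run from the shell:

```bash
tissuemod simulate --preset bulk --seed 0 --out run/
tissuemod all --config config.yaml        # simulate ... trajectory end to end
```

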