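"""Cohort-level statistics for module eigengenes.

Covers module-trait Pearson correlations with Student-t p-values and
Benjamini–Hochberg adjustment, paired inflamed/uninflamed eigengene tests,
projection of module definitions onto replication cohorts, Mann–Whitney
responder/nonresponder tests, Hedges-g effect sizes pooled under a
DerSimonian–Laird random-effects meta-analysis, per-gene predictive AUROC
ranking with cross-study combined ranks, and hierarchical grouping of
patients on selected modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .network import (
    DataError,
    Eigengenes,
    ExpressionMatrix,
    ParameterError,
    eigengene_from_submatrix,
)
from .simulate import ResponseDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """Pearson correlation with a Student-t p-value."""

    r: float
    n: int
    t_statistic: float
    p: float
    fdr: float = float("nan")


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with the Student-t p-value ``t = r sqrt(n-2)/sqrt(1-r^2)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise DataError("correlation undefined for a constant vector")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        return CorrelationResult(r=r, n=n, t_statistic=float("inf") * np.sign(r), p=0.0)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r=r, n=n, t_statistic=float(t), p=float(p))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clamped to 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_eigengenes_with_traits(
    eigengenes: Eigengenes,
    traits: pd.DataFrame,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """All module x numeric-trait Pearson correlations, BH across the grid.

    Samples are aligned on index; non-numeric trait columns are ignored.
    Returns a long table with columns module, trait, r, n, t, p, fdr,
    significant.
    """
    numeric = traits.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise ParameterError("trait table has no numeric columns")
    shared = eigengenes.scores.index.intersection(numeric.index)
    if len(shared) < 3:
        raise DataError("fewer than 3 overlapping samples between eigengenes and traits")
    eg = eigengenes.scores.loc[shared]
    tr = numeric.loc[shared]
    rows = []
    for module in eg.columns:
        for trait in tr.columns:
            res = pearson_with_p(eg[module].to_numpy(), tr[trait].to_numpy())
            rows.append({"module": module, "trait": trait, "r": res.r, "n": res.n,
                         "t": res.t_statistic, "p": res.p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_level
    return out


def paired_eigengene_test(
    eigengenes: Eigengenes,
    pairing: pd.Series,
    condition: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired t-test of eigengenes between matched tissue conditions.

    ``pairing`` maps sample id -> pair id (each pair id on exactly two
    samples); ``condition`` is a two-level label (e.g. inflamed /
    noninflamed).  Per module the two-sided paired t-test is computed on
    per-pair differences (first condition level, sorted, minus second — so
    "inflamed" minus "noninflamed" under the default lexicographic order);
    p-values are BH-adjusted across modules.

    Returns ``(per-module table, per-pair difference table)``.
    """
    levels = sorted(condition.dropna().unique())
    if len(levels) != 2:
        raise ParameterError("condition must have exactly two levels")
    pairs = {}
    for sample, pid in pairing.dropna().items():
        pairs.setdefault(pid, []).append(sample)
    complete = {
        pid: ss for pid, ss in pairs.items()
        if len(ss) == 2 and {condition[ss[0]], condition[ss[1]]} == set(levels)
    }
    if len(complete) < 2:
        raise DataError("need at least 2 complete pairs")
    diffs = {}
    for pid, (a, b) in sorted(complete.items()):
        hi = a if condition[a] == levels[0] else b
        lo = b if hi == a else a
        diffs[pid] = eigengenes.scores.loc[hi] - eigengenes.scores.loc[lo]
    diff_table = pd.DataFrame(diffs).T  # pairs x modules
    rows = []
    for module in diff_table.columns:
        d = diff_table[module].to_numpy()
        if d.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if d.mean() == 0 else (np.inf * np.sign(d.mean()), 0.0)
        else:
            t, p = sps.ttest_1samp(d, 0.0)
        rows.append({"module": module, "mean_difference": float(d.mean()),
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out, diff_table


# ---------------------------------------------------------------------------
# projection onto replication cohorts
# ---------------------------------------------------------------------------


def project_modules(
    module_sets: Mapping[str, Sequence[str]],
    expr_new: ExpressionMatrix,
    min_coverage_warn: float = 0.5,
) -> tuple[Eigengenes, pd.DataFrame]:
    """Recompute module eigengenes on a replication expression matrix.

    Genes of each module definition are mapped by identifier into the new
    matrix; eigengenes use the same standardization and sign convention as
    on the defining cohort.  Modules with fewer than 2 mapped genes are
    skipped with a logged reason.  Returns ``(eigengenes, coverage report)``
    where the report lists n_defined / n_mapped / fraction_mapped per module.
    """
    if expr_new.scale != "log":
        raise ParameterError("projection expects a log-scale matrix")
    index = {g: i for i, g in enumerate(expr_new.gene_ids)}
    cols, ve, cov = {}, {}, []
    for name, genes in module_sets.items():
        mapped = [g for g in genes if g in index]
        frac = len(mapped) / len(genes) if genes else 0.0
        cov.append({"module": name, "n_defined": len(genes),
                    "n_mapped": len(mapped), "fraction_mapped": frac})
        if len(mapped) < 2:
            logger.warning("module %s skipped: only %d of %d genes mapped",
                           name, len(mapped), len(genes))
            continue
        if frac < min_coverage_warn:
            logger.warning("module %s: only %.0f%% of genes mapped", name, 100 * frac)
        rows = [index[g] for g in mapped]
        e, v = eigengene_from_submatrix(expr_new.values[rows])
        cols[name] = e
        ve[name] = v
    if not cols:
        raise DataError("no module could be projected (fewer than 2 mapped genes each)")
    eig = Eigengenes(
        scores=pd.DataFrame(cols, index=expr_new.sample_ids),
        variance_explained=pd.Series(ve, dtype=float),
    )
    return eig, pd.DataFrame(cov)


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

EXACT_MAX_N = 8


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact p by enumeration of the U distribution when ``min(n_a, n_b) <= 8``
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns ``(U of group_a, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= EXACT_MAX_N and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def test_response_difference(
    eigengenes: Eigengenes,
    response: pd.Series,
    regimen: pd.Series | None = None,
) -> pd.DataFrame:
    """Mann–Whitney tests of pretreatment eigengenes between response groups.

    ``response`` labels each sample "responder" or "nonresponder".  When
    ``regimen`` is given, tests run separately per regimen; BH adjustment is
    across modules within each (dataset, regimen) block.  ``direction`` is
    the sign of (mean nonresponder − mean responder).
    """
    labels = response.loc[eigengenes.scores.index]
    if set(labels.unique()) != {"responder", "nonresponder"}:
        raise DataError("response must contain both 'responder' and 'nonresponder'")
    blocks = (
        [("all", eigengenes.scores.index)]
        if regimen is None
        else [(str(r), regimen[regimen == r].index.intersection(eigengenes.scores.index))
              for r in sorted(regimen.dropna().unique())]
    )
    out = []
    for reg_name, samples in blocks:
        lab = labels.loc[samples]
        nonresp = samples[lab == "nonresponder"]
        resp = samples[lab == "responder"]
        if len(nonresp) == 0 or len(resp) == 0:
            raise DataError(f"regimen {reg_name}: single-class data")
        rows = []
        for module in eigengenes.scores.columns:
            x = eigengenes.scores.loc[nonresp, module].to_numpy()
            y = eigengenes.scores.loc[resp, module].to_numpy()
            u, p = mann_whitney(x, y)
            rows.append({"regimen": reg_name, "module": module, "U": u, "p": p,
                         "direction": int(np.sign(x.mean() - y.mean()))})
        block = pd.DataFrame(rows)
        block["fdr"] = bh_adjust(block["p"].to_numpy())
        out.append(block)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# effect sizes and meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class EffectSize:
    """Hedges-g standardized mean difference with its sampling variance."""

    g: float
    v: float
    n1: int
    n2: int
    study_id: str = ""

    def __post_init__(self) -> None:
        lower = (self.n1 + self.n2) / (self.n1 * self.n2)
        if self.v < lower - 1e-12:
            raise DataError("effect-size variance below its g=0 lower bound")


def hedges_g(
    group_a: Sequence[float], group_b: Sequence[float], study_id: str = ""
) -> EffectSize:
    """Exact (gamma-function) Hedges-g estimate of the SMD of A minus B.

    ``d = (mean_a - mean_b)/s_pooled``; the exact small-sample correction is
    ``J(m) = Gamma(m/2) / (sqrt(m/2) Gamma((m-1)/2))`` with
    ``m = n_a + n_b - 2``; ``g = J d`` and
    ``v = (n_a+n_b)/(n_a n_b) + g^2/(2(n_a+n_b))``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs >= 2 observations")
    m = n1 + n2 - 2
    s_pooled = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / m)
    if s_pooled == 0:
        raise DataError("zero pooled standard deviation")
    d = (a.mean() - b.mean()) / s_pooled
    j = np.exp(gammaln(m / 2.0) - gammaln((m - 1) / 2.0)) / np.sqrt(m / 2.0)
    g = float(j * d)
    v = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return EffectSize(g=g, v=float(v), n1=n1, n2=n2, study_id=study_id)


@dataclass
class MetaAnalysisResult:
    """DerSimonian–Laird random-effects pooling of standardized differences."""

    effects: list[EffectSize]
    Q: float
    tau2: float
    pooled_smd: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float


def meta_analyze(effects: Sequence[EffectSize]) -> MetaAnalysisResult:
    """Pool Hedges-g effects under a DerSimonian–Laird random-effects model.

    Fixed weights ``w_i = 1/v_i`` give ``Q``; the method-of-moments
    heterogeneity is ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))``;
    random weights ``1/(v_i + tau2)`` give the pooled SMD, its standard error,
    a 95% normal CI and a two-sided normal p-value.
    """
    if len(effects) == 0:
        raise ParameterError("meta-analysis needs at least one effect")
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    w = 1.0 / v
    g_fixed = float(np.sum(w * g) / np.sum(w))
    q = float(np.sum(w * (g - g_fixed) ** 2))
    k = len(effects)
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    ws = 1.0 / (v + tau2)
    pooled = float(np.sum(ws * g) / np.sum(ws))
    se = float(np.sum(ws) ** -0.5)
    z = pooled / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return MetaAnalysisResult(
        effects=list(effects), Q=q, tau2=float(tau2), pooled_smd=pooled, se=se,
        ci_low=pooled - 1.96 * se, ci_high=pooled + 1.96 * se, z=float(z), p=p,
    )


# ---------------------------------------------------------------------------
# per-gene AUROC ranking
# ---------------------------------------------------------------------------


def _rank_auc(predictor: np.ndarray, is_case: np.ndarray) -> float:
    """AUC of a continuous predictor via the rank (Mann–Whitney) formula."""
    ranks = sps.rankdata(predictor)
    n1 = int(is_case.sum())
    n0 = is_case.size - n1
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def rank_genes_by_auc(dataset: ResponseDataset) -> pd.DataFrame:
    """Predictive AUROC of every gene for therapy nonresponse, with ranks.

    Each gene is the sole predictor of nonresponse in a univariate logistic
    model; because the logistic link is monotone, the AUC of the fitted
    predictions equals the AUC of the predictor oriented by the sign of the
    fitted slope, which in the univariate model matches the sign of the
    case/control mean difference.  The AUC is therefore computed rank-wise as
    ``(wins + 0.5 ties) / (n1 n0)`` on the oriented gene, without a per-gene
    model fit.  Constant genes get AUC 0.5 by convention.

    Ranks are 1..n_genes by descending AUC, ties broken by gene identifier.
    """
    labels = dataset.response.loc[dataset.expr.sample_ids]
    is_case = (labels == "nonresponder").to_numpy()
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise DataError("both classes need >= 2 samples for AUC ranking")
    aucs = np.empty(dataset.expr.n_genes)
    for i in range(dataset.expr.n_genes):
        x = dataset.expr.values[i]
        if np.ptp(x) == 0:
            aucs[i] = 0.5
            continue
        orient = np.sign(x[is_case].mean() - x[~is_case].mean())
        auc = _rank_auc(x, is_case)
        aucs[i] = auc if orient >= 0 else 1.0 - auc
    out = pd.DataFrame(
        {"gene": dataset.expr.gene_ids, "auc": aucs, "study_id": dataset.study_id}
    )
    order = out.sort_values(["auc", "gene"], ascending=[False, True]).index
    ranks = pd.Series(np.arange(1, len(out) + 1), index=order)
    out["rank"] = ranks.sort_index().to_numpy()
    return out


def combine_ranks(
    tables: Sequence[pd.DataFrame],
    module_sets: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Sum per-study AUC ranks over the shared gene universe.

    Genes are restricted to the intersection across studies and re-ranked
    within it (descending AUC, ties by identifier) so combined ranks stay a
    sum of permutations of 1..n.  When ``module_sets`` is given, per-module
    combined-rank distributions are compared pairwise by Mann–Whitney with BH
    adjustment.

    Returns ``(combined table, pairwise module comparison or None)``.
    """
    if len(tables) < 2:
        raise ParameterError("need at least two AUC tables to combine")
    shared: set[str] | None = None
    for t in tables:
        shared = set(t["gene"]) if shared is None else shared & set(t["gene"])
    if not shared:
        raise DataError("no genes shared across studies")
    genes = sorted(shared)
    combined = pd.DataFrame(index=genes)
    total = np.zeros(len(genes))
    for t in tables:
        sub = t.set_index("gene").loc[genes]
        order = sub.reset_index().sort_values(["auc", "gene"], ascending=[False, True])
        rank = pd.Series(np.arange(1, len(genes) + 1), index=order["gene"]).loc[genes]
        study = str(sub["study_id"].iloc[0])
        combined[f"rank_{study}"] = rank.to_numpy()
        combined[f"auc_{study}"] = sub["auc"].to_numpy()
        total += rank.to_numpy()
    combined["combined_rank"] = total.astype(int)
    combined.index.name = "gene"
    comparisons = None
    if module_sets is not None:
        membership = pd.Series("unassigned", index=combined.index)
        for name, members in module_sets.items():
            membership.loc[membership.index.intersection(list(members))] = name
        combined["module"] = membership
        rows = []
        names = [n for n in module_sets if (membership == n).any()]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                ra = combined.loc[membership == a, "combined_rank"].to_numpy()
                rb = combined.loc[membership == b, "combined_rank"].to_numpy()
                u, p = mann_whitney(ra, rb)
                rows.append({"module_a": a, "module_b": b, "U": u, "p": p,
                             "median_a": float(np.median(ra)),
                             "median_b": float(np.median(rb))})
        comparisons = pd.DataFrame(rows)
        if len(comparisons):
            comparisons["fdr"] = bh_adjust(comparisons["p"].to_numpy())
    return combined, comparisons


# ---------------------------------------------------------------------------
# patient grouping
# ---------------------------------------------------------------------------


def group_percentages(sizes: Sequence[int]) -> list[float]:
    """Group sizes as percentages of the total, rounded to one decimal."""
    total = sum(sizes)
    if total == 0:
        raise ParameterError("empty grouping")
    return [round(100.0 * s / total, 1) for s in sizes]


def cluster_patients(
    eigengenes: Eigengenes,
    module_subset: Sequence[str],
    k: int,
) -> pd.DataFrame:
    """Group patients by Ward clustering of selected module eigengenes.

    Selected eigengene columns are standardized, patients are clustered with
    Ward linkage on Euclidean distance and the tree is cut into ``k`` groups.
    Each group is annotated high/low per module by comparing its mean
    eigengene to the overall mean.  Returns a per-group summary with sizes,
    percentages and a ``label`` like "M4-high/M5-high/M6-low"; per-sample
    group ids are attached as the attribute ``.attrs["groups"]``.
    """
    missing = [m for m in module_subset if m not in eigengenes.scores.columns]
    if missing:
        raise ParameterError(f"modules not in eigengenes: {missing}")
    x = eigengenes.scores[list(module_subset)].to_numpy()
    n = x.shape[0]
    if not (1 <= k <= n):
        raise ParameterError("k must satisfy 1 <= k <= n_samples")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    if k == 1:
        groups = np.ones(n, dtype=int)
    else:
        groups = fcluster(linkage(z, method="ward"), t=k, criterion="maxclust")
    overall = z.mean(axis=0)
    rows = []
    for g in sorted(set(groups)):
        mask = groups == g
        means = z[mask].mean(axis=0)
        label = "/".join(
            f"{m}-{'high' if mu > ov else 'low'}"
            for m, mu, ov in zip(module_subset, means, overall)
        )
        rows.append({"group": int(g), "n": int(mask.sum()), "label": label,
                     **{f"mean_{m}": float(mu) for m, mu in zip(module_subset, means)}})
    out = pd.DataFrame(rows)
    out["percent"] = group_percentages(out["n"].tolist())
    out.attrs["groups"] = pd.Series(groups, index=eigengenes.scores.index, name="group")
    return out
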