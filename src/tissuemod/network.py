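"""Signed weighted gene coexpression networks and module detection.

Implements the network arm of the module-discovery pipeline: soft-threshold
selection against a scale-free topology criterion, signed adjacency
``a_ij = ((1 + r_ij)/2)**beta``, the topological overlap matrix (TOM),
average-linkage module detection on ``1 - TOM``, module eigengenes as the
first principal component of the standardized module submatrix, and merging
of modules with highly correlated eigengenes.

All functions here are deterministic: there is no random number generation in
this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

VALID_SCALES = ("counts", "tpm", "log")

#: default candidate soft powers for the threshold scan
DEFAULT_POWERS: tuple[int, ...] = tuple(range(1, 21))


class TissuemodError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(TissuemodError, ValueError):
    """Invalid parameter value."""


class DataError(TissuemodError, ValueError):
    """Input data violates a documented precondition."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression values with a declared scale.

    Parameters
    ----------
    values
        ``(n_genes, n_samples)`` float array with no missing values.
    gene_ids, sample_ids
        Unique string identifiers matching the matrix dimensions.
    scale
        One of ``"counts"``, ``"tpm"`` or ``"log"``; downstream stages check
        this tag instead of guessing from the data.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = "tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values contain NaN or infinity")
        if self.scale not in VALID_SCALES:
            raise ParameterError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise DataError(f"genes absent from matrix: {missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows], list(genes), self.sample_ids, self.scale)


@dataclass
class ThresholdScan:
    """Result of the soft-threshold scan.

    ``table`` has one row per candidate power with the signed scale-free fit
    index (−sign(slope)·R² of the log–log degree fit) and connectivity
    summaries; ``chosen_power`` is the smallest power whose index reaches the
    fit threshold, or the argmax when none does, unless overridden.
    """

    table: pd.DataFrame
    chosen_power: int
    overridden: bool = False


@dataclass
class AdjacencyMatrix:
    """Symmetric signed adjacency in [0, 1] with unit diagonal."""

    a: np.ndarray
    beta: float
    signed: bool = True
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DataError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise DataError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise DataError("adjacency entries must lie in [0, 1]")
        if not np.allclose(np.diag(a), 1.0):
            raise DataError("adjacency diagonal must be 1")
        self.a = np.clip(a, 0.0, 1.0)
        np.fill_diagonal(self.a, 1.0)

    @property
    def n_genes(self) -> int:
        return self.a.shape[0]

    def connectivity(self) -> np.ndarray:
        """Whole-network connectivity k_i = sum_{j != i} a_ij."""
        return self.a.sum(axis=0) - np.diag(self.a)


@dataclass
class TOMMatrix:
    """Topological overlap similarity, symmetric in [0, 1], unit diagonal."""

    t: np.ndarray
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise DataError("TOM must be square")
        if not np.allclose(t, t.T, atol=1e-10):
            raise DataError("TOM must be symmetric")
        if t.min() < -1e-10 or t.max() > 1 + 1e-10:
            raise DataError("TOM entries must lie in [0, 1]")
        if not np.allclose(np.diag(t), 1.0):
            raise DataError("TOM diagonal must be 1")
        self.t = np.clip(t, 0.0, 1.0)
        np.fill_diagonal(self.t, 1.0)


@dataclass
class ModuleAssignment:
    """Gene -> integer module label; 0 means unassigned ("grey").

    Labels 1..K are ordered by decreasing module size, ties broken by the
    index of the first member gene.
    """

    labels: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.gene_ids):
            raise DataError("labels must be 1-D and match gene_ids")
        if self.labels.min(initial=0) < 0:
            raise DataError("module labels must be >= 0")

    @property
    def n_modules(self) -> int:
        return int(self.labels.max(initial=0))

    def module_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}

    def genes_in_module(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def to_gene_sets(self, prefix: str = "M") -> dict[str, list[str]]:
        """Module assignment as named gene sets M1..MK (unassigned omitted)."""
        return {
            f"{prefix}{m}": self.genes_in_module(m) for m in range(1, self.n_modules + 1)
        }


@dataclass
class Eigengenes:
    """Samples x modules eigengene scores.

    Each column is the unit-L2-norm first left singular vector (over samples)
    of the gene-standardized module submatrix, sign-aligned to correlate
    positively with the module's mean standardized expression.
    """

    scores: pd.DataFrame
    variance_explained: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.variance_explained is None:
            self.variance_explained = pd.Series(np.nan, index=self.scores.columns)
        norms = np.linalg.norm(self.scores.to_numpy(), axis=0)
        if self.scores.shape[0] and not np.allclose(norms, 1.0, atol=1e-6):
            raise DataError("eigengene columns must have unit L2 norm")

    @property
    def module_names(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_and_log(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Drop low-expressed genes and move to natural-log scale.

    Genes with zero counts in strictly more than half of the samples are
    removed; the rest are transformed as ``log(x + pseudocount)``.
    """
    if expr.scale not in ("counts", "tpm"):
        raise ParameterError("filter_and_log expects a counts or tpm matrix")
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be > 0")
    n_zero = (expr.values == 0).sum(axis=1)
    keep = n_zero <= expr.n_samples / 2.0
    if not keep.any():
        raise DataError("no genes survive the zero-count filter")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_and_log: removed %d/%d genes with zeros in >50%% of samples",
                    n_removed, expr.n_genes)
    values = np.log(expr.values[keep] + pseudocount)
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(values, genes, expr.sample_ids, scale="log")


# ---------------------------------------------------------------------------
# adjacency / TOM
# ---------------------------------------------------------------------------


def _pearson_gene_correlation(expr: ExpressionMatrix) -> np.ndarray:
    sd = expr.values.std(axis=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        names = [expr.gene_ids[i] for i in zero_var[:10]]
        raise DataError(f"zero-variance genes (correlation undefined): {names}")
    r = np.corrcoef(expr.values)
    return np.clip(r, -1.0, 1.0)


def signed_adjacency(expr: ExpressionMatrix, beta: float) -> AdjacencyMatrix:
    """Signed adjacency ``a_ij = ((1 + r_ij)/2)**beta`` with unit diagonal."""
    if expr.scale != "log":
        raise ParameterError("network construction expects a log-scale matrix")
    if beta < 1:
        raise ParameterError("beta must be >= 1")
    r = _pearson_gene_correlation(expr)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(a=a, beta=beta, signed=True, gene_ids=list(expr.gene_ids))


def tom_similarity(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap of a weighted network.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``k_i = sum_{u != i} a_iu`` and unit diagonal.
    """
    a = adj.a
    k = adj.connectivity()
    # sum_{u != i,j} a_iu a_uj = (A @ A)_ij - a_ii a_ij - a_ij a_jj = (A@A)_ij - 2 a_ij
    shared = a @ a
    numer = shared - 2.0 * a + a  # + a_ij direct-link term
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):  # diagonal is overwritten
        t = numer / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(t=t, gene_ids=adj.gene_ids)


# ---------------------------------------------------------------------------
# soft-threshold scan
# ---------------------------------------------------------------------------


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity vector.

    Bins log10(k) into ``n_bins`` equal-width bins, regresses log10(bin
    frequency) on log10(mean k per bin) and returns −sign(slope)·R².
    """
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    which = np.digitize(logk, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope, _ = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    candidate_powers: Iterable[int] = DEFAULT_POWERS,
    fit_threshold: float = 0.8,
    override: int | None = None,
) -> ThresholdScan:
    """Scan candidate soft powers for approximate scale-free topology.

    For each power the signed adjacency is built, whole-network connectivity
    computed and the signed R² of the log–log degree distribution fit
    recorded.  The chosen power is the smallest one reaching
    ``fit_threshold``, or the argmax if none does.  ``override`` short-cuts
    the choice (the scan table is still produced).
    """
    powers = sorted(int(b) for b in candidate_powers)
    if not powers or min(powers) < 1:
        raise ParameterError("candidate powers must be integers >= 1")
    if expr.n_genes < 10:
        raise DataError("soft-threshold scan needs at least 10 genes")
    r = _pearson_gene_correlation(expr)
    s = (1.0 + r) / 2.0
    np.fill_diagonal(s, 0.0)  # exclude self from connectivity
    rows = []
    for beta in powers:
        a = s**beta
        k = a.sum(axis=0)
        rows.append(
            {
                "power": beta,
                "fit_r2": _scale_free_fit(k),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    if override is not None:
        if override < 1:
            raise ParameterError("override power must be >= 1")
        return ThresholdScan(table=table, chosen_power=int(override), overridden=True)
    good = table[table["fit_r2"] >= fit_threshold]
    if len(good):
        chosen = int(good["power"].iloc[0])
    else:
        chosen = int(table.loc[table["fit_r2"].idxmax(), "power"])
        logger.warning(
            "no power reached fit R2 >= %.2f; using argmax power %d (R2=%.3f)",
            fit_threshold, chosen, table["fit_r2"].max(),
        )
    return ThresholdScan(table=table, chosen_power=chosen)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------


def _relabel_by_size(labels: np.ndarray, min_module_size: int) -> np.ndarray:
    """Zero out small clusters, relabel survivors 1..K by decreasing size.

    Ties in size are broken by the index of the first member gene, which makes
    the labelling invariant to the arbitrary cluster ids of the tree cut.
    """
    out = np.zeros_like(labels)
    info = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        members = np.flatnonzero(labels == lab)
        if members.size >= min_module_size:
            info.append((members.size, members[0], lab))
    info.sort(key=lambda t: (-t[0], t[1]))
    for new, (_, _, old) in enumerate(info, start=1):
        out[labels == old] = new
    return out


def _gap_cut_height(z: np.ndarray, min_module_size: int) -> float | None:
    """Static cut height chosen from the dendrogram's own geometry.

    Replays the merges bottom-up, tracking after each merge how many flat
    clusters have at least ``min_module_size`` members.  Among the height
    intervals that attain the maximal module count, the widest one is taken
    (modules are complete but chaining of background genes has not started)
    and the cut is placed at its midpoint.

    Returns ``None`` when no clear gap exists: clusters that reach the
    minimum size only through quasi-continuous chaining of background genes
    produce height gaps no wider than the typical merge spacing, whereas a
    genuine module sits below a wide structural gap.  The floor is 10x the
    mean merge spacing.
    """
    n = z.shape[0] + 1
    size = np.ones(2 * n - 1, dtype=int)
    count = n if min_module_size <= 1 else 0
    counts = np.empty(n - 1, dtype=int)
    for k in range(n - 1):
        a, b = int(z[k, 0]), int(z[k, 1])
        merged = size[a] + size[b]
        size[n + k] = merged
        count -= (size[a] >= min_module_size) + (size[b] >= min_module_size)
        count += merged >= min_module_size
        counts[k] = count
    heights = z[:, 2]
    upper = np.append(heights[1:], heights[-1] + 1e-6)
    widths = upper - heights
    best = counts.max()
    if best == 0:
        return None
    candidates = np.flatnonzero(counts == best)
    k = candidates[np.argmax(widths[candidates])]
    gap_floor = 10.0 * (heights[-1] - heights[0]) / max(n - 1, 1)
    if min_module_size > 1 and widths[k] < gap_floor:
        return None
    return float((heights[k] + upper[k]) / 2.0)


def detect_modules(
    tom: TOMMatrix,
    min_module_size: int = 30,
    cut_quantile: float | None = None,
) -> ModuleAssignment:
    """Assign genes to modules by average-linkage clustering of ``1 - TOM``.

    By default the dendrogram is cut at the midpoint of the widest
    merge-height gap among cut levels that maximize the number of clusters
    with at least ``min_module_size`` members (see :func:`_gap_cut_height`);
    passing ``cut_quantile`` instead cuts at that quantile of the merge
    heights.  Flat clusters smaller than ``min_module_size`` are left
    unassigned (label 0) and survivors are relabelled 1..K by decreasing
    size.
    """
    if min_module_size < 1:
        raise ParameterError("min_module_size must be >= 1")
    if cut_quantile is not None and not (0 < cut_quantile <= 1):
        raise ParameterError("cut_quantile must lie in (0, 1]")
    n = tom.t.shape[0]
    gene_ids = tom.gene_ids or [f"g{i}" for i in range(n)]
    if n == 1:
        return ModuleAssignment(labels=np.zeros(1, dtype=int), gene_ids=list(gene_ids))
    d = 1.0 - tom.t
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    if cut_quantile is None:
        cut_height = _gap_cut_height(z, min_module_size)
        if cut_height is None:
            logger.info("detect_modules: no clear cut gap; all %d genes unassigned", n)
            return ModuleAssignment(labels=np.zeros(n, dtype=int),
                                    gene_ids=list(gene_ids))
    else:
        cut_height = float(np.quantile(z[:, 2], cut_quantile))
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = _relabel_by_size(np.asarray(raw, dtype=int), min_module_size)
    logger.info(
        "detect_modules: cut height %.4f -> %d modules, %d unassigned of %d genes",
        cut_height, int(labels.max(initial=0)), int((labels == 0).sum()), n,
    )
    return ModuleAssignment(labels=labels, gene_ids=list(gene_ids))


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DataError("zero-variance gene in module; eigengene undefined")
    return (x - mu) / sd


def eigengene_from_submatrix(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First-PC eigengene of a genes x samples submatrix.

    Rows are standardized (mean 0, sd 1 with the n−1 denominator); the
    eigengene is the unit-norm first right singular vector over samples,
    sign-aligned to correlate non-negatively with the mean standardized
    expression.  Returns ``(eigengene, variance_explained)``.
    """
    zs = _standardize_rows(np.asarray(x, dtype=float))
    _, s, vt = np.linalg.svd(zs, full_matrices=False)
    e = vt[0]
    e = e / np.linalg.norm(e)
    avg = zs.mean(axis=0)
    if float(e @ avg) < 0:
        e = -e
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return e, var_explained


def compute_eigengenes(expr: ExpressionMatrix, modules: ModuleAssignment) -> Eigengenes:
    """Eigengene of every module of an assignment, on its defining matrix."""
    if expr.scale != "log":
        raise ParameterError("eigengenes are computed on log-scale expression")
    missing = [g for g in modules.gene_ids if g not in set(expr.gene_ids)]
    if missing:
        raise DataError(f"module genes absent from expression matrix: {missing[:10]}")
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    cols, ve = {}, {}
    for m in range(1, modules.n_modules + 1):
        rows = [index[g] for g in modules.genes_in_module(m)]
        e, v = eigengene_from_submatrix(expr.values[rows])
        name = f"M{m}"
        cols[name] = e
        ve[name] = v
    scores = pd.DataFrame(cols, index=expr.sample_ids)
    return Eigengenes(scores=scores, variance_explained=pd.Series(ve, dtype=float))


def merge_close_modules(
    expr: ExpressionMatrix,
    modules: ModuleAssignment,
    merge_cut: float = 0.1,
) -> ModuleAssignment:
    """Merge modules whose eigengenes are nearly identical.

    Repeatedly merges the closest module pair with eigengene dissimilarity
    ``1 - cor`` below ``merge_cut``, recomputing eigengenes after each merge,
    until no pair qualifies; the result is relabelled by size.
    ``merge_cut = 0`` is the identity.
    """
    if not (0 <= merge_cut < 1):
        raise ParameterError("merge_cut must lie in [0, 1)")
    labels = modules.labels.copy()
    if merge_cut == 0 or modules.n_modules < 2:
        return ModuleAssignment(labels=labels, gene_ids=list(modules.gene_ids))
    while True:
        current = ModuleAssignment(labels=labels, gene_ids=list(modules.gene_ids))
        if current.n_modules < 2:
            break
        eig = compute_eigengenes(expr, current)
        corr = np.corrcoef(eig.scores.to_numpy().T)
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut:
            break
        a, b = sorted((i + 1, j + 1))
        logger.info("merging modules M%d and M%d (eigengene dissimilarity %.4f)",
                    a, b, diss[i, j])
        labels[labels == b] = a
        # compact labels so eigengene columns track 1..K
        for new, old in enumerate(sorted(set(labels) - {0}), start=1):
            labels[labels == old] = new
    labels = _relabel_by_size(labels, min_module_size=1)
    return ModuleAssignment(labels=labels, gene_ids=list(modules.gene_ids))
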