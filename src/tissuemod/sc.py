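"""Single-cell arm: QC, log(CP10K), module scoring, pseudobulk, trajectory.

QC drops droplets with too few detected genes or too high a mitochondrial
read fraction; normalization is the exact per-cell formula
``log(1 + 1e4 * UMI_gi / total_i)`` (natural log, sparsity preserved);
module scores are sums of per-gene z-scores of normalized expression across
all cells; pseudobulk sums UMIs over (donor, cluster); the trajectory is a
Hastie–Stuetzle principal curve on a 2-D embedding whose arc-length position,
scaled to [0, 100], serves as pseudotime, summarized over equal-cell-count
("uniform-density") windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .network import DataError, ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def qc_filter(
    adata: AnnData, min_genes: int = 500, max_mito_fraction: float = 0.20
) -> AnnData:
    """Remove droplets failing detected-gene or mitochondrial-fraction QC.

    Cells with strictly fewer than ``min_genes`` detected genes, or with a
    mitochondrial count fraction strictly greater than ``max_mito_fraction``,
    are removed; cells exactly at either threshold are retained.  Counts of
    retained cells are untouched.
    """
    if "mito" not in adata.var:
        raise DataError("adata.var must carry a boolean 'mito' mask")
    x = sp.csr_matrix(adata.X)
    detected = np.asarray((x > 0).sum(axis=1)).ravel()
    totals = np.asarray(x.sum(axis=1)).ravel()
    mito_counts = np.asarray(x[:, adata.var["mito"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    fail_genes = detected < min_genes
    fail_mito = mito_frac > max_mito_fraction
    keep = ~(fail_genes | fail_mito)
    if not keep.any():
        raise DataError(
            f"QC removed all cells ({int(fail_genes.sum())} below {min_genes} genes, "
            f"{int(fail_mito.sum())} above {max_mito_fraction:.0%} mitochondrial)"
        )
    logger.info("qc_filter: kept %d/%d cells (%d failed gene count, %d failed mito)",
                int(keep.sum()), adata.n_obs, int(fail_genes.sum()), int(fail_mito.sum()))
    return adata[keep].copy()


def normalize_cp10k(adata: AnnData) -> AnnData:
    """Depth-normalize counts to natural-log counts-per-10,000.

    ``y_gi = log(1 + 1e4 * UMI_gi / sum_h UMI_hi)`` applied to the sparse
    nonzero entries only, so zeros stay zero.  Raw counts are kept in
    ``layers["counts"]``.
    """
    x = sp.csr_matrix(adata.X).astype(float)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise DataError("cells with zero total counts; run qc_filter first")
    out = adata.copy()
    out.layers["counts"] = x.copy()
    scaled = x.copy()
    row_rep = np.repeat(totals, np.diff(scaled.indptr))
    scaled.data = np.log1p(1e4 * scaled.data / row_rep)
    out.X = scaled
    out.uns["normalization"] = "log1p(CP10K), natural log"
    return out


# ---------------------------------------------------------------------------
# gene-set scoring
# ---------------------------------------------------------------------------


def score_gene_sets(
    adata: AnnData, gene_sets: dict[str, list[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell gene-set scores as sums of per-gene z-scores.

    For each gene present in the matrix with nonzero variance, the z-score
    of its normalized expression across all cells (sd with the n−1
    denominator) is computed; the score of a set is the sum of its genes'
    z-scores.  Absent and zero-variance genes are dropped.

    Returns ``(scores cells x sets, genes used per set)``.
    """
    x = sp.csr_matrix(adata.X)
    n = adata.n_obs
    if n < 2:
        raise DataError("need at least 2 cells to z-score")
    index = {g: i for i, g in enumerate(adata.var_names)}
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    scores = {}
    used = {}
    xc = sp.csc_matrix(x)
    for name, genes in gene_sets.items():
        cols = [index[g] for g in genes if g in index and sd[index[g]] > 0]
        if not cols:
            raise DataError(f"gene set {name!r} has no usable genes")
        dropped = len(genes) - len(cols)
        if dropped:
            logger.info("set %s: dropped %d absent/zero-variance genes", name, dropped)
        sub = np.asarray(xc[:, cols].todense())
        z = (sub - mean[cols]) / sd[cols]
        scores[name] = z.sum(axis=1)
        used[name] = len(cols)
    return (
        pd.DataFrame(scores, index=adata.obs_names),
        pd.Series(used, name="n_genes_used"),
    )


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------


def pseudobulk(
    adata: AnnData,
    by: tuple[str, str] = ("donor", "cluster"),
    min_cells: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum UMI counts over all cells sharing a (donor, cluster) pair.

    Returns ``(pseudobulk samples x genes, n_cells per sample)``; samples
    with fewer than ``min_cells`` cells are flagged (dropped) from the
    matrix.  Integer totals are conserved exactly.
    """
    for col in by:
        if col not in adata.obs:
            raise DataError(f"missing per-cell annotation {col!r}")
    x = sp.csr_matrix(adata.X)
    keys = pd.MultiIndex.from_frame(adata.obs[list(by)].astype(str))
    groups = keys.unique().sort_values()
    rows, names, ncells = [], [], []
    for key in groups:
        mask = np.asarray(keys == key)
        rows.append(np.asarray(x[mask].sum(axis=0)).ravel())
        names.append("|".join(key))
        ncells.append(int(mask.sum()))
    out = pd.DataFrame(np.vstack(rows), index=names, columns=adata.var_names)
    n_cells = pd.Series(ncells, index=names, name="n_cells")
    small = n_cells < min_cells
    if small.any():
        logger.warning("dropping %d pseudobulk samples with < %d cells",
                       int(small.sum()), min_cells)
        out = out.loc[~small]
        n_cells = n_cells.loc[~small]
    return out, n_cells


# ---------------------------------------------------------------------------
# principal-curve trajectory
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryResult:
    """Principal-curve fit: pseudotime in [0, 100] plus diagnostics."""

    pseudotime: pd.Series
    vertices: np.ndarray  # ordered curve vertices (n_cells x 2)
    n_iterations: int
    converged: bool
    projection_error: list[float] = field(default_factory=list)


def _project_to_polyline(
    points: np.ndarray, vertices: np.ndarray
) -> tuple[np.ndarray, float]:
    """Orthogonally project points onto a polyline.

    Returns ``(arc-length parameter per point, total squared distance)``.
    Chunked over segments to bound memory.
    """
    # drop zero-length segments (duplicate consecutive vertices)
    keep = np.ones(vertices.shape[0], dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(vertices, axis=0), axis=1) > 1e-12
    vertices = vertices[keep]
    if vertices.shape[0] < 2:
        lam = np.zeros(points.shape[0])
        d2 = np.sum((points - vertices[0]) ** 2, axis=1)
        return lam, float(d2.sum())
    seg_start = vertices[:-1]
    seg_vec = np.diff(vertices, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_pts = points.shape[0]
    best_d2 = np.full(n_pts, np.inf)
    best_lam = np.zeros(n_pts)
    chunk = max(1, int(2e6 / max(n_pts, 1)))
    for s0 in range(0, seg_start.shape[0], chunk):
        s1 = min(s0 + chunk, seg_start.shape[0])
        diff = points[None, :, :] - seg_start[s0:s1, None, :]
        t = np.einsum("spd,sd->sp", diff, seg_vec[s0:s1]) / (seg_len[s0:s1] ** 2)[:, None]
        t = np.clip(t, 0.0, 1.0)
        proj = seg_start[s0:s1, None, :] + t[:, :, None] * seg_vec[s0:s1, None, :]
        d2 = np.sum((points[None, :, :] - proj) ** 2, axis=2)
        seg_best = np.argmin(d2, axis=0)
        pts_idx = np.arange(n_pts)
        dmin = d2[seg_best, pts_idx]
        better = dmin < best_d2
        sb = seg_best[better]
        best_d2[better] = dmin[better]
        best_lam[better] = cum[s0 + sb] + t[sb, pts_idx[better]] * seg_len[s0 + sb]
    return best_lam, float(best_d2.sum())


def _local_linear_smooth(lam: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Local-linear (loess-like, tricube weights) smooth of y against lam."""
    n = lam.size
    k = max(4, int(np.ceil(span * n)))
    order = np.argsort(lam, kind="mergesort")
    ls, ys = lam[order], y[order]
    out = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - k // 2, n - k))
        hi = lo + k
        xs = ls[lo:hi]
        yy = ys[lo:hi]
        h = max(abs(xs - ls[i]).max(), 1e-12)
        w = (1 - np.minimum(np.abs(xs - ls[i]) / h, 1.0) ** 3) ** 3
        sw = w.sum()
        xm = (w * xs).sum() / sw
        ym = (w * yy).sum() / sw
        sxx = (w * (xs - xm) ** 2).sum()
        slope = (w * (xs - xm) * (yy - ym)).sum() / sxx if sxx > 1e-300 else 0.0
        out[i] = ym + slope * (ls[i] - xm)
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return out[inv]


def fit_principal_curve(
    embedding: np.ndarray | pd.DataFrame,
    span: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 30,
    cluster_labels: pd.Series | None = None,
) -> TrajectoryResult:
    """Fit a principal curve and read off arc-length pseudotime.

    Hastie–Stuetzle iteration initialized at the first principal-component
    line: alternately (i) project points orthogonally onto the current
    polyline to get arc-length parameters, (ii) smooth each coordinate
    against the parameter with a local-linear smoother of the given span,
    (iii) reparameterize by arc length.  A smoothing step is accepted only if
    it does not increase the total squared projection distance, which makes
    the per-iteration error sequence non-increasing by construction;
    iteration stops when the relative change drops below ``tol``.

    Final positions are affinely scaled to [0, 100].  The curve is
    direction-blind; when ``cluster_labels`` is given, pseudotime is flipped
    if needed so the first label in input order sits at the lower end.
    """
    if isinstance(embedding, pd.DataFrame):
        index = embedding.index
        pts = embedding.to_numpy(dtype=float)
    else:
        pts = np.asarray(embedding, dtype=float)
        index = pd.RangeIndex(pts.shape[0])
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("embedding must be n_cells x 2")
    if pts.shape[0] < 10:
        raise ParameterError("need at least 10 cells")
    if np.allclose(pts, pts[0]):
        raise DataError("degenerate embedding: all points identical")

    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    lam = (pts - center) @ vt[0]
    order = np.argsort(lam, kind="mergesort")
    vertices = center + lam[order, None] * vt[0]
    lam_now, err = _project_to_polyline(pts, vertices)
    errors = [err]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sx = _local_linear_smooth(lam_now, pts[:, 0], span)
        sy = _local_linear_smooth(lam_now, pts[:, 1], span)
        order = np.argsort(lam_now, kind="mergesort")
        new_vertices = np.column_stack([sx, sy])[order]
        new_lam, new_err = _project_to_polyline(pts, new_vertices)
        if new_err > errors[-1] + 1e-12:
            logger.info("principal curve: error would increase at iteration %d; stopping", it)
            converged = True
            break
        vertices = new_vertices
        rel = abs(errors[-1] - new_err) / max(errors[-1], 1e-300)
        lam_now, err = new_lam, new_err
        errors.append(err)
        if rel < tol:
            converged = True
            break

    span_lam = lam_now.max() - lam_now.min()
    if span_lam <= 0:
        raise DataError("degenerate curve: all projections coincide")
    pt = 100.0 * (lam_now - lam_now.min()) / span_lam
    if cluster_labels is not None:
        labels = pd.Series(cluster_labels).reindex(index)
        present = labels.dropna()
        if len(present):
            if isinstance(labels.dtype, pd.CategoricalDtype):
                first = next(c for c in labels.cat.categories if (present == c).any())
            else:
                first = sorted(present.unique())[0]
            mid = pd.Series(pt, index=index)[labels == first].median()
            if mid > 50.0:
                pt = 100.0 - pt
                logger.info("pseudotime flipped so cluster %r sits at the low end", first)
    return TrajectoryResult(
        pseudotime=pd.Series(pt, index=index, name="pseudotime"),
        vertices=vertices,
        n_iterations=it,
        converged=converged,
        projection_error=errors,
    )


def window_density(
    pseudotime: pd.Series,
    cluster_labels: pd.Series,
    n_windows: int = 100,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Summarize cluster abundance over equal-cell-count pseudotime windows.

    Cells are sorted by pseudotime and split into ``n_windows`` windows of
    equal cell count (any remainder goes to the earliest windows).  For each
    cluster the proportion of its cells per window is reported (rows sum to
    1) together with its modal window and that window's midpoint on the
    0–100 scale.

    Returns ``(window id per cell, densities clusters x windows, modal
    summary)``.
    """
    pt = pseudotime.dropna()
    n = len(pt)
    if n_windows > n:
        raise ParameterError("n_windows cannot exceed the number of cells")
    order = pt.sort_values(kind="mergesort").index
    base, rem = divmod(n, n_windows)
    sizes = np.full(n_windows, base)
    sizes[:rem] += 1
    window = pd.Series(np.repeat(np.arange(n_windows), sizes), index=order, name="window")
    window = window.reindex(pseudotime.index)
    labels = cluster_labels.reindex(pt.index)
    density = (
        pd.crosstab(labels, window.loc[pt.index])
        .reindex(columns=range(n_windows), fill_value=0)
        .astype(float)
    )
    density = density.div(density.sum(axis=1), axis=0)
    modal = density.idxmax(axis=1)
    summary = pd.DataFrame(
        {
            "modal_window": modal,
            "modal_position": (modal + 0.5) * 100.0 / n_windows,
        }
    )
    return window, density, summary
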