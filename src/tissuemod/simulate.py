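"""Synthetic cohorts with planted structure.

Three generators emulate the data shapes of an inflamed-tissue transcriptomics
study: a bulk discovery cohort with latent coexpression modules whose
eigengenes track a continuous inflammation trait, replication cohorts in
which nonresponders' module activity is shifted by a planted standardized
mean difference, and droplet single-cell UMI data with discrete clusters,
donor structure, library-size variation, a mitochondrial gene subset and a
latent one-dimensional trajectory.

Every generator is a pure function of its parameter object: the root seed is
split into named child streams so that adding a feature does not shift the
draws of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .network import DataError, ExpressionMatrix, ModuleAssignment, ParameterError

MITO_PREFIX = "MT-"


def _rng(seed: int, *names: str) -> np.random.Generator:
    """Deterministic named child stream of a root seed."""
    keys = [int(seed)] + [zlib.crc32(n.encode("utf8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------


@dataclass
class BulkSimParams:
    """Parameters of the bulk discovery-cohort generator.

    Defaults are desk-scale: 200 samples x 2,000 genes with ten 50-gene
    modules (a quarter of the genes in modules, the rest unstructured noise),
    per-gene loadings near 1, within-gene noise sd 0.5 and a continuous
    inflammation trait driven by the first module's latent factor.
    """

    n_samples: int = 200
    n_genes: int = 2000
    module_sizes: Sequence[int] = (50,) * 10
    loading_mean: float = 1.0
    loading_sd: float = 0.1
    noise_sd: float = 0.5
    trait_effects: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    pseudo_trait_noise_sd: float = 0.5
    base_log_mean: float = 2.0
    base_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ParameterError("n_samples and n_genes must be positive")
        if any(s < 1 for s in self.module_sizes):
            raise ParameterError("all module sizes must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ParameterError("sum of module sizes exceeds n_genes")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        bad = [m for m in self.trait_effects if not 1 <= m <= len(self.module_sizes)]
        if bad:
            raise ParameterError(f"trait_effects refer to nonexistent modules: {bad}")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


def _module_labels(params: BulkSimParams) -> np.ndarray:
    labels = np.zeros(params.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(params.module_sizes, start=1):
        labels[start : start + size] = m
        start += size
    return labels


def _bulk_log_signal(
    params: BulkSimParams, latent: np.ndarray, rng_load, rng_noise, rng_base
) -> np.ndarray:
    """Log-scale signal: baseline + loading * module latent + gene noise."""
    labels = _module_labels(params)
    base = rng_base.normal(params.base_log_mean, params.base_log_sd, size=params.n_genes)
    loadings = rng_load.normal(params.loading_mean, params.loading_sd, size=params.n_genes)
    log_expr = np.tile(base[:, None], (1, latent.shape[0]))
    in_mod = labels > 0
    log_expr[in_mod] += loadings[in_mod, None] * latent[:, labels[in_mod] - 1].T
    log_expr += rng_noise.normal(0.0, params.noise_sd, size=log_expr.shape)
    return log_expr


def simulate_bulk_cohort(
    params: BulkSimParams, kind: str = "tpm"
) -> tuple[ExpressionMatrix, pd.DataFrame, ModuleAssignment, np.ndarray]:
    """Simulate a bulk cohort with planted coexpression modules.

    Genes in module *m* follow ``exp(base + loading * latent_m + noise)``;
    with ``kind="counts"`` the continuous mean is Poisson-sampled to integer
    counts, with ``kind="tpm"`` it is returned as-is.  The continuous
    inflammation trait is ``sum_m trait_effects[m] * latent_m`` plus noise.

    Returns ``(expression, trait table, true module assignment, latent
    factors)`` where the latent matrix is samples x modules.
    """
    if kind not in ("tpm", "counts"):
        raise ParameterError("kind must be 'tpm' or 'counts'")
    latent = _rng(params.seed, "latent").normal(size=(params.n_samples, params.n_modules))
    log_expr = _bulk_log_signal(
        params, latent,
        _rng(params.seed, "loadings"), _rng(params.seed, "noise"), _rng(params.seed, "baseline"),
    )
    continuous = np.exp(log_expr)
    if kind == "counts":
        values = _rng(params.seed, "counts").poisson(continuous).astype(float)
    else:
        values = continuous
    gene_ids = [f"G{i:05d}" for i in range(params.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(params.n_samples)]
    expr = ExpressionMatrix(values, gene_ids, sample_ids, scale=kind)

    trait = np.zeros(params.n_samples)
    for m, eff in params.trait_effects.items():
        trait += eff * latent[:, m - 1]
    trait += _rng(params.seed, "trait").normal(0.0, params.pseudo_trait_noise_sd,
                                               size=params.n_samples)
    traits = pd.DataFrame({"inflammation": trait}, index=sample_ids)
    traits.index.name = "sample_id"
    truth = ModuleAssignment(labels=_module_labels(params), gene_ids=gene_ids)
    return expr, traits, truth, latent


# ---------------------------------------------------------------------------
# replication / therapy-response cohorts
# ---------------------------------------------------------------------------


@dataclass
class ResponseDataset:
    """One replication cohort with binary therapy-response labels."""

    expr: ExpressionMatrix
    response: pd.Series  # index sample_id, values "responder"/"nonresponder"
    study_id: str
    treatment: str
    regimen: str | None = None
    latent: np.ndarray | None = None  # samples x modules ground truth

    def __post_init__(self) -> None:
        counts = self.response.value_counts()
        if len(counts) < 2:
            raise DataError(f"study {self.study_id}: both response classes must be non-empty")


@dataclass
class ResponseSimParams:
    """Parameters of the replication-cohort generator.

    ``module_smd`` plants a standardized mean difference of the named
    modules' latent factors between nonresponders and responders (latent sd
    is 1, so the shift equals the SMD).  Each of the ``n_studies`` cohorts
    retains a random ``gene_overlap_fraction`` of the base gene universe.
    """

    n_responders: int = 50
    n_nonresponders: int = 50
    module_smd: Mapping[int, float] = field(default_factory=lambda: {1: 0.87})
    n_studies: int = 3
    gene_overlap_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise ParameterError("each response group needs >= 2 samples")
        if not (0 < self.gene_overlap_fraction <= 1):
            raise ParameterError("gene_overlap_fraction must lie in (0, 1]")
        if self.n_studies < 1:
            raise ParameterError("n_studies must be >= 1")


_TREATMENTS = ("anti-TNF", "corticosteroid", "anti-integrin")


def simulate_response_cohort(
    params: ResponseSimParams, base: BulkSimParams
) -> list[ResponseDataset]:
    """Simulate replication cohorts sharing the base cohort's gene universe.

    Module structure (gene symbols, module membership) matches ``base``;
    loadings and noise are redrawn per study.  Nonresponders' latent factors
    are shifted by ``module_smd[m]`` (in latent-sd units) for each planted
    module.
    """
    bad = [m for m in params.module_smd if not 1 <= m <= base.n_modules]
    if bad:
        raise ParameterError(f"module_smd refers to nonexistent modules: {bad}")
    n = params.n_responders + params.n_nonresponders
    gene_ids = np.array([f"G{i:05d}" for i in range(base.n_genes)])
    n_keep = int(np.floor(params.gene_overlap_fraction * base.n_genes))
    out = []
    for s in range(params.n_studies):
        study = f"study{s + 1}"
        latent = _rng(params.seed, study, "latent").normal(size=(n, base.n_modules))
        is_nonresponder = np.zeros(n, dtype=bool)
        is_nonresponder[params.n_responders :] = True
        for m, smd in params.module_smd.items():
            latent[is_nonresponder, m - 1] += smd
        log_expr = _bulk_log_signal(
            base, latent,
            _rng(params.seed, study, "loadings"),
            _rng(params.seed, study, "noise"),
            _rng(params.seed, study, "baseline"),
        )
        keep = np.sort(
            _rng(params.seed, study, "genes").choice(base.n_genes, size=n_keep, replace=False)
        )
        sample_ids = [f"{study}_S{i:04d}" for i in range(n)]
        expr = ExpressionMatrix(
            np.exp(log_expr[keep]), list(gene_ids[keep]), sample_ids, scale="tpm"
        )
        response = pd.Series(
            np.where(is_nonresponder, "nonresponder", "responder"),
            index=sample_ids, name="response",
        )
        out.append(
            ResponseDataset(
                expr=expr,
                response=response,
                study_id=study,
                treatment=_TREATMENTS[s % len(_TREATMENTS)],
                latent=latent,
            )
        )
    return out


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------


@dataclass
class CellSimParams:
    """Parameters of the droplet single-cell generator.

    Defaults are desk-scale: 3,000 cells x 1,000 genes, four clusters over
    three donors, lognormal library sizes around e^8 ≈ 3,000 UMIs and a
    mitochondrial gene subset drawing ~5% of each cell's reads.  Clusters
    listed in ``trajectory_clusters`` are laid end to end along a latent
    position in [0, 1] that tilts a block of gradient genes.
    """

    n_cells: int = 3000
    n_genes: int = 1000
    n_clusters: int = 4
    n_donors: int = 3
    cluster_mean_logfc: float = 1.0
    n_marker_genes: int = 25
    library_size_lognormal_mu: float = 8.0
    library_size_lognormal_sigma: float = 0.3
    n_mito_genes: int = 10
    mito_fraction_mean: float = 0.05
    mito_fraction_sd: float = 0.02
    trajectory_clusters: Sequence[int] = (1, 2, 3)
    trajectory_logfc: float = 2.0
    n_gradient_genes: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ParameterError("n_clusters must be >= 2")
        if self.n_donors < 1:
            raise ParameterError("n_donors must be >= 1")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ParameterError("n_cells and n_genes must be positive")
        if any(c not in range(self.n_clusters) for c in self.trajectory_clusters):
            raise ParameterError(
                "trajectory_clusters must be a subset of 0..n_clusters-1"
            )
        needed = self.n_mito_genes + self.n_clusters * self.n_marker_genes + self.n_gradient_genes
        if needed > self.n_genes:
            raise ParameterError("n_genes too small for mito + marker + gradient blocks")


def simulate_cells(params: CellSimParams) -> tuple[AnnData, pd.DataFrame]:
    """Simulate droplet UMI counts with clusters, donors and a trajectory.

    Per cell, a library size is drawn lognormally and UMIs are multinomial
    over gene proportions that depend on the cell's cluster (marker-gene
    blocks at ``cluster_mean_logfc``) and, for trajectory clusters, on a
    continuous position in [0, 1] tilting the gradient-gene block.
    Mitochondrial genes are renormalized to a per-cell target fraction.

    Returns ``(AnnData cells x genes, cell table)``; the cell table (also
    ``adata.obs``) carries donor, library, cluster, true pseudotime and a
    noisy 2-D embedding of the trajectory.
    """
    p = params
    gene_ids = [f"{MITO_PREFIX}{i + 1}" for i in range(p.n_mito_genes)] + [
        f"SC{i:04d}" for i in range(p.n_genes - p.n_mito_genes)
    ]
    mito = np.zeros(p.n_genes, dtype=bool)
    mito[: p.n_mito_genes] = True

    # gene blocks: per-cluster markers, then gradient genes, all non-mito
    start = p.n_mito_genes
    marker_idx = []
    for c in range(p.n_clusters):
        marker_idx.append(np.arange(start, start + p.n_marker_genes))
        start += p.n_marker_genes
    gradient_idx = np.arange(start, start + p.n_gradient_genes)

    base_logw = _rng(p.seed, "base_weights").normal(0.0, 1.0, size=p.n_genes)

    clusters = _rng(p.seed, "clusters").integers(0, p.n_clusters, size=p.n_cells)
    donors = _rng(p.seed, "donors").integers(0, p.n_donors, size=p.n_cells)
    libsize = np.maximum(
        1,
        np.round(
            _rng(p.seed, "libsize").lognormal(
                p.library_size_lognormal_mu, p.library_size_lognormal_sigma, size=p.n_cells
            )
        ).astype(int),
    )
    mito_target = np.clip(
        _rng(p.seed, "mito").normal(p.mito_fraction_mean, p.mito_fraction_sd, size=p.n_cells),
        0.005, 0.5,
    )

    # latent trajectory position in [0, 1] for cells of trajectory clusters
    traj = list(p.trajectory_clusters)
    pseudotime = np.full(p.n_cells, np.nan)
    u = _rng(p.seed, "pseudotime").uniform(size=p.n_cells)
    for rank, c in enumerate(traj):
        in_c = clusters == c
        pseudotime[in_c] = (rank + u[in_c]) / len(traj)

    count_rng = _rng(p.seed, "counts")
    rows = []
    for i in range(p.n_cells):
        logw = base_logw.copy()
        logw[marker_idx[clusters[i]]] += p.cluster_mean_logfc
        if np.isfinite(pseudotime[i]):
            logw[gradient_idx] += p.trajectory_logfc * (pseudotime[i] - 0.5)
        w = np.exp(logw - logw.max())
        prob = w / w.sum()
        # renormalize so mitochondrial mass hits the per-cell target exactly
        m = prob[mito].sum()
        prob[mito] *= mito_target[i] / m
        prob[~mito] *= (1.0 - mito_target[i]) / (1.0 - m)
        rows.append(sp.csr_matrix(count_rng.multinomial(libsize[i], prob)))
    x = sp.vstack(rows).astype(np.int64)

    emb_rng = _rng(p.seed, "embedding")
    embed = np.zeros((p.n_cells, 2))
    on_traj = np.isfinite(pseudotime)
    t = pseudotime[on_traj]
    # gentle arc so the embedding is genuinely 2-D (along-trajectory variance
    # dominates, as after a diffusion-like embedding of a 1-D process)
    embed[on_traj, 0] = 10.0 * t
    embed[on_traj, 1] = 16.0 * (t - 0.5) ** 2
    off = ~on_traj
    if off.any():
        centers = {c: (-5.0 - 3.0 * k, 5.0 + 3.0 * k)
                   for k, c in enumerate(sorted(set(clusters[off])))}
        embed[off] = np.array([centers[c] for c in clusters[off]])
    embed += emb_rng.normal(0.0, 0.3, size=embed.shape)

    obs = pd.DataFrame(
        {
            "donor": [f"D{d}" for d in donors],
            "library": [f"lib{d}" for d in donors],
            "cluster": pd.Categorical([f"C{c}" for c in clusters]),
            "pseudotime_true": pseudotime,
            "embed_x": embed[:, 0],
            "embed_y": embed[:, 1],
        },
        index=[f"CELL{i:05d}" for i in range(p.n_cells)],
    )
    var = pd.DataFrame({"mito": mito}, index=gene_ids)
    adata = AnnData(X=x, obs=obs, var=var)
    return adata, obs.copy()
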