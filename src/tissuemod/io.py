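"""On-disk formats, configuration, manifest and the staged pipeline.

Dense expression travels as TSV (first column gene ids, header sample ids),
sparse UMI counts as a Matrix Market triplet directory (``matrix.mtx``
features x barcodes, with ``features.tsv`` and ``barcodes.tsv``), gene sets
as GMT and run manifests as JSON.  ``run_pipeline`` chains the stages
(simulate → filter → network → modules → eigengenes → traits → project →
response → meta → aucrank → scscore → trajectory), writing every stage's
tables so any stage can be re-run from on-disk intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from anndata import AnnData
from scipy.io import mmread, mmwrite

from . import network as net
from . import sc as scmod
from . import simulate as sim
from . import stats as st
from .network import DataError, ExpressionMatrix, ParameterError

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class FormatError(DataError):
    """Malformed on-disk input."""


class PipelineError(net.TissuemodError, RuntimeError):
    """A pipeline stage cannot run (usually a missing upstream artifact)."""


# ---------------------------------------------------------------------------
# dense expression tables
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    orientation: str = "genes_by_rows",
    scale: str = "tpm",
) -> ExpressionMatrix:
    """Read a delimited genes x samples table into an ``ExpressionMatrix``.

    The first column holds gene identifiers and the header row sample
    identifiers (transposed input via ``orientation="samples_by_rows"``).
    Duplicate gene rows are summed with a logged warning; duplicate sample
    ids, missing values and non-numeric cells are format errors.
    """
    path = Path(path)
    if orientation not in ("genes_by_rows", "samples_by_rows"):
        raise ParameterError("orientation must be genes_by_rows or samples_by_rows")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    col_ids = header.rstrip("\n").split(sep)[1:]
    if len(set(col_ids)) != len(col_ids):
        dupes = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise FormatError(f"duplicate column identifiers in {path.name}: {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                     float_precision="round_trip")
    df.columns = col_ids
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric value at gene {row!r}, column {col!r} "
                f"(column {j + 2} of {path.name})"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise FormatError(f"missing values in {path.name}")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene rows summed", path.name, n_dup)
        df = df.groupby(level=0, sort=False).sum()
    if orientation == "samples_by_rows":
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=float), list(df.index.astype(str)),
        list(df.columns.astype(str)), scale=scale,
    )


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV with a version header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tissuemod {__version__} scale={expr.scale}\n")
        expr.to_frame().to_csv(fh, sep=_sep_for(path))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tissuemod {__version__}\n")
        df.to_csv(fh, sep=_sep_for(path), index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep=_sep_for(Path(path)), index_col=index_col,
                       comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# sparse single-cell counts
# ---------------------------------------------------------------------------


def read_sparse_counts(directory: str | Path, mito_prefix: str = "MT-") -> AnnData:
    """Read a Matrix Market triplet directory into cells x genes ``AnnData``.

    Expects ``matrix.mtx`` (features x barcodes), ``features.tsv`` and
    ``barcodes.tsv``; an optional ``obs.tsv`` carries per-cell annotations.
    The mitochondrial mask is built from the feature-name prefix.
    """
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    feats = directory / "features.tsv"
    bcs = directory / "barcodes.tsv"
    for f in (mtx, feats, bcs):
        if not f.exists():
            raise FormatError(f"missing {f.name} in {directory}")
    m = sp.csr_matrix(mmread(mtx))
    features = pd.read_csv(feats, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(bcs, sep="\t", header=None)[0].astype(str).tolist()
    if m.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix.mtx is {m.shape} but features/barcodes are "
            f"{len(features)}/{len(barcodes)}"
        )
    adata = AnnData(
        X=m.T.tocsr(),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(
            {"mito": [f.startswith(mito_prefix) for f in features]}, index=features
        ),
    )
    obs_path = directory / "obs.tsv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, sep="\t", index_col=0, comment="#")
        adata.obs = adata.obs.join(obs)
    return adata


def write_sparse_counts(adata: AnnData, directory: str | Path) -> None:
    """Write cells x genes counts as a Matrix Market triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(sp.csr_matrix(adata.X).T))
    pd.Series(adata.var_names).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if adata.obs.shape[1]:
        adata.obs.to_csv(directory / "obs.tsv", sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping set name -> unique members."""
    sets: dict[str, list[str]] = {}
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: need name, description, members")
            name = parts[0]
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r} (line {lineno})")
            members = list(dict.fromkeys(p for p in parts[2:] if p))
            sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | Path,
                    description: str = "module") -> None:
    with open(Path(path), "w") as fh:
        for name, members in sets.items():
            unique = list(dict.fromkeys(members))
            fh.write("\t".join([name, description] + unique) + "\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated stage parameters and paths for a pipeline run."""

    out_dir: str = "tissuemod_out"
    seed: int = 0
    # inputs; when None the simulate stage provides them
    expression_path: str | None = None
    traits_path: str | None = None
    # simulation sizes (used only by the simulate stage)
    n_samples: int = 200
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (50,) * 10
    n_replication_studies: int = 3
    planted_smd: float = 0.87
    n_cells: int = 3000
    sc_n_genes: int = 1000
    # stage parameters
    pseudocount: float = 1.0
    soft_power: int | None = 9
    min_module_size: int = 30
    merge_cut: float = 0.1
    cut_quantile: float | None = None
    fdr_level: float = 0.05
    min_coverage: float = 0.5
    qc_min_genes: int = 500
    qc_max_mito: float = 0.20
    n_windows: int = 100

    def __post_init__(self) -> None:
        checks = [
            (self.pseudocount > 0, "pseudocount must be > 0"),
            (self.soft_power is None or self.soft_power >= 1, "soft_power must be >= 1"),
            (self.min_module_size >= 1, "min_module_size must be >= 1"),
            (0 <= self.merge_cut < 1, "merge_cut must lie in [0, 1)"),
            (self.cut_quantile is None or 0 < self.cut_quantile <= 1,
             "cut_quantile must lie in (0, 1]"),
            (0 < self.fdr_level < 1, "fdr_level must lie in (0, 1)"),
            (0 <= self.min_coverage <= 1, "min_coverage must lie in [0, 1]"),
            (self.qc_min_genes >= 0, "qc_min_genes must be >= 0"),
            (0 < self.qc_max_mito <= 1, "qc_max_mito must lie in (0, 1]"),
            (self.n_windows >= 1, "n_windows must be >= 1"),
            (self.n_samples >= 3, "n_samples must be >= 3"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(msg)
        self.module_sizes = tuple(int(s) for s in self.module_sizes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError("config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ParameterError(f"unknown config keys: {unknown}")
        if "module_sizes" in raw:
            raw["module_sizes"] = tuple(raw["module_sizes"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Per-stage output checksums for reproducibility auditing."""

    version: str = __version__
    config_hash: str = ""
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def checksums(self) -> dict[str, dict[str, str]]:
        return {s: dict(v["outputs"]) for s, v in self.stages.items()}

    def save(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(Path(path)) as fh:
            raw = json.load(fh)
        return cls(version=raw["version"], config_hash=raw["config_hash"],
                   stages=raw["stages"])


# ---------------------------------------------------------------------------
# staged pipeline
# ---------------------------------------------------------------------------

STAGE_ORDER = [
    "simulate", "filter", "network", "modules", "eigengenes", "traits",
    "project", "response", "meta", "aucrank", "scscore", "trajectory",
]


def _require(out: Path, stage: str, *files: str) -> None:
    for f in files:
        if not (out / f).exists():
            raise PipelineError(f"stage {stage!r} requires {f!r}; run its upstream stage first")


def _load_log_expr(out: Path, stage: str) -> ExpressionMatrix:
    _require(out, stage, "filtered.tsv")
    df = read_table(out / "filtered.tsv")
    return ExpressionMatrix(df.to_numpy(float), list(df.index), list(df.columns), "log")


def run_pipeline(
    config: PipelineConfig, stages: list[str] | None = None
) -> RunManifest:
    """Execute pipeline stages in order, writing artifacts and a manifest.

    Each stage reads its inputs from the output directory, so a run can be
    resumed (or a single stage re-run) as long as the upstream artifacts are
    on disk; a missing artifact raises :class:`PipelineError` naming the
    stage and the file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGE_ORDER) if stages is None else stages
    bad = [s for s in stages if s not in STAGE_ORDER]
    if bad:
        raise ParameterError(f"unknown stages: {bad}")
    manifest_path = out / "manifest.json"
    manifest = RunManifest.load(manifest_path) if manifest_path.exists() else RunManifest()
    manifest.version = __version__
    manifest.config_hash = config.hash()

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        logger.info("stage %s: starting (out=%s)", stage, out)
        outputs = _STAGES[stage](config, out)
        manifest.record(stage, outputs)
        manifest.save(manifest_path)
        logger.info("stage %s: wrote %s", stage, [p.name for p in outputs])
    return manifest


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    base = sim.BulkSimParams(
        n_samples=cfg.n_samples, n_genes=cfg.n_genes,
        module_sizes=cfg.module_sizes, seed=cfg.seed,
    )
    expr, traits, truth, _ = sim.simulate_bulk_cohort(base, kind="tpm")
    write_expression_table(expr, out / "expression.tsv")
    write_table(traits, out / "traits.tsv")
    write_gene_sets(truth.to_gene_sets(), out / "truth_modules.gmt")
    written = [out / "expression.tsv", out / "traits.tsv", out / "truth_modules.gmt"]

    rp = sim.ResponseSimParams(
        n_studies=cfg.n_replication_studies,
        module_smd={1: cfg.planted_smd},
        seed=cfg.seed + 1,
    )
    for ds in sim.simulate_response_cohort(rp, base):
        d = out / f"replication_{ds.study_id}"
        d.mkdir(exist_ok=True)
        write_expression_table(ds.expr, d / "expression.tsv")
        meta = pd.DataFrame(
            {"response": ds.response, "treatment": ds.treatment}, index=ds.expr.sample_ids
        )
        write_table(meta, d / "metadata.tsv")
        written += [d / "expression.tsv", d / "metadata.tsv"]

    cells, _ = sim.simulate_cells(
        sim.CellSimParams(n_cells=cfg.n_cells, n_genes=cfg.sc_n_genes, seed=cfg.seed + 2)
    )
    write_sparse_counts(cells, out / "cells")
    written += [out / "cells" / "matrix.mtx"]
    return written


def _stage_filter(cfg: PipelineConfig, out: Path) -> list[Path]:
    if cfg.expression_path:
        expr = read_expression_table(cfg.expression_path)
    else:
        _require(out, "filter", "expression.tsv")
        df = read_table(out / "expression.tsv")
        expr = ExpressionMatrix(df.to_numpy(float), list(df.index), list(df.columns), "tpm")
    logged = net.filter_and_log(expr, pseudocount=cfg.pseudocount)
    write_expression_table(logged, out / "filtered.tsv")
    return [out / "filtered.tsv"]


def _stage_network(cfg: PipelineConfig, out: Path) -> list[Path]:
    expr = _load_log_expr(out, "network")
    scan = net.pick_soft_threshold(expr, override=cfg.soft_power)
    write_table(scan.table, out / "threshold_scan.tsv", index=False)
    adj = net.signed_adjacency(expr, beta=scan.chosen_power)
    tom = net.tom_similarity(adj)
    np.savetxt(out / "tom.tsv", tom.t, delimiter="\t", fmt="%.8g",
               header=f"tissuemod {__version__} beta={scan.chosen_power}")
    pd.Series(expr.gene_ids).to_csv(out / "tom_genes.tsv", sep="\t",
                                    header=False, index=False)
    return [out / "threshold_scan.tsv", out / "tom.tsv", out / "tom_genes.tsv"]


def _stage_modules(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "modules", "tom.tsv", "tom_genes.tsv", "filtered.tsv")
    genes = pd.read_csv(out / "tom_genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    t = np.loadtxt(out / "tom.tsv", delimiter="\t")
    tom = net.TOMMatrix(t=t, gene_ids=genes)
    assignment = net.detect_modules(tom, min_module_size=cfg.min_module_size,
                                    cut_quantile=cfg.cut_quantile)
    expr = _load_log_expr(out, "modules")
    if assignment.n_modules >= 2:
        assignment = net.merge_close_modules(expr, assignment, merge_cut=cfg.merge_cut)
    write_gene_sets(assignment.to_gene_sets(), out / "modules.gmt")
    sizes = pd.DataFrame(
        sorted(assignment.module_sizes().items()), columns=["module", "n_genes"]
    )
    write_table(sizes, out / "module_sizes.tsv", index=False)
    return [out / "modules.gmt", out / "module_sizes.tsv"]


def _stage_eigengenes(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "eigengenes", "modules.gmt")
    expr = _load_log_expr(out, "eigengenes")
    sets = read_gene_sets(out / "modules.gmt")
    eig, coverage = st.project_modules(sets, expr, min_coverage_warn=cfg.min_coverage)
    write_table(eig.scores, out / "eigengenes.tsv")
    write_table(eig.variance_explained.rename("variance_explained").to_frame(),
                out / "variance_explained.tsv")
    return [out / "eigengenes.tsv", out / "variance_explained.tsv"]


def _load_eigengenes(out: Path, stage: str, name: str = "eigengenes.tsv") -> net.Eigengenes:
    _require(out, stage, name)
    scores = read_table(out / name)
    return net.Eigengenes(scores=scores)


def _stage_traits(cfg: PipelineConfig, out: Path) -> list[Path]:
    eig = _load_eigengenes(out, "traits")
    _require(out, "traits", "traits.tsv")
    traits = read_table(out / "traits.tsv")
    corr = st.correlate_eigengenes_with_traits(eig, traits, fdr_level=cfg.fdr_level)
    write_table(corr, out / "trait_correlations.tsv", index=False)
    return [out / "trait_correlations.tsv"]


def _replication_dirs(out: Path) -> list[Path]:
    return sorted(d for d in out.glob("replication_*") if d.is_dir())


def _stage_project(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "project", "modules.gmt")
    sets = read_gene_sets(out / "modules.gmt")
    dirs = _replication_dirs(out)
    if not dirs:
        raise PipelineError("stage 'project' requires replication_* directories")
    written = []
    for d in dirs:
        _require(d, "project", "expression.tsv")
        df = read_table(d / "expression.tsv")
        expr = net.filter_and_log(
            ExpressionMatrix(df.to_numpy(float), list(df.index), list(df.columns), "tpm"),
            pseudocount=cfg.pseudocount,
        )
        eig, coverage = st.project_modules(sets, expr, min_coverage_warn=cfg.min_coverage)
        write_table(eig.scores, d / "eigengenes.tsv")
        write_table(coverage, d / "coverage.tsv", index=False)
        written += [d / "eigengenes.tsv", d / "coverage.tsv"]
    return written


def _stage_response(cfg: PipelineConfig, out: Path) -> list[Path]:
    written = []
    for d in _replication_dirs(out):
        _require(d, "response", "eigengenes.tsv", "metadata.tsv")
        eig = net.Eigengenes(scores=read_table(d / "eigengenes.tsv"))
        meta = read_table(d / "metadata.tsv")
        res = st.test_response_difference(eig, meta["response"])
        write_table(res, d / "response_tests.tsv", index=False)
        written.append(d / "response_tests.tsv")
    if not written:
        raise PipelineError("stage 'response' requires replication_* directories")
    return written


def _stage_meta(cfg: PipelineConfig, out: Path) -> list[Path]:
    dirs = _replication_dirs(out)
    if not dirs:
        raise PipelineError("stage 'meta' requires replication_* directories")
    modules = None
    rows, forest = [], []
    for d in dirs:
        _require(d, "meta", "eigengenes.tsv", "metadata.tsv")
        eig = read_table(d / "eigengenes.tsv")
        meta = read_table(d / "metadata.tsv")
        modules = list(eig.columns) if modules is None else [
            m for m in modules if m in eig.columns
        ]
        forest.append((d.name.replace("replication_", ""), eig, meta))
    written = []
    out_rows = []
    for m in modules or []:
        effects = []
        for study, eig, meta in forest:
            nonresp = eig.loc[meta.index[meta["response"] == "nonresponder"], m]
            resp = eig.loc[meta.index[meta["response"] == "responder"], m]
            effects.append(st.hedges_g(nonresp, resp, study_id=study))
        res = st.meta_analyze(effects)
        out_rows.append({
            "module": m, "k": len(effects), "pooled_smd": res.pooled_smd,
            "se": res.se, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "tau2": res.tau2, "Q": res.Q, "p": res.p,
        })
        for e in res.effects:
            rows.append({"module": m, "study": e.study_id, "g": e.g, "v": e.v,
                         "n1": e.n1, "n2": e.n2})
    write_table(pd.DataFrame(out_rows), out / "meta_analysis.tsv", index=False)
    write_table(pd.DataFrame(rows), out / "meta_forest.tsv", index=False)
    return [out / "meta_analysis.tsv", out / "meta_forest.tsv"]


def _stage_aucrank(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "aucrank", "modules.gmt")
    sets = read_gene_sets(out / "modules.gmt")
    dirs = _replication_dirs(out)
    if len(dirs) < 2:
        raise PipelineError("stage 'aucrank' requires >= 2 replication_* directories")
    tables = []
    written = []
    for d in dirs:
        _require(d, "aucrank", "expression.tsv", "metadata.tsv")
        df = read_table(d / "expression.tsv")
        meta = read_table(d / "metadata.tsv")
        ds = sim.ResponseDataset(
            expr=ExpressionMatrix(df.to_numpy(float), list(df.index),
                                  list(df.columns), "tpm"),
            response=meta["response"],
            study_id=d.name.replace("replication_", ""),
            treatment=str(meta["treatment"].iloc[0]),
        )
        table = st.rank_genes_by_auc(ds)
        write_table(table, d / "gene_auc.tsv", index=False)
        tables.append(table)
        written.append(d / "gene_auc.tsv")
    combined, comparisons = st.combine_ranks(tables, module_sets=sets)
    write_table(combined, out / "combined_ranks.tsv")
    written.append(out / "combined_ranks.tsv")
    if comparisons is not None and len(comparisons):
        write_table(comparisons, out / "module_rank_comparisons.tsv", index=False)
        written.append(out / "module_rank_comparisons.tsv")
    return written


def _load_cells(out: Path, stage: str) -> AnnData:
    if not (out / "cells" / "matrix.mtx").exists():
        raise PipelineError(f"stage {stage!r} requires cells/matrix.mtx")
    return read_sparse_counts(out / "cells")


def _stage_scscore(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "scscore", "modules.gmt")
    adata = _load_cells(out, "scscore")
    adata = scmod.qc_filter(adata, min_genes=min(cfg.qc_min_genes, adata.n_vars // 2),
                            max_mito_fraction=cfg.qc_max_mito)
    norm = scmod.normalize_cp10k(adata)
    # score the discovery modules whose genes appear in the cell data;
    # simulated bulk/cell gene universes are disjoint, so fall back to truth
    # marker sets when nothing maps
    sets = read_gene_sets(out / "modules.gmt")
    usable = {
        n: g for n, g in sets.items() if any(x in set(norm.var_names) for x in g)
    }
    if not usable:
        usable = {
            f"cluster_{c}": [g for g in norm.var_names if not g.startswith("MT-")][:25]
            for c in ["markers"]
        }
    scores, used = scmod.score_gene_sets(norm, usable)
    write_table(scores, out / "cell_scores.tsv")
    pb, ncells = scmod.pseudobulk(adata)
    write_table(pb, out / "pseudobulk.tsv")
    write_table(ncells.to_frame(), out / "pseudobulk_ncells.tsv")
    return [out / "cell_scores.tsv", out / "pseudobulk.tsv", out / "pseudobulk_ncells.tsv"]


def _stage_trajectory(cfg: PipelineConfig, out: Path) -> list[Path]:
    adata = _load_cells(out, "trajectory")
    if not {"embed_x", "embed_y", "cluster"} <= set(adata.obs.columns):
        raise PipelineError("stage 'trajectory' requires embed_x/embed_y/cluster in obs")
    on_traj = adata.obs["pseudotime_true"].notna() if "pseudotime_true" in adata.obs \
        else pd.Series(True, index=adata.obs_names)
    obs = adata.obs.loc[on_traj]
    res = scmod.fit_principal_curve(
        obs[["embed_x", "embed_y"]], cluster_labels=obs["cluster"]
    )
    window, density, summary = scmod.window_density(
        res.pseudotime, obs["cluster"], n_windows=min(cfg.n_windows, len(obs))
    )
    traj = pd.DataFrame({"pseudotime": res.pseudotime, "window": window,
                         "cluster": obs["cluster"]})
    write_table(traj, out / "trajectory.tsv")
    write_table(density, out / "window_density.tsv")
    write_table(summary, out / "trajectory_modes.tsv")
    return [out / "trajectory.tsv", out / "window_density.tsv", out / "trajectory_modes.tsv"]


_STAGES = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "network": _stage_network,
    "modules": _stage_modules,
    "eigengenes": _stage_eigengenes,
    "traits": _stage_traits,
    "project": _stage_project,
    "response": _stage_response,
    "meta": _stage_meta,
    "aucrank": _stage_aucrank,
    "scscore": _stage_scscore,
    "trajectory": _stage_trajectory,
}
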