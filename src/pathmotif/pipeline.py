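"""End-to-end orchestration: config → integrate → scan → classify → crosstalk.

A single YAML config drives the whole analysis. All thresholds default to
the framework's canonical constants (on-threshold 0.3, min 2 genes on,
q = 0.95 scaling, peak-width cutoff 0.35, motif/private percentiles 90/50)
and every run records a provenance block (package version, seed, config
hash) next to its outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import __version__, io, synthetic
from .dispersion import (
    build_embedding,
    classify_profiles,
    lower_bound_distribution,
    motif_tissue_table,
    profile_dispersion,
    upper_bound_distribution,
)
from .integration import (
    CellStateMatrix,
    cluster_dataset,
    intersect_and_concat,
    pseudobulk,
    qc_filter,
    renormalize_integrate,
)
from .interpathway import (
    extend_labels,
    match_trajectory,
    pairwise_ami,
    profile_centroids,
    rescale_to_reference,
    stage_mean_profiles,
)
from .profiles import PathwayDefinition, cluster_profiles, scale_pathway
from .recurrence import scan_pathway

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips through YAML unchanged."""

    out_dir: str = "pathmotif_out"
    seed: int = 0
    # input: either dataset directories (MTX trios) or a synthetic block
    dataset_dirs: list[str] = field(default_factory=list)
    synthetic: dict = field(default_factory=dict)
    pathways: list[str] = field(default_factory=list)  # JSON/TSV paths
    # QC / clustering
    qc: bool = False
    min_counts: int = 2000
    max_mito_frac: float = 0.2
    min_genes: int = 200
    leiden_resolution: float = 1.0
    cluster_by: str = "leiden"  # or an obs column holding given annotations
    # scaling / gating
    scale_quantile: float = 0.95
    on_threshold: float = 0.3
    min_genes_on: int = 2
    # scan
    k_min: int = 3
    k_max: int = 100
    n_rand: int = 100
    smooth_window: int = 1
    peak_width_cutoff: float = 0.35
    kopt_rule: str = "reach"
    # classification
    motif_percentile: float = 90.0
    private_percentile: float = 50.0
    n_rand_upper: int = 100
    n_hvg: int = 4000
    n_pc_integration: int = 50
    n_pc_dispersion: int = 100
    # optional trajectory input
    trajectory_cells: str = ""
    trajectory_stages: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.on_threshold < 1:
            raise ValueError("on_threshold must be in (0, 1)")
        if not 0 < self.scale_quantile <= 1:
            raise ValueError("scale_quantile must be in (0, 1]")
        if self.min_genes_on < 1 or self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("invalid clustering bounds")
        if not 0 < self.peak_width_cutoff <= 1:
            raise ValueError("peak_width_cutoff must be in (0, 1]")
        for p in (self.motif_percentile, self.private_percentile):
            if not 0 <= p <= 100:
                raise ValueError("percentiles must be in [0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(io.read_yaml(path) or {}))

    def to_yaml(self, path: str | Path) -> None:
        io.write_yaml(asdict(self), path)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def simulate_datasets(cfg: PipelineConfig) -> list[ad.AnnData]:
    """Generate the synthetic datasets described by the config's block."""
    blk = dict(cfg.synthetic)
    emit = {
        k: blk.pop(k)
        for k in ("n_datasets", "cells_per_state", "n_background", "gene_dropout")
        if k in blk
    }
    truth = synthetic.simulate_truth(seed=cfg.seed, **blk)
    return synthetic.emit_single_cell_datasets(truth, **emit)


def integrate_datasets(
    datasets: list[ad.AnnData], cfg: PipelineConfig
) -> tuple[CellStateMatrix, "object"]:
    """QC (optional), per-dataset clustering, pseudo-bulk, intersection,
    renormalization and 50-PC embedding."""
    per_dataset = []
    for i, adata in enumerate(datasets):
        ds_id = adata.uns.get("dataset_id", f"dataset{i}")
        if cfg.qc:
            adata = qc_filter(
                adata, cfg.min_counts, cfg.max_mito_frac, cfg.min_genes
            )
        if cfg.cluster_by == "leiden":
            labels = cluster_dataset(
                adata, n_pc=cfg.n_pc_integration,
                resolution=cfg.leiden_resolution, seed=cfg.seed,
            )
        else:
            labels = pd.factorize(adata.obs[cfg.cluster_by], sort=True)[0]
        per_dataset.append(pseudobulk(adata, labels, dataset_id=ds_id))
    merged = intersect_and_concat(per_dataset)
    return renormalize_integrate(
        merged, n_hvg=cfg.n_hvg, n_pc=cfg.n_pc_integration, seed=cfg.seed
    )


def analyze_pathway(
    states: CellStateMatrix,
    emb100,
    pw: PathwayDefinition,
    cfg: PipelineConfig,
    outdir: Path | None = None,
) -> dict:
    """Scale → gate → scan → cluster at k_opt → dispersion classification."""
    scaled = scale_pathway(
        states, pw, cfg.scale_quantile, cfg.on_threshold, cfg.min_genes_on
    )
    if scaled.n_on == 0:
        raise ValueError(f"pathway {pw.name}: no on-states")
    k_grid = np.arange(cfg.k_min, min(cfg.k_max, scaled.n_on - 1) + 1)
    scan = scan_pathway(
        scaled, k_grid, n_rand=cfg.n_rand, seed=cfg.seed,
        smooth_window=cfg.smooth_window, rule=cfg.kopt_rule,
    )
    labeling = cluster_profiles(scaled, scan.k_opt)
    disp = profile_dispersion(labeling, emb100)
    lower = lower_bound_distribution(emb100, scan.k_opt)
    upper = upper_bound_distribution(
        labeling, emb100, n_rand=cfg.n_rand_upper, seed=cfg.seed
    )
    report = classify_profiles(
        disp, lower, upper, labeling, cfg.motif_percentile, cfg.private_percentile
    )
    tables = motif_tissue_table(labeling, states.state_meta)
    full = extend_labels(labeling, scaled.on_mask)
    if outdir is not None:
        scan.to_json(outdir / f"{pw.name}.scan.json")
        io.write_labels(full, outdir / f"{pw.name}.labels.tsv")
        report.to_json(outdir / f"{pw.name}.dispersion.json")
        tables.by_organ.to_csv(outdir / f"{pw.name}.by_organ.tsv", sep="\t")
        tables.by_cell_class.to_csv(outdir / f"{pw.name}.by_class.tsv", sep="\t")
        scaled.values.to_csv(outdir / f"{pw.name}.scaled.tsv", sep="\t")
    classes = report.table["class"]
    return {
        "pathway": pw.name,
        "n_genes": pw.n_genes,
        "n_on_states": scaled.n_on,
        "k_opt": int(scan.k_opt),
        "recurrence": round(scan.recurrence, 1),
        "peak_width": round(scan.peak_width, 4),
        "excluded_wide_peak": bool(scan.excluded),
        "n_motifs": int((classes == "motif").sum()),
        "n_private": int((classes == "private").sum()),
        "_full_labels": full,
        "_scaled": scaled,
        "_labeling": labeling,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage and write a machine-readable summary."""
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.synthetic:
        datasets = simulate_datasets(cfg)
    elif cfg.dataset_dirs:
        datasets = [io.read_dataset_mtx(d) for d in cfg.dataset_dirs]
    else:
        raise ValueError("config needs dataset_dirs or a synthetic block")

    stage = "integrate"
    try:
        states, _emb50 = integrate_datasets(datasets, cfg)
        io.write_state_matrix(states, outdir / "states.tsv")
        stage = "embed"
        emb100 = build_embedding(
            states, n_hvg=cfg.n_hvg, n_pc=cfg.n_pc_dispersion, seed=cfg.seed
        )
        stage = "pathways"
        pathways = [_load_pathway(p) for p in cfg.pathways]
        results, labelings = [], {}
        for pw in pathways:
            res = analyze_pathway(states, emb100, pw, cfg, outdir)
            labelings[pw.name] = res.pop("_full_labels")
            res.pop("_scaled")
            res.pop("_labeling")
            results.append(res)
        stage = "crosstalk"
        if len(labelings) >= 2:
            ami = pairwise_ami(labelings)
            ami.to_csv(outdir / "ami.tsv", sep="\t")
        stage = "trajectory"
        if cfg.trajectory_cells and cfg.trajectory_stages:
            _run_trajectory(cfg, states, pathways, outdir)
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    summary = {
        "pathways": results,
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.digest(),
        },
    }
    io.write_json(summary, outdir / "summary.json")
    return summary


def _load_pathway(path: str) -> PathwayDefinition:
    p = Path(path)
    return (
        PathwayDefinition.from_json(p)
        if p.suffix == ".json"
        else PathwayDefinition.from_tsv(p)
    )


def _run_trajectory(
    cfg: PipelineConfig,
    states: CellStateMatrix,
    pathways: list[PathwayDefinition],
    outdir: Path,
) -> None:
    from .integration import _lognormalize

    dev = io.read_dataset_mtx(cfg.trajectory_cells) if Path(
        cfg.trajectory_cells
    ).is_dir() else io.read_dense_matrix(cfg.trajectory_cells)
    stages = pd.read_csv(cfg.trajectory_stages, sep="\t", index_col=0).iloc[:, 0]
    stages.index = stages.index.astype(str)
    logn = _lognormalize(dev)
    dev_df = pd.DataFrame(
        np.asarray(logn.X), index=logn.obs_names, columns=logn.var_names
    )
    for pw in pathways:
        scaled = scale_pathway(
            states, pw, cfg.scale_quantile, cfg.on_threshold, cfg.min_genes_on
        )
        labeling = cluster_profiles(scaled, max(2, min(6, scaled.n_on)))
        refs = profile_centroids(scaled, labeling)
        dev_scaled = rescale_to_reference(
            dev_df[[g for g in scaled.values.columns if g in dev_df.columns]], scaled
        )
        means = stage_mean_profiles(dev_scaled, stages)
        track = match_trajectory(means, refs)
        out = track.stage_means.copy()
        out["matched_profile"] = track.matched_profile
        out["match_distance"] = track.match_distance
        out.to_csv(outdir / f"{pw.name}.trajectory.tsv", sep="\t")
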