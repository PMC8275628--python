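"""Staged orchestration of the full analysis over one dataset.

:class:`PipelineConfig` collects every threshold, panel and seed; the
``run_*`` functions execute the stages in study order and
:func:`run_all` chains them, returning a :class:`PipelineResult` and
(optionally) writing TSV/JSON artifacts plus a machine-readable manifest.
The numbered scripts under ``analysis/`` are thin drivers over this module.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hepatoseq import clustering, coexpression, normalization, panels, ploidy, qc, variability, zonation
from hepatoseq.containers import CountMatrix, FilterReport, NormalizedMatrix
from hepatoseq.simulate import SimulationConfig, GroundTruth, simulate_dataset


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults equal the study's stated values."""

    seed: int
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    scale_constant: float = 10_000.0
    post_norm_max_total: float = 50_000.0
    batch_correct: bool = False
    n_pcs: int = 50
    k_neighbors: int = 15
    cluster_resolution: float = 1.0
    de_log2fc_threshold: float = 0.5
    de_alpha: float = 0.05
    ks_alpha: float = 0.05
    ks_d_threshold: float = 0.15
    hvg_top_fraction: float = 0.10
    coexpr_distance_threshold: float = 0.5
    coexpr_min_markers: int = 2
    zonation_n_clusters: int = 3
    n_bins: int = 10
    min_stratum_size: int = 10
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)


@dataclass
class PipelineResult:
    """Artifacts of a full run; stages not reached stay None."""

    counts: CountMatrix | None = None
    truth: GroundTruth | None = None
    filter_report: FilterReport | None = None
    normalized: NormalizedMatrix | None = None
    clusters: clustering.ClusterAssignment | None = None
    hepatocytes: NormalizedMatrix | None = None
    de_2n_4n: pd.DataFrame | None = None
    ks_2n_4n: pd.DataFrame | None = None
    detected_fold: float | None = None
    variability: variability.VariabilityResult | None = None
    hvg_2n: variability.HVGReport | None = None
    hvg_4n: variability.HVGReport | None = None
    jaccard: coexpression.JaccardResult | None = None
    modules: list[list[str]] | None = None
    coexpr_summary: pd.DataFrame | None = None
    zonation: zonation.ZonationAssignment | None = None
    enrichment: float | None = None
    bin_profiles: pd.DataFrame | None = None
    zonation_de: zonation.ZonationDEByPloidy | None = None


def _hep_masks(res: PipelineResult) -> tuple[np.ndarray, np.ndarray]:
    pl = res.hepatocytes.nuclei["ploidy"].astype(str)
    return (pl == "2n").to_numpy(), (pl == "4n").to_numpy()


def run_simulate(cfg: PipelineConfig, res: PipelineResult) -> PipelineResult:
    res.counts, res.truth = simulate_dataset(cfg.simulation)
    return res


def run_qc(cfg: PipelineConfig, res: PipelineResult) -> PipelineResult:
    if res.counts is None:
        raise RuntimeError("run_qc requires counts; run the simulate stage (or load data) first")
    filtered, res.filter_report = qc.apply_qc_filters(res.counts, cfg.qc_thresholds)
    res.counts = qc.drop_technical_replicates(filtered)
    return res


def run_normalize(cfg: PipelineConfig, res: PipelineResult) -> PipelineResult:
    if res.filter_report is None:
        raise RuntimeError("run_normalize requires QC output; run the qc stage first")
    sf = normalization.ercc_size_factors(res.counts)
    nm = normalization.normalize_eq1(res.counts, sf, scale_constant=cfg.scale_constant)
    nm = normalization.post_normalization_filter(nm, max_total=cfg.post_norm_max_total)
    # keep the count matrix aligned for count-based statistics downstream
    res.counts = res.counts.subset(res.counts.nuclei.index.isin(nm.nuclei.index).astype(bool), None)
    nm = normalization.log_transform(nm)
    if cfg.batch_correct:
        nm = normalization.batch_correct(nm)
    res.normalized = nm
    return res


def run_cluster(cfg: PipelineConfig, res: PipelineResult) -> PipelineResult:
    if res.normalized is None:
        raise RuntimeError("run_cluster requires normalized data; run the normalize stage first")
    ca = clustering.embed_and_cluster(
        res.normalized,
        n_pcs=cfg.n_pcs,
        k_neighbors=cfg.k_neighbors,
        resolution=cfg.cluster_resolution,
        seed=cfg.seed,
    )
    ca = clustering.annotate_clusters(ca, res.normalized, panels.load_celltype_panel())
    res.clusters = ca
    res.hepatocytes = clustering.subset_hepatocytes(res.normalized, ca)
    return res


def run_ploidy(cfg: PipelineConfig, res: PipelineResult) -> PipelineResult:
    if res.hepatocytes is None:
        raise RuntimeError("run_ploidy requires the hepatocyte subset; run the cluster stage first")
    m2, m4 = _hep_masks(res)
    hep_ids = res.hepatocytes.nuclei.index
    cm_hep_mask = res.counts.nuclei.index.isin(hep_ids)
    cm_hep = res.counts.subset(cm_hep_mask, None)
    pl = cm_hep.nuclei["ploidy"].astype(str)
    res.detected_fold = ploidy.detected_genes_fold(
        cm_hep, (pl == "2n").to_numpy(), (pl == "4n").to_numpy()
    )
    res.de_2n_4n = ploidy.welch_de(
        res.hepatocytes, m4, m2, log2fc_threshold=cfg.de_log2fc_threshold, alpha=cfg.de_alpha
    )
    res.ks_2n_4n = ploidy.ks_shift(
        res.hepatocytes, m2, m4, alpha=cfg.ks_alpha, d_threshold=cfg.ks_d_threshold
    )
    return res


def run_variability(cfg: PipelineConfig, res: PipelineResult) -> PipelineResult:
    if res.hepatocytes is None:
        raise RuntimeError("run_variability requires the hepatocyte subset")
    m2, m4 = _hep_masks(res)
    res.variability = variability.cv_compare(res.hepatocytes, m2, m4)
    de = res.de_2n_4n
    res.hvg_2n = variability.hvg_nonde_count(res.hepatocytes, m2, de, top_fraction=cfg.hvg_top_fraction)
    res.hvg_4n = variability.hvg_nonde_count(res.hepatocytes, m4, de, top_fraction=cfg.hvg_top_fraction)
    return res


def run_coexpression(cfg: PipelineConfig, res: PipelineResult) -> PipelineResult:
    if res.hepatocytes is None:
        raise RuntimeError("run_coexpression requires the hepatocyte subset")
    bm = coexpression.binarize(res.hepatocytes)
    bm = coexpression.subset_markers_drop_empty(bm, panels.load_stem_panel())
    res.jaccard = coexpression.pairwise_jaccard(bm)
    res.modules = coexpression.extract_modules(res.jaccard, cfg.coexpr_distance_threshold)
    pl = res.hepatocytes.nuclei["ploidy"].astype(str)
    res.coexpr_summary, _ = coexpression.coexpression_counts(bm, pl, min_markers=cfg.coexpr_min_markers)
    return res


def run_zonation(cfg: PipelineConfig, res: PipelineResult) -> PipelineResult:
    if res.hepatocytes is None:
        raise RuntimeError("run_zonation requires the hepatocyte subset")
    panel = panels.load_zonation_panel()
    za = zonation.assign_zonation(
        res.hepatocytes,
        panel,
        n_clusters=cfg.zonation_n_clusters,
        k_neighbors=cfg.k_neighbors,
        n_bins=cfg.n_bins,
        seed=cfg.seed,
    )
    res.zonation = za
    pl = res.hepatocytes.nuclei["ploidy"].astype(str)
    res.enrichment = zonation.ploidy_enrichment(za, pl)
    profile_genes = [g for g in panel.pericentral + panel.periportal + panel.non_zonated]
    res.bin_profiles = zonation.bin_profiles(za, res.hepatocytes, profile_genes, n_bins=cfg.n_bins)
    res.zonation_de = zonation.zonation_de_by_ploidy(
        res.hepatocytes, za, pl, min_group=cfg.min_stratum_size
    )
    return res


STAGES = {
    "simulate": run_simulate,
    "qc": run_qc,
    "normalize": run_normalize,
    "cluster": run_cluster,
    "ploidy": run_ploidy,
    "variability": run_variability,
    "coexpr": run_coexpression,
    "zonation": run_zonation,
}


def run_all(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage in study order; optionally write artifacts to ``outdir``."""
    res = PipelineResult()
    for stage_fn in STAGES.values():
        res = stage_fn(cfg, res)
    if outdir is not None:
        write_artifacts(cfg, res, outdir)
    return res


def write_artifacts(cfg: PipelineConfig, res: PipelineResult, outdir: str | Path) -> Path:
    """TSV/JSON exports plus a run manifest with seeds and thresholds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if res.filter_report is not None:
        (outdir / "filter_report.json").write_text(res.filter_report.to_json())
    if res.clusters is not None:
        res.clusters.table.to_csv(outdir / "clusters.tsv", sep="\t")
    if res.de_2n_4n is not None:
        res.de_2n_4n.to_csv(outdir / "de_4n_vs_2n.tsv", sep="\t")
        (outdir / "de_summary.json").write_text(json.dumps(ploidy.de_summary(res.de_2n_4n), indent=2))
    if res.ks_2n_4n is not None:
        res.ks_2n_4n.to_csv(outdir / "ks_2n_vs_4n.tsv", sep="\t")
    if res.jaccard is not None:
        res.jaccard.distance.to_csv(outdir / "jaccard_distance.tsv", sep="\t")
        (outdir / "modules.json").write_text(json.dumps(res.modules, indent=2))
    if res.zonation is not None:
        res.zonation.table.to_csv(outdir / "zonation.tsv", sep="\t")
        res.bin_profiles.to_csv(outdir / "bin_profiles.tsv", sep="\t")
    summary = {
        "detected_fold": res.detected_fold,
        "enrichment": res.enrichment,
        "cv_ratio_2n_over_4n": res.variability.ratio_of_medians if res.variability else None,
        "zonation_de_counts": res.zonation_de.counts() if res.zonation_de else None,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest = {
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(cfg).items() if not isinstance(v, dict) or k != "simulation"
        },
    }
    manifest["config"]["qc_thresholds"] = dataclasses.asdict(cfg.qc_thresholds)
    manifest["config"]["simulation"] = dataclasses.asdict(cfg.simulation)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
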