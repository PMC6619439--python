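"""End-to-end orchestration of the brain and microbiome analyses.

A single :class:`PipelineConfig` (seed, QC thresholds, normalization and
network settings, stage toggles) drives everything; inputs come either from
TSV paths or from the synthetic generator.  Every run writes its artifacts
plus a manifest (stage parameters and SHA-256 of each output file), so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as io_mod
from . import simulate
from .containers import CtMatrix, validate_sample_meta
from .diffexpr import differential_abundance, differential_table
from .dimred import centroid_distances, lda_project, pca_composite_weights
from .microbiome import classify_direction, fb_ratio, normalize_abundance, read_taxon_panel
from .network import build_network, edge_summary, write_network
from .normalization import genorm_m, normalize, select_reference_genes, zscore_by_gene
from .qc import exclude_failed_assays, sample_qc, validate_celltype_markers
from .subpheno import scan_bimodality

logger = logging.getLogger(__name__)

BRAIN_STAGES = ("qc", "normalize", "differential", "dimred", "network", "subpheno")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results"
    # inputs: paths to ct/meta/panel tables; None = simulate
    ct_path: str | None = None
    meta_path: str | None = None
    taxon_panel_path: str | None = None
    # QC
    failure_rule: float = 1.0
    max_missing_frac: float = 0.3
    hk_ct_range: tuple[float, float] = (5.0, 35.0)
    # normalization
    n_refs: int = 2
    control_gene: str = "Gapdh"
    centering_scope: str = "per-group"  # brain panels centered within cell type
    # network
    q_threshold: float = 1e-3
    min_pairs: int = 5
    # subphenotypes
    bimodal_min_group: int = 3
    bimodal_criterion: float = 6.0
    bimodal_conditions: tuple[str, ...] = ("Withdrawal",)
    # stage toggles
    stages: tuple[str, ...] = BRAIN_STAGES
    # simulation overrides (passed to the generator when no input paths)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hk_ct_range", "bimodal_conditions", "stages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig, outdir: Path):
        self.outdir = outdir
        self.data = {"config": config.to_dict(), "stages": {}, "files": {}}

    def stage(self, name: str, **params) -> None:
        self.data["stages"][name] = params

    def record(self, path: Path) -> None:
        self.data["files"][path.name] = _sha256(path)

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True, default=str))
        return path


def _load_or_simulate_brain(config: PipelineConfig):
    if config.ct_path is not None:
        ct = io_mod.read_ct_matrix(config.ct_path)
        meta = io_mod.read_sample_meta(config.meta_path)
        return ct, validate_sample_meta(meta, ct), None
    sim_cfg = simulate.default_brain_config(seed=config.seed, **config.sim)
    ct, meta, truth = simulate.generate_sc_qpcr(sim_cfg)
    return ct, meta, truth


def run_brain_pipeline(config: PipelineConfig) -> dict:
    """Run the brain stages in order; returns the in-memory artifact bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, outdir)
    bundle: dict = {}

    ct, meta, truth = _load_or_simulate_brain(config)
    bundle["meta"] = meta
    hk_candidates = [g for g in simulate.DEFAULT_HOUSEKEEPING_SD if g in ct.assay_ids]

    # --- QC
    ct, assay_report = exclude_failed_assays(ct, meta, failure_rule=config.failure_rule)
    ct, sample_report = sample_qc(
        ct,
        max_missing_frac=config.max_missing_frac,
        hk_genes=[g for g in hk_candidates if g in ct.assay_ids],
        hk_ct_range=config.hk_ct_range,
    )
    meta = meta.loc[ct.sample_ids]
    report = assay_report.merged_with(sample_report)
    bundle["qc_report"] = report
    path = outdir / "qc_report.tsv"
    io_mod.write_qc_report(report, path, outdir / "qc_report.json")
    manifest.stage("qc", failure_rule=config.failure_rule,
                   max_missing_frac=config.max_missing_frac,
                   n_datapoints_retained=report.n_datapoints_retained)
    manifest.record(path)
    if "qc" == config.stages[-1]:
        manifest.write()
        return bundle

    # --- normalization (per cell type centering by default)
    ranking = genorm_m(ct, [g for g in hk_candidates if g in ct.assay_ids])
    refs = select_reference_genes(
        ranking, n_refs=config.n_refs, never_select=(config.control_gene,)
    )
    expr, dropped = normalize(
        ct, refs,
        scope=config.centering_scope,
        groups=meta["cell_type"] if config.centering_scope == "per-group" else None,
        control_genes=(config.control_gene,),
    )
    meta = meta.loc[expr.values.index]
    bundle["stability"] = ranking
    bundle["references"] = refs
    bundle["expression"] = expr
    # marker validation needs the global scale: per-cell-type centering
    # zeroes every gene's median within its own cell type by construction
    if all(m in expr.values.columns for m in simulate.DEFAULT_MARKERS.values()):
        global_expr, _ = normalize(ct, refs, scope="global")
        bundle["marker_validation"] = validate_celltype_markers(
            global_expr.values, meta.loc[global_expr.values.index], simulate.DEFAULT_MARKERS
        )
    else:
        bundle["marker_validation"] = None
    zmat, _ = zscore_by_gene(expr)
    bundle["zscores"] = zmat

    stab_path = outdir / "stability_report.tsv"
    ranking.table.assign(selected=[g in refs for g in ranking.table.index]).to_csv(
        stab_path, sep="\t"
    )
    expr_path = outdir / "neg_ddct_matrix.tsv"
    expr.values.to_csv(expr_path, sep="\t", na_rep="NA")
    manifest.stage("normalize", references=refs, scope=config.centering_scope,
                   dropped_samples=[s for s, _ in dropped])
    manifest.record(stab_path)
    manifest.record(expr_path)

    if "differential" in config.stages:
        diff = differential_table(expr, meta)
        bundle["differential"] = diff
        p = outdir / "differential_expression.tsv"
        diff.to_csv(p, sep="\t")
        manifest.stage("differential", method="animal_means", n_genes=len(diff))
        manifest.record(p)

    if "dimred" in config.stages:
        weights = pca_composite_weights(expr)
        lda = lda_project(expr, meta["treatment"])
        cents = centroid_distances(lda.coords, meta["treatment"])
        bundle["composite_weights"] = weights
        bundle["lda"] = lda
        bundle["centroids"] = cents
        wp = outdir / "composite_weights.tsv"
        weights.table.to_csv(wp, sep="\t")
        cp = outdir / "centroid_distances.tsv"
        cents.distances.to_csv(cp, sep="\t")
        sp = outdir / "lda_coordinates.tsv"
        lda.coords.assign(treatment=meta["treatment"]).to_csv(sp, sep="\t")
        manifest.stage("dimred", n_discriminants=lda.coords.shape[1])
        for p in (wp, cp, sp):
            manifest.record(p)

    if "network" in config.stages:
        networks = []
        for (trt, cell), idx in meta.groupby(["treatment", "cell_type"]).groups.items():
            sub = expr.values.loc[idx, expr.analysis_genes()]
            net = build_network(
                sub, condition=f"{trt}:{cell}",
                q_threshold=config.q_threshold, min_pairs=config.min_pairs,
            )
            networks.append(net)
            safe = net.condition.replace(":", "_")
            ep = outdir / f"network_{safe}.tsv"
            write_network(net, ep, outdir / f"network_{safe}.graphml")
            manifest.record(ep)
        bundle["networks"] = networks
        summary = edge_summary(networks)
        bundle["edge_summary"] = summary
        ep = outdir / "edge_summary.tsv"
        summary["degree"].to_csv(ep, sep="\t")
        summary["edge_counts"].to_csv(outdir / "edge_counts.tsv", sep="\t")
        manifest.stage("network", q_threshold=config.q_threshold,
                       edge_counts=summary["edge_counts"].to_dict())
        manifest.record(ep)

    if "subpheno" in config.stages:
        calls = scan_bimodality(
            expr, meta,
            conditions=list(config.bimodal_conditions),
            min_group=config.bimodal_min_group,
            criterion_threshold=config.bimodal_criterion,
            seed=config.seed,
        )
        bundle["bimodality"] = calls
        p = outdir / "bimodality_calls.tsv"
        calls.to_csv(p, sep="\t", index=False)
        manifest.stage("subpheno", criterion=config.bimodal_criterion,
                       n_bimodal=int(calls["is_bimodal"].sum()))
        manifest.record(p)

    bundle["manifest_path"] = manifest.write()
    if truth is not None:
        bundle["ground_truth"] = truth
    return bundle


def run_microbiome_pipeline(config: PipelineConfig, mb_config=None) -> dict:
    """Microbiome stages: normalize, differential abundance, direction, ratio."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, outdir)
    bundle: dict = {}

    if config.ct_path is not None:
        ct = io_mod.read_ct_matrix(config.ct_path)
        meta = validate_sample_meta(io_mod.read_sample_meta(config.meta_path), ct)
        panel = read_taxon_panel(config.taxon_panel_path)
        truth = None
    else:
        mb_config = mb_config or simulate.MicrobiomeConfig(seed=config.seed)
        ct, meta, panel, truth = simulate.generate_microbiome(mb_config)

    expr, dropped = normalize_abundance(ct, panel)
    meta = meta.loc[expr.values.index]
    bundle["abundance"] = expr
    ap = outdir / "taxon_neg_ddct.tsv"
    expr.values.to_csv(ap, sep="\t", na_rep="NA")
    manifest.stage("normalize", references=panel.control_assays,
                   dropped_samples=[s for s, _ in dropped])
    manifest.record(ap)

    taxa = [a for a in expr.analysis_genes() if not panel.table.at[a, "is_control"]]
    results = differential_abundance(expr, meta, taxa=taxa)
    bundle["differential"] = results
    dp = outdir / "differential_abundance.tsv"
    results.to_csv(dp, sep="\t")
    manifest.record(dp)

    direction = classify_direction(results, expr, meta)
    bundle["direction"] = direction
    cp = outdir / "induced_suppressed.tsv"
    direction.to_csv(cp, sep="\t")
    manifest.record(cp)

    report = fb_ratio(expr, panel, meta, treatments=tuple(meta["treatment"].unique()))
    bundle["fb_ratio"] = report
    rp = outdir / "fb_ratio_table.tsv"
    report.to_frame().to_csv(rp, sep="\t")
    manifest.stage("ratio", display={k: v for k, v in report.display.items()})
    manifest.record(rp)

    bundle["manifest_path"] = manifest.write()
    if truth is not None:
        bundle["ground_truth"] = truth
    return bundle
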