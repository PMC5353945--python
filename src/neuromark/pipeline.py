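"""End-to-end orchestration of the discovery and biomarker phases.

A run is driven by one :class:`RunConfig` (YAML-loadable) holding either
paths to input files or a ``simulate`` block; a single seed derives per-stage
substreams so stages are individually reproducible. Every run emits its
stage artifacts plus a manifest recording the configuration snapshot, file
checksums, package version and timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .gene_sets import GeneSet, write_gmt, GeneSetCollection
from .network import (
    detect_modules,
    filter_seeded_modules,
    seed_neighborhoods,
    select_soft_power,
    topological_overlap,
)
from .prioritize import PriorityReport, module_gene_sets, prioritize_modules, negative_control_compare
from .screen import (
    derive_duration_set,
    derive_progression_set,
    load_gwas_set,
    screen_pathology_correlates,
    screen_to_frame,
)
from .study import ExpressionStudy, read_expression_tsv
from .synthetic import SimConfig, generate_edge_table, generate_study

__all__ = ["StageParams", "RunConfig", "RunManifest", "run_discovery", "run_biomarker"]


@dataclass
class StageParams:
    """Per-stage thresholds, defaulting to the published workflow's values."""

    screen_alpha: float = 0.01
    assessment_alpha: float = 0.05
    gwas_threshold: float = 5e-8
    seed_fraction: float = 0.01
    min_module_size: int = 30
    cut_height_quantile: float = 0.9
    soft_power_r2: float = 0.8
    n_pcs: int = 15
    csf_centile: float = 0.25
    expansion_min_edges: int = 2
    expansion_max_added: int = 12


@dataclass
class RunConfig:
    output_dir: str = "neuromark_run"
    seed: int = 0
    simulate: SimConfig | None = None
    cns_expression: str | None = None
    cns_clinical: str | None = None
    blood_expression: str | None = None
    blood_clinical: str | None = None
    gene_map: str | None = None
    gwas_table: str | None = None
    edge_table: str | None = None
    csf_table: str | None = None
    params: StageParams = field(default_factory=StageParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = d.pop("simulate", None)
        params = d.pop("params", None)
        cfg = cls(**d)
        if sim is not None:
            if "module_sizes" in sim:
                sim["module_sizes"] = tuple(sim["module_sizes"])
            if "duration_range_years" in sim:
                sim["duration_range_years"] = tuple(sim["duration_range_years"])
            cfg.simulate = SimConfig(**sim)
        if params is not None:
            cfg.params = StageParams(**params)
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            needed = ["cns_expression", "cns_clinical", "gene_map"]
            missing = [k for k in needed if getattr(self, k) is None]
            if missing:
                raise ConfigurationError(f"no simulate block and missing inputs: {missing}")
            for k in (
                "cns_expression",
                "cns_clinical",
                "blood_expression",
                "blood_clinical",
                "gene_map",
                "gwas_table",
                "edge_table",
                "csf_table",
            ):
                v = getattr(self, k)
                if v is not None and not Path(v).exists():
                    raise ConfigurationError(f"configuration error: {k} path {v} does not exist")


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str]  # relative path -> sha256
    summary: dict
    version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _snapshot(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _load_or_simulate(config: RunConfig):
    """Return (cns_study, blood_study, truth_or_none)."""
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        study = generate_study(sim)
        return study.cns, study.blood, study
    gene_map = pd.read_csv(config.gene_map).set_index("transcript_id")["gene_id"]
    cns = ExpressionStudy(
        read_expression_tsv(config.cns_expression),
        gene_map,
        pd.read_csv(config.cns_clinical, index_col=0),
    )
    blood = None
    if config.blood_expression and config.blood_clinical:
        blood = ExpressionStudy(
            read_expression_tsv(config.blood_expression),
            gene_map,
            pd.read_csv(config.blood_clinical, index_col=0),
        )
    return cns, blood, None


def run_discovery(config: RunConfig) -> RunManifest:
    """Screen -> seeding -> soft power/TOM -> modules -> seed filter -> prioritisation."""
    config.validate()
    params = config.params
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    cns, blood, sim = _load_or_simulate(config)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate the failing stage for diagnostics
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    screen_res = _stage("screen", screen_pathology_correlates, cns, params.screen_alpha)
    seeds = [r.transcript_id for r in screen_res if r.selected]
    if not seeds:
        raise RuntimeError("stage 'screen' produced no seeds")
    net = _stage("seeding", seed_neighborhoods, cns, seeds, params.seed_fraction)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        scan = _stage("soft_power", select_soft_power, net, r2_target=params.soft_power_r2)
    tom = _stage("tom", topological_overlap, net, scan.chosen_power)
    partition = _stage(
        "modules", detect_modules, tom, net.node_ids, params.min_module_size, params.cut_height_quantile
    )
    partition = _stage("seed_filter", filter_seeded_modules, partition, seeds)

    duration_set = _stage("duration_set", derive_duration_set, cns, params.assessment_alpha)
    if blood is not None:
        progression_set = _stage("progression_set", derive_progression_set, blood, params.assessment_alpha)
    else:
        raise ConfigurationError("blood expression required for the progression assessment set")
    if sim is not None:
        gwas_set = sim.truth["gwas_like"]
    elif config.gwas_table:
        gwas_set = _stage("gwas_set", load_gwas_set, config.gwas_table, params.gwas_threshold)
    else:
        raise ConfigurationError("gwas_table required (or a simulate block)")

    universe = GeneSet("measured genes", cns.measured_genes, "platform")
    report = _stage(
        "prioritize",
        prioritize_modules,
        partition,
        cns,
        [duration_set, progression_set, gwas_set],
        universe,
        params.assessment_alpha,
    )
    if sim is not None:
        control = GeneSet("identity control", sim.truth["control_identity_genes"])
        report.control_comparison = negative_control_compare(
            control, [duration_set, progression_set, gwas_set], universe
        )

    screen_to_frame(screen_res).to_csv(outdir / "screen.tsv", sep="\t", index=False)
    scan.to_frame().to_csv(outdir / "soft_power_scan.tsv", sep="\t", index=False)
    partition.to_frame(seeds).to_csv(outdir / "partition.tsv", sep="\t", index=False)
    write_gmt(
        GeneSetCollection([duration_set, progression_set, gwas_set]), outdir / "assessment_sets.gmt"
    )
    report.write(outdir / "priority_report")

    outputs = {
        p.name: _sha256(p)
        for p in [
            outdir / "screen.tsv",
            outdir / "soft_power_scan.tsv",
            outdir / "partition.tsv",
            outdir / "assessment_sets.gmt",
            outdir / "priority_report.tsv",
            outdir / "priority_report.json",
        ]
    }
    summary = {
        "n_seeds": len(seeds),
        "n_network_nodes": net.n_nodes,
        "chosen_power": scan.chosen_power,
        "n_modules": len(partition.module_numbers),
        "triple_enriched_modules": report.triple_enriched_modules,
    }
    manifest = RunManifest(_snapshot(config), outputs, summary, started=started,
                           finished=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.write(outdir / "discovery_manifest.json")
    return manifest


def run_biomarker(config: RunConfig, module: GeneSet | None = None) -> RunManifest:
    """Expansion -> blood evaluation -> CSF evaluation, aggregated into one report.

    ``module`` defaults to the top triple-enriched module of a prior
    discovery run found in the output directory.
    """
    from .blood import fit_ph_model, loocv_panel_accuracy, make_survival_design, per_gene_logistic_screen
    from .csf import assign_stage, compare_groups, load_csf_fixture, load_csf_table, stage_stratified_association, stage_summary
    from .expansion import enrichment_improvement, expand_module

    config.validate()
    params = config.params
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    cns, blood, sim = _load_or_simulate(config)
    if module is None:
        report_path = outdir / "priority_report.json"
        if not report_path.exists():
            raise ConfigurationError("no module supplied and no discovery report found")
        report = PriorityReport.from_json(report_path.read_text())
        if not report.triple_enriched_modules:
            raise ConfigurationError("discovery report has no triple-enriched module")
        partition_frame = pd.read_csv(outdir / "partition.tsv", sep="\t")
        top = int(report.triple_enriched_modules[0].split()[-1])
        transcripts = partition_frame.loc[partition_frame["module_number"] == top, "transcript_id"]
        module = GeneSet(f"module {top}", cns.genes_for(transcripts))
    if not module.members:
        raise ConfigurationError("empty module")

    universe = GeneSet("measured genes", cns.measured_genes, "platform")
    summary: dict = {"module": module.name, "module_size": len(module)}

    # --- expansion ------------------------------------------------------
    if config.edge_table is not None:
        edges = pd.read_csv(config.edge_table, sep="\t")
    elif sim is not None:
        edges = generate_edge_table(sim, n_partners=params.expansion_max_added, noise_edges=50)
    else:
        edges = None
    if edges is not None:
        expanded = expand_module(module, edges, params.expansion_min_edges, params.expansion_max_added)
        (outdir / "expanded_module.json").write_text(expanded.to_json())
        duration_set = derive_duration_set(cns, params.assessment_alpha)
        sets = [duration_set]
        if blood is not None:
            sets.append(derive_progression_set(blood, params.assessment_alpha))
        improvement = enrichment_improvement(module, expanded.expanded_set, sets, universe)
        summary["expansion"] = {
            "added": list(expanded.added_members),
            "improvement": improvement,
        }
        module_for_blood = expanded.expanded_set
    else:
        module_for_blood = module

    # --- blood ----------------------------------------------------------
    if blood is not None:
        design = make_survival_design(blood, module_for_blood, n_pcs=params.n_pcs)
        cox = fit_ph_model(design)
        gene_screen = per_gene_logistic_screen(blood, module_for_blood, params.assessment_alpha)
        gene_screen.to_csv(outdir / "blood_gene_screen.tsv", sep="\t", index=False)
        panel = list(gene_screen.head(3)["gene"]) if len(gene_screen) >= 3 else list(gene_screen["gene"])
        panel_fit = loocv_panel_accuracy(blood, panel)
        panel_fit.predictions.to_csv(outdir / "blood_panel_loocv.tsv", sep="\t", index=False)
        summary["blood"] = {
            "cox_lr_chi2": cox.lr_chi2,
            "cox_p": cox.p_value,
            "cox_df": cox.lr_df,
            "panel": list(panel_fit.gene_list),
            "panel_accuracy": panel_fit.accuracy,
            "panel_chance_p": panel_fit.chance_p,
            "panel_majority_baseline": panel_fit.majority_baseline,
        }

    # --- CSF ------------------------------------------------------------
    csf = load_csf_table(config.csf_table) if config.csf_table else load_csf_fixture()
    comparison = compare_groups(csf)
    stages = assign_stage(csf, params.csf_centile)
    per_stage = stage_summary(csf, stages)
    per_stage.to_csv(outdir / "csf_stage_summary.tsv", sep="\t", index=False)
    assoc = stage_stratified_association(csf, stages)
    summary["csf"] = {
        "mean_case": comparison.mean_case,
        "mean_control": comparison.mean_control,
        "mw_p_one_sided": comparison.mw.p_value,
        "mw_p_two_sided": comparison.mw_two_sided.p_value,
        "stage_means": {r["stage"]: r["mean_strem2_ng_ml"] for r in per_stage.to_dict("records")},
        "stage_association": {
            k: (v if isinstance(v, str) else {"rho": v.statistic, "p": v.p_value})
            for k, v in assoc.items()
        },
    }

    (outdir / "biomarker_report.json").write_text(json.dumps(summary, indent=1, default=str))
    outputs = {
        p.name: _sha256(p) for p in outdir.glob("*.json") if p.name != "biomarker_manifest.json"
    }
    outputs["biomarker_report.json"] = _sha256(outdir / "biomarker_report.json")
    manifest = RunManifest(_snapshot(config), outputs, summary, started=started,
                           finished=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.write(outdir / "biomarker_manifest.json")
    return manifest
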