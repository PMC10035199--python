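"""End-to-end orchestration: simulate -> quantify -> differential abundance
-> co-expression modules -> enrichment -> hot subnetworks -> cross-cohort
GESS validation -> cell-type enrichment.

One YAML-able config drives the whole chain; every stage writes plain-text
artifacts under the output directory and the run report (JSON) records
parameters, per-stage counts and a sha256 digest of every file, so two runs
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from protmod import io
from protmod.simulate import (
    SimConfig,
    generate_peptide_report,
    generate_validation_stats,
    generate_annotation_sets,
    generate_specificity_inputs,
    proteome_markers,
)
from protmod.quantify import quantify_report
from protmod.diffexp import beta_binomial_test, fit_bum, cluster_samples
from protmod.coexpression import build_similarity, detect_modules, test_module_dysregulation
from protmod.enrichment import go_overrepresentation
from protmod.subnetworks import build_module_graph, vertex_scores, find_hot_subnetworks
from protmod.gess import validate_all_modules
from protmod.celltype import compute_specificity, ewce_bootstrap, marker_direction_enrichment

logger = logging.getLogger("protmod")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters plus either a simulation config or input paths."""

    seed: int = 0
    simulate: SimConfig | None = None
    report_path: str | None = None  # alternative to simulation: read a report
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("tau", "control"), ("tdp", "control"), ("tau", "tdp")]
    )
    primary_contrast: tuple[str, str] = ("tau", "control")
    q_max: float = 0.01
    sample_fraction: float = 0.5
    top_k_peptides: int = 5
    soft_power: int = 7
    min_module_size: int = 15
    deep_split: int = 2
    fdr_levels: tuple[float, ...] = (0.05, 0.1, 0.2)
    top_n_cluster: int = 50
    edge_threshold: float = 0.5
    hotnet_beta: float = 0.5
    hotnet_n_perm: int = 100
    hotnet_max_modules: int | None = None  # None = all modules
    gess_thresholds: tuple[float, ...] = (0.1, 0.2, 0.5, 0.8)
    gess_n_perm: int = 1000
    n_boot: int = 20000
    n_annotation_terms: int = 30
    annotation_alignment: float = 0.5
    with_validation: bool = True
    with_celltype: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        cfg.primary_contrast = tuple(cfg.primary_contrast)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full chain; returns the run report (also written as JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    report: dict = {"seed": config.seed, "stages": {}, "counts": {}, "artifacts": {}}
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    def log_stage(name: str, **info):
        logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))
        report["stages"][name] = info

    # 1. input: simulate or load
    if config.simulate is not None:
        sim = config.simulate
        peptides, truth = generate_peptide_report(sim, seed=stage_seed[0])
        io.write_peptide_report(peptides, out / "peptide_report.tsv")
        (out / "ground_truth.json").write_text(json.dumps({
            "true_module_of": truth.true_module_of,
            "true_effect": truth.true_effect,
            "concordant_modules": list(truth.concordant_modules),
            "hot_members": truth.hot_members,
            "celltype_of_module": truth.celltype_of_module,
        }, indent=1, sort_keys=True))
        log_stage("simulate", n_proteins=sim.n_proteins, n_modules=len(sim.module_sizes),
                  seed=stage_seed[0])
    elif config.report_path is not None:
        peptides = io.read_peptide_report(config.report_path)
        truth = None
        log_stage("load", path=config.report_path, rows=len(peptides))
    else:
        raise ValueError("config needs either a simulation block or a report path")

    # 2. quantify
    matrix, groups = quantify_report(peptides, q_max=config.q_max,
                                     sample_fraction=config.sample_fraction,
                                     top_k=config.top_k_peptides)
    io.write_protein_matrix(matrix, groups, out / "protein_matrix.tsv")
    report["counts"]["proteins_quantified"] = int(len(matrix))
    log_stage("quantify", proteins=len(matrix), samples=matrix.shape[1])

    # 3. differential abundance + BUM thresholds
    contrast_results: dict[str, pd.DataFrame] = {}
    bum_info: dict[str, dict] = {}
    present = set(groups.values())
    for case, ref in config.contrasts:
        if case not in present or ref not in present:
            logger.warning("contrast %s:%s skipped (group absent)", case, ref)
            continue
        name = f"{case}_vs_{ref}"
        res = beta_binomial_test(matrix, groups, (case, ref))
        contrast_results[name] = res
        io.write_contrast(res, out / f"contrast_{name}.tsv")
        fit = fit_bum(res["pvalue"].to_numpy())
        thresholds = {str(f): fit.fdr_threshold(f) for f in config.fdr_levels}
        n_sig = {lvl: int((res["pvalue"] <= tau).sum()) for lvl, tau in thresholds.items()}
        bum_info[name] = {"lambda": fit.lambda_, "a": fit.a_, "pi_ub": fit.pi_ub_,
                          "tau": thresholds, "n_significant": n_sig}
        log_stage(f"diffexp_{name}", n_proteins=len(res), **{f"n_sig_fdr{k}": v for k, v in n_sig.items()})
    (out / "bum_fits.json").write_text(json.dumps(bum_info, indent=1, sort_keys=True))

    # 4. sample clustering on top hits
    if contrast_results:
        clust = cluster_samples(matrix, list(contrast_results.values()), top_n=config.top_n_cluster)
        pd.Series(clust.sample_order, name="sample").to_csv(out / "sample_order.tsv", sep="\t", index=False)
        log_stage("cluster_samples", top_n=len(clust.selected_proteins))

    # 5. co-expression modules + dysregulation
    sim_matrix = build_similarity(matrix, soft_power=config.soft_power)
    assignment = detect_modules(sim_matrix, min_size=config.min_module_size,
                                deep_split=config.deep_split)
    io.write_modules(dict(assignment), out / "modules.tsv")
    module_labels = sorted(set(assignment) - {"M00"})
    report["counts"]["modules_found"] = len(module_labels)
    log_stage("modules", n_modules=len(module_labels), unassigned=int((assignment == "M00").sum()))

    primary_name = f"{config.primary_contrast[0]}_vs_{config.primary_contrast[1]}"
    stats_tables = []
    for name, res in contrast_results.items():
        t = test_module_dysregulation(assignment, res)
        t["contrast"] = name
        stats_tables.append(t.reset_index())
    module_stats = pd.concat(stats_tables, ignore_index=True) if stats_tables else pd.DataFrame()
    if len(module_stats):
        module_stats.to_csv(out / "module_stats.tsv", sep="\t", index=False)
        n_dys = int(module_stats.loc[module_stats["contrast"] == primary_name, "dysregulated"].sum())
        report["counts"]["modules_dysregulated_primary"] = n_dys
        log_stage("module_stats", dysregulated_primary=n_dys)

    # 6. per-module GO over-representation on synthetic annotation terms
    if config.simulate is not None and truth is not None:
        sets = generate_annotation_sets(truth, n_terms=config.n_annotation_terms,
                                        alignment=config.annotation_alignment, seed=stage_seed[1])
        io.write_gmt(sets, out / "annotation_sets.gmt")
        background = set(matrix.index)
        ora_rows = []
        for lab in module_labels:
            members = set(assignment.index[assignment == lab]) & background
            tab = go_overrepresentation(members, sets, background).head(3)
            tab = tab.reset_index().assign(module=lab)
            ora_rows.append(tab)
        if ora_rows:
            pd.concat(ora_rows, ignore_index=True).to_csv(out / "module_ora.tsv", sep="\t", index=False)
        log_stage("ora", n_terms=len(sets))

    # 7. hot subnetworks per module on the primary contrast
    n_subnets = 0
    if primary_name in contrast_results:
        rows = []
        todo = module_labels[: config.hotnet_max_modules] if config.hotnet_max_modules else module_labels
        for j, lab in enumerate(todo):
            members = [p for p in assignment.index[assignment == lab]
                       if p in contrast_results[primary_name].index]
            if len(members) < 2:
                continue
            g = build_module_graph(matrix, members, edge_threshold=config.edge_threshold)
            sc = vertex_scores(contrast_results[primary_name], list(g.nodes))
            res = find_hot_subnetworks(g, sc, beta=config.hotnet_beta,
                                       n_perm=config.hotnet_n_perm,
                                       seed=stage_seed[2] + j)
            for si, subnet in enumerate(res.subnetworks):
                for p in subnet:
                    rows.append({"module": lab, "subnetwork": si, "protein": p,
                                 "score": float(sc[p]), "permutation_p": res.permutation_p})
            n_subnets += len(res.subnetworks)
        if rows:
            pd.DataFrame(rows).to_csv(out / "subnetworks.tsv", sep="\t", index=False)
        report["counts"]["subnetworks_found"] = n_subnets
        log_stage("subnetworks", n=n_subnets)

    # 8. cross-cohort GESS validation
    if config.with_validation and config.simulate is not None and truth is not None \
            and primary_name in contrast_results:
        val = generate_validation_stats(truth, config.simulate, seed=stage_seed[3])
        io.write_contrast(val, out / "validation_stats.tsv")
        gess_table = validate_all_modules(assignment, contrast_results[primary_name],
                                          {"validation": val},
                                          thresholds=config.gess_thresholds,
                                          n_perm=config.gess_n_perm, seed=stage_seed[4])
        if len(gess_table):
            gess_table.to_csv(out / "gess.tsv", sep="\t", index=False)
            n_val = int(gess_table["validated"].sum())
        else:
            n_val = 0
        report["counts"]["modules_validated"] = n_val
        log_stage("gess", validated=n_val)
    else:
        log_stage("gess", skipped=True)

    # 9. cell-type enrichment
    if config.with_celltype and config.simulate is not None and truth is not None:
        expr, markers = generate_specificity_inputs(config.simulate, seed=stage_seed[5], truth=truth)
        spec = compute_specificity(expr)
        background = sorted(set(matrix.index) & set(spec.index))
        # directional summaries need markers among the quantified proteins
        prot_markers = proteome_markers(expr, background)
        ewce_rows, dir_rows = [], []
        for j, lab in enumerate(module_labels):
            members = sorted(set(assignment.index[assignment == lab]) & set(background))
            if not members:
                continue
            e = ewce_bootstrap(members, spec, background, n_boot=config.n_boot,
                               seed=stage_seed[6] + j)
            ewce_rows.append(e.reset_index().assign(module=lab))
            if primary_name in contrast_results:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # modules without markers are fine
                    d = marker_direction_enrichment(members, contrast_results[primary_name], prot_markers)
                if len(d):
                    dir_rows.append(d.reset_index().assign(module=lab))
        if ewce_rows:
            pd.concat(ewce_rows, ignore_index=True).to_csv(out / "ewce.tsv", sep="\t", index=False)
        if dir_rows:
            pd.concat(dir_rows, ignore_index=True).to_csv(out / "marker_directions.tsv", sep="\t", index=False)
        log_stage("ewce", modules=len(ewce_rows))
    else:
        log_stage("ewce", skipped=True)

    report["runtime_s"] = round(time.time() - t_start, 2)
    for f in sorted(out.glob("*")):
        if f.name != "run_report.json" and f.is_file():
            report["artifacts"][f.name] = _sha256(f)
    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
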