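"""End-to-end orchestration of the synthetic demo pipeline.

``run_pipeline`` generates every input with one seed, pushes it through all
stages (morphometry, stratification, consensus peaks + differential
accessibility, methylome segmentation + DMRs, integration, TF networks) and
writes a results directory with a manifest listing every output and its row
count.  Stages can be toggled; a downstream stage whose inputs were toggled
off fails fast.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import integrate, methylome, morphometry, networks, regions, stratify
from . import synthetic

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "fibers", "stratify", "accessibility",
                  "methylome", "integration", "network")


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


_KNOWN_KEYS = {"seed", "outdir", "stages", "sim", "morphometry", "dar_fdr",
               "dmr", "network_min_expr"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    unknown = set(stages) - set(DEFAULT_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    sim_kwargs = dict(config.get("sim", {}))
    cfg = synthetic.SimConfig(seed=seed, **sim_kwargs)
    manifest: dict = {"seed": seed, "outputs": {}}

    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump({"seed": seed, "stages": list(stages), "sim": sim_kwargs}, fh)

    def record(name, path, n_rows):
        manifest["outputs"][name] = {"path": str(path), "rows": int(n_rows)}

    if "simulate" not in stages:
        raise ConfigError("the demo pipeline needs the simulate stage")

    # --- simulate -----------------------------------------------------------
    expr, deg_table, csa, gene_truth = synthetic.make_expression(cfg)
    slow_frac = synthetic.make_slow_fraction_phenotype(cfg)
    tracks, seg_truth, dmr_truth = synthetic.make_methylome(cfg)
    rep_sets, count_matrix, core, dar_truth = synthetic.make_peaks(cfg)
    tf_res = synthetic.make_tf_resources(cfg)
    gene_models = synthetic.make_gene_models(cfg)
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    deg_table.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)
    record("expression", outdir / "expression.tsv", len(expr))
    record("deg_table", outdir / "deg_table.tsv", len(deg_table))

    # --- fibers -------------------------------------------------------------
    if "fibers" in stages:
        rgb, _, truth = synthetic.make_fiber_image(cfg)
        params = morphometry.MorphometryParams(
            pixel_size_um=cfg.pixel_size_um, **config.get("morphometry", {}))
        _, records, summary = morphometry.run_morphometry(rgb, params)
        fiber_df = pd.DataFrame([r.__dict__ for r in records])
        fiber_df.to_csv(outdir / "fibers.tsv", sep="\t", index=False)
        with open(outdir / "fiber_summary.json", "w") as fh:
            json.dump(summary.__dict__, fh, indent=1)
        record("fibers", outdir / "fibers.tsv", len(fiber_df))

    # --- stratify -----------------------------------------------------------
    deg_sets = assignment = None
    if "stratify" in stages:
        deg_sets, deg_union = stratify.select_degs(deg_table)
        cor = stratify.spearman_phenotype(expr.loc[sorted(deg_union)], csa)
        cor = cor.dropna()
        som = stratify.fit_som_1d(cor["rho"].to_numpy(), seed=seed)
        groups = pd.Series(stratify.split_two_groups(som), index=cor.index)
        assignment = stratify.assign_tendencies(expr, groups, seed=seed)
        cor.to_csv(outdir / "correlation.tsv", sep="\t")
        assignment.to_csv(outdir / "assignment.tsv", sep="\t")
        record("correlation", outdir / "correlation.tsv", len(cor))
        record("assignment", outdir / "assignment.tsv", len(assignment))

    # --- accessibility ------------------------------------------------------
    annotated = dars = None
    consensus_by_stage = {}
    if "accessibility" in stages:
        stage_names = stratify.STAGES[: cfg.n_stages]
        for s in stage_names:
            reps = [rep_sets[f"{s}_{r + 1}"] for r in range(cfg.atac_reps_per_stage)]
            consensus_by_stage[s] = regions.consensus_peaks(reps)
        samples = count_matrix.columns
        early = [c for c in samples if c.split("_")[0] in stage_names[:2]]
        late = [c for c in samples if c.split("_")[0] in stage_names[2:]]
        region_map = {iv.name: iv for iv in core}
        dars = regions.differential_regions(
            count_matrix, early, late,
            comparison=f"{stage_names[0]}-{stage_names[-1]}",
            fdr_lt=float(config.get("dar_fdr", 0.1)), regions=region_map)
        annotated = [regions.annotate_feature(d.region, gene_models) for d in dars]
        dar_df = pd.DataFrame([{
            "region": d.region.name or f"{d.region.chrom}:{d.region.start}-{d.region.end}",
            "comparison": d.comparison, "log2_ratio": d.log2_ratio,
            "fdr": d.fdr, "category": a.category, "nearest_gene": a.nearest_gene,
        } for d, a in zip(dars, annotated)])
        dar_df.to_csv(outdir / "dars.tsv", sep="\t", index=False)
        record("dars", outdir / "dars.tsv", len(dar_df))

    # --- methylome ----------------------------------------------------------
    segments = dmrs = None
    if "methylome" in stages:
        stage_names = stratify.STAGES[: cfg.n_stages]
        first_track = tracks[f"{stage_names[0]}_1"]
        segments = methylome.segment_methylome(first_track)
        segments, wilcoxon_p = methylome.merge_lmr_umr(segments)
        seg_df = pd.DataFrame([s.__dict__ for s in segments])
        seg_df.to_csv(outdir / "segments.tsv", sep="\t", index=False)
        record("segments", outdir / "segments.tsv", len(seg_df))
        manifest["lmr_umr_wilcoxon_p"] = None if np.isnan(wilcoxon_p) else wilcoxon_p
        group_a = [tracks[k] for k in tracks if k.split("_")[0] in stage_names[:2]]
        group_b = [tracks[k] for k in tracks if k.split("_")[0] in stage_names[2:]]
        dmr_params = dict(config.get("dmr", {}))
        dmrs = methylome.call_dmrs(group_a, group_b, **dmr_params)
        dmr_df = pd.DataFrame([d.__dict__ for d in dmrs])
        dmr_df.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
        record("dmrs", outdir / "dmrs.tsv", len(dmr_df))

    # --- integration --------------------------------------------------------
    coreg_pairs = classes = None
    if "integration" in stages:
        if dars is None or dmrs is None or deg_sets is None:
            raise DataError("integration needs accessibility, methylome and "
                            "stratify outputs; enable those stages")
        coreg_pairs, quad = integrate.dar_deg_consistency(
            list(zip(dars, annotated)), deg_table)
        quad.to_csv(outdir / "dar_deg_quadrants.tsv", sep="\t", index=False)
        pd.DataFrame([p.__dict__ for p in coreg_pairs]).to_csv(
            outdir / "dar_deg_pairs.tsv", sep="\t", index=False)
        record("dar_deg_pairs", outdir / "dar_deg_pairs.tsv", len(coreg_pairs))
        _, deg_union = stratify.select_degs(deg_table)
        dmr_hosts = {
            regions.annotate_feature(d.interval, gene_models).nearest_gene
            for d in dmrs}
        dmr_genes = integrate.dmr_regulated_genes(dmr_hosts, deg_union)
        layout = synthetic.make_interaction_layout(cfg)
        layout_consensus = regions.consensus_peaks(layout["replicate_peaks"])
        classes = integrate.tss_window_classes(
            layout["genes"], layout_consensus, layout["track"])
        contrast = integrate.class_expression_contrast(classes, layout["expression"])
        contrast.to_csv(outdir / "class_expression.tsv", sep="\t")
        manifest["class_ordering_holds"] = contrast.attrs["ordering_holds"]
        classes.to_csv(outdir / "tss_classes.tsv", sep="\t")
        record("tss_classes", outdir / "tss_classes.tsv", len(classes))
        screen = integrate.slow_fiber_correlates(expr, slow_frac)
        screen.to_csv(outdir / "slow_fiber_correlates.tsv", sep="\t")
        record("dar_deg_quadrants", outdir / "dar_deg_quadrants.tsv", len(quad))
        record("class_expression", outdir / "class_expression.tsv", len(contrast))
        record("slow_fiber_correlates", outdir / "slow_fiber_correlates.tsv",
               len(screen))
        manifest["dmr_regulated_genes"] = sorted(dmr_genes)

    # --- network ------------------------------------------------------------
    if "network" in stages:
        if coreg_pairs is None:
            raise DataError("network needs the integration stage")
        stage_means = stratify.stage_mean_matrix(expr)
        pwms = [networks.PWM(tf, mat) for tf, mat in tf_res["pwms"].items()]
        hits = []
        for p in pwms:
            hits.extend(networks.scan_motifs(tf_res["sequences"], p))
        hit_tfs = sorted({h.tf for h in hits})
        validated = networks.validate_tf_expression(
            hit_tfs, stage_means, alias=tf_res.get("alias"),
            min_expr=float(config.get("network_min_expr", 1.0)))
        candidates = {p.gene for p in coreg_pairs} | set(tf_res["edges"]["target"])
        net = networks.build_network(validated, candidates, tf_res["edges"], "idr")
        net.to_frame().to_csv(outdir / "network_idr.tsv", sep="\t", index=False)
        with open(outdir / "network_summary.json", "w") as fh:
            json.dump(net.summary(), fh, indent=1)
        record("network_idr", outdir / "network_idr.tsv", len(net.edges))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
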