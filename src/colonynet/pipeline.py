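"""End-to-end orchestration from a single YAML/dict config.

Stage order mirrors the analysis: simulate (optional) -> preprocess ->
trait association -> enrichment -> coexpression network -> evolution.
Every stage writes its outputs under the run directory and contributes a
section to the JSON report; the config is echoed verbatim into the run
directory for provenance, and all randomness derives from the global seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, evolution, io, network, preprocess, simulate, traits as traits_mod

log = logging.getLogger("colonynet")

KNOWN_KEYS = {
    "outdir", "seed", "stages", "inputs", "simulate", "preprocess",
    "network", "enrichment", "evolution",
}
DEFAULT_STAGES = ("simulate", "preprocess", "traits", "enrich", "network", "evolve")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")


def _sim_config(cfg: dict, seed: int) -> simulate.SimConfig:
    block = dict(cfg.get("simulate", {}))
    modules = [simulate.ModuleSpec(**m) for m in block.pop("module_spec", [])] or None
    kwargs = {k: v for k, v in block.items() if k != "enabled"}
    if modules is not None:
        kwargs["module_spec"] = modules
    return simulate.default_config(seed=seed, **kwargs)


def run_pipeline(cfg: dict, outdir: str | Path | None = None) -> dict:
    """Run the enabled stages in order; returns the report dict.

    A stage failure raises with the stage name; outputs written before the
    failure are left in place.
    """
    validate_config(cfg)
    outdir = Path(outdir or cfg.get("outdir", "run"))
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    seed = int(cfg.get("seed", 0))
    stages = tuple(cfg.get("stages", DEFAULT_STAGES))
    report: dict = {"seed": seed, "stages": list(stages)}

    matrix = truth = colony_traits = annotations = dnds = None
    trait_table = modules = to = None

    try:
        stage = "simulate"
        if stage in stages:
            sim_cfg = _sim_config(cfg, seed)
            colony_traits = simulate.simulate_colony_traits(sim_cfg)
            matrix, truth = simulate.simulate_expression(sim_cfg, colony_traits)
            annotations = simulate.simulate_annotations(sim_cfg, truth)
            dnds = simulate.simulate_dnds(sim_cfg, truth)
            simulate.write_simulation(outdir / "simulated", matrix, truth,
                                      colony_traits, annotations, dnds)
            report[stage] = {"n_genes": matrix.n_genes, "n_samples": matrix.n_samples,
                             "n_terms": len(annotations)}
        else:
            inputs = cfg.get("inputs", {})
            matrix = io.read_expression(inputs["expression"], inputs["sample_meta"],
                                        unit=inputs.get("unit", "tpm"))
            colony_traits = io.read_traits(inputs["traits"])
            if "annotations" in inputs:
                annotations = enrichment.read_annotations(inputs["annotations"])
            if "dnds" in inputs:
                dnds = io.read_dnds(inputs["dnds"])

        stage = "preprocess"
        if stage in stages:
            pp = dict(cfg.get("preprocess", {}))
            matrix, reports = preprocess.preprocess_pipeline(matrix, **pp)
            (outdir / "filter_report.json").write_text(json.dumps(
                {k: (v.to_dict() if hasattr(v, "to_dict") else v)
                 for k, v in reports.items()}, indent=2))
            io.write_tsv(matrix.values, outdir / "expression_preprocessed.tsv")
            report[stage] = {"n_genes": matrix.n_genes, "n_samples": matrix.n_samples}

        stage = "traits"
        if stage in stages:
            trait_table = traits_mod.trait_correlation_table(matrix, colony_traits)
            io.write_tsv(trait_table.table, outdir / "trait_correlations.tsv")
            scores, var_exp = traits_mod.pca_samples(matrix, k=min(30, matrix.n_samples - 1))
            io.write_tsv(scores, outdir / "pca_scores.tsv")
            g, frac, p = traits_mod.sample_distance_network(matrix, seed=seed)
            io.write_edge_list(g, outdir / "sample_network_edges.tsv")
            agreement = {}
            for t in colony_traits.columns:
                r, r2, pv = traits_mod.correlation_method_agreement(
                    trait_table.table[f"r_sample_{t}"], trait_table.table[f"r_colony_{t}"])
                agreement[t] = {"r": r, "r2": r2, "p": pv}
            report[stage] = {
                "pca_var_explained_3": float(var_exp[:3].sum()),
                "nestmate_edge_fraction": frac, "nestmate_edge_p": p,
                "estimator_agreement": agreement,
            }

        stage = "enrich"
        if stage in stages and annotations is not None and trait_table is not None:
            blk = dict(cfg.get("enrichment", {}))
            alpha = blk.get("alpha", 0.05)
            sig = {}
            for t in colony_traits.columns:
                ranking = trait_table.summary_coefficient(t).dropna()
                res = enrichment.omnibus_enrichment(
                    ranking, annotations,
                    min_annotated=blk.get("min_annotated", 10),
                    direction=blk.get("direction", "top"))
                io.write_tsv(res.table, outdir / f"enrichment_{t}.tsv")
                sig[t] = int((res.table["p_corrected"] < alpha).sum())
            report[stage] = {"n_significant_terms": sig}

        stage = "network"
        if stage in stages:
            blk = dict(cfg.get("network", {}))
            params = network.NetworkParams(seed=seed, **blk)
            modules, to = network.iterative_density_filter(matrix, params)
            io.write_tsv(modules.labels.to_frame(), outdir / "module_labels.tsv")
            if modules.linkage_matrix is not None and to is not None:
                (outdir / "dendrogram.nwk").write_text(
                    network.dendrogram_to_newick(modules.linkage_matrix, to.index))
            if len(modules.module_names()):
                io.write_tsv(modules.eigengenes, outdir / "module_eigengenes.tsv")
                io.write_tsv(modules.kme.to_frame(), outdir / "module_kme.tsv")
                modules.quality_z = network.module_quality_z(
                    to, modules.labels, seed=seed)
                io.write_tsv(modules.summary(), outdir / "module_summary.tsv")
                net_matrix = matrix.subset(genes=to.index)
                mt = network.module_trait_analysis(
                    modules, net_matrix, colony_traits,
                    trait_r=trait_table.table if trait_table else None)
                io.write_tsv(mt["me_trait"], outdir / "module_trait.tsv")
                anova, contrasts = network.me_colony_comparison(
                    modules, net_matrix.colonies())
                io.write_tsv(anova, outdir / "me_colony_anova.tsv")
            report[stage] = {
                "n_modules": len(modules.module_names()),
                "module_sizes": modules.sizes(),
                "rounds": len(modules.filter_log),
            }

        stage = "evolve"
        if stage in stages and dnds is not None:
            raw = matrix.values
            table = evolution.build_dnds_table(
                dnds,
                median_tpm=raw.median(axis=1),
                expr_sd=raw.std(axis=1),
                trait_r=trait_table.table if trait_table else None,
                kme=modules.kme if modules is not None and len(modules.kme) else None,
                module_label=(modules.labels.replace({network.GREY: "none"})
                              if modules is not None else None),
            )
            io.write_tsv(table, outdir / "dnds_table.tsv")
            sect: dict = {}
            preds = [c for c in ("abs_r_sample_humidity", "abs_r_sample_da5ht",
                                 "kme", "median_tpm", "expr_sd") if c in table.columns]
            usable = table[["decile", *preds]].dropna()
            if len(usable) >= 30 and preds:
                glm = evolution.constraint_glm(table, predictors=tuple(preds))
                io.write_tsv(glm, outdir / "constraint_glm.tsv")
                sect["glm"] = glm["estimate"].to_dict()
            if "module" in table.columns and (table["module"] != "none").any():
                mods = [m for m in table["module"].unique() if m != "none"]
                mtests = [evolution.module_constraint_test(table, m) for m in mods]
                io.write_tsv(pd.DataFrame(mtests).set_index("module"),
                             outdir / "module_constraint.tsv")
                if (table["module"] == "none").sum() >= 3:
                    sect["in_module_vs_background"] = evolution.in_module_vs_background_test(table)
            report[stage] = sect or {"n_genes_with_dnds": int(table["decile"].notna().sum())}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (outdir / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
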