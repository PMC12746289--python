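"""End-to-end pipeline orchestration.

``run_pipeline`` drives simulate -> normalize -> dispersion -> DDR -> VPA
-> PERMANOVA -> NCM -> NST -> niche breadth -> network -> Y-A-S from a
single config mapping, writing tidy TSV/JSON artifacts plus a manifest
that echoes the resolved configuration, seed, and package version, so any
artifact can be regenerated from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import ncm_fit, niche_breadth, nst
from .core import (
    CommunityTable,
    SampleMetadata,
    alpha_diversity,
    bray_curtis,
    cpm_normalize,
    geo_distance,
    read_metadata,
    read_table,
    write_metadata,
    write_table,
)
from .dispersion import two_scale_homogeneity
from .network import (
    build_network,
    detect_modules,
    stability,
    write_edge_list,
    write_node_attributes,
    zi_pi,
)
from .simulate import SimConfig, simulate_paired_design, simulate_trait_table
from .spatial import ddr_fit, forward_select, pcnm, permanova, variation_partition
from .traits import cat_profile, compare_cat

logger = logging.getLogger(__name__)

DEFAULT_STAGES = (
    "dispersion", "ddr", "vpa", "permanova", "ncm", "nst", "niche",
    "network", "yas",
)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _dump_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict, out_dir) -> Path:
    """Run the enabled stages and return the output directory.

    ``config`` keys: ``seed`` (global seed), ``simulate`` (SimConfig
    fields; used when no ``inputs`` given), ``inputs`` (``table``,
    ``metadata``, optional ``trait_map`` paths), ``stages`` (name ->
    bool), and per-stage parameter mappings under the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = {name: True for name in DEFAULT_STAGES}
    stages.update(config.get("stages", {}))
    manifest = {"version": __version__, "seed": seed,
                "config": config, "stages_run": [], "artifacts": []}

    def emit(name: str):
        manifest["artifacts"].append(name)
        return out / name

    # ---- inputs ----------------------------------------------------
    trait_map = None
    if "inputs" in config:
        inputs = config["inputs"]
        table = read_table(inputs["table"], kind=inputs.get("kind", "asv"))
        metadata = read_metadata(inputs["metadata"]).aligned_to(table)
        if inputs.get("trait_map"):
            from .traits import read_trait_map
            trait_map = read_trait_map(inputs["trait_map"])
    else:
        sim_cfg = SimConfig(**{**config.get("simulate", {}), "seed": seed})
        table, metadata = simulate_paired_design(sim_cfg)
        trait_props = config.get("trait_proportions", (0.4, 0.35, 0.25))
        trait_map = simulate_trait_table(table.n_features, trait_props,
                                         seed=seed + 1,
                                         gene_ids=table.feature_ids)
        write_table(table, emit("counts.tsv"))
        write_metadata(metadata, emit("metadata.tsv"))
        trait_map.to_csv(emit("trait_map.tsv"), sep="\t", index=False)
        manifest["stages_run"].append("simulate")

    land_use = metadata.data.loc[table.sample_ids, "land_use"]
    dm = bray_curtis(table)
    alpha = alpha_diversity(table)
    alpha.data.to_csv(emit("alpha_diversity.tsv"), sep="\t")

    # ---- stages ----------------------------------------------------
    if stages.get("dispersion"):
        params = config.get("dispersion", {})
        report = two_scale_homogeneity(dm, metadata,
                                       method=params.get("test", "ranksum"),
                                       n_perm=params.get("n_perm", 999),
                                       seed=seed)
        zfrm = pd.DataFrame({
            "regional_z": report.regional.z,
            "local_z": report.local.z,
            "land_use": land_use,
        })
        zfrm.to_csv(emit("dispersion_z.tsv"), sep="\t", index_label="sample_id")
        _dump_json({"regional": report.regional_test,
                    "local": report.local_test},
                   emit("dispersion_tests.json"))
        manifest["stages_run"].append("dispersion")

    geo = geo_distance(metadata.aligned_to(table))
    if stages.get("ddr"):
        params = config.get("ddr", {})
        fit = ddr_fit(dm, geo, land_use.to_numpy(),
                      n_perm=params.get("n_perm", 999), seed=seed)
        fit.pairs.to_csv(emit("ddr_pairs.tsv"), sep="\t", index=False)
        _dump_json({"per_group": fit.per_group, "slope_diff": fit.slope_diff,
                    "slope_diff_p": fit.slope_diff_p},
                   emit("ddr_fit.json"))
        manifest["stages_run"].append("ddr")

    if stages.get("vpa"):
        params = config.get("vpa", {})
        env = metadata.aligned_to(table).env()
        basis = pcnm(geo)
        n_perm = params.get("n_perm", 199)
        env_sel = forward_select(table, env, n_perm=n_perm, seed=seed)
        spa_sel = forward_select(table, basis.vectors, n_perm=n_perm,
                                 seed=seed + 1)
        vpa = variation_partition(table,
                                  env[env_sel.selected] if env_sel.selected else None,
                                  basis.vectors[spa_sel.selected]
                                  if spa_sel.selected else None)
        _dump_json(dataclasses.asdict(vpa), emit("vpa.json"))
        manifest["stages_run"].append("vpa")

    if stages.get("permanova"):
        params = config.get("permanova", {})
        res = permanova(dm, land_use.to_numpy(),
                        n_perm=params.get("n_perm", 999), seed=seed)
        _dump_json(res, emit("permanova.json"))
        manifest["stages_run"].append("permanova")

    groups = {lu: [s for s in table.sample_ids if land_use[s] == lu]
              for lu in ("AS", "NS") if (land_use == lu).any()}

    if stages.get("ncm"):
        fits = {}
        taxa_frames = []
        for lu, samples in groups.items():
            sub = CommunityTable(table.data.loc[samples], table.feature_kind,
                                 table.normalization)
            fit = ncm_fit(sub)
            fits[lu] = {"m": fit.m, "N": fit.N, "Nm": fit.Nm, "r2": fit.r2}
            frame = fit.taxa.copy()
            frame["land_use"] = lu
            taxa_frames.append(frame)
        _dump_json(fits, emit("ncm.json"))
        pd.concat(taxa_frames).to_csv(emit("ncm_taxa.tsv"), sep="\t")
        manifest["stages_run"].append("ncm")

    if stages.get("nst"):
        params = config.get("nst", {})
        res = nst(table, land_use.to_numpy(),
                  null_model=params.get("null_model", "PF"),
                  n_null=params.get("n_null", 1000), seed=seed)
        res.pairs.to_csv(emit("nst_pairs.tsv"), sep="\t", index=False)
        _dump_json({"group_nst": res.group_nst, "null_model": res.null_model,
                    "n_null": res.n_null, "seed": res.seed},
                   emit("nst.json"))
        manifest["stages_run"].append("nst")

    if stages.get("niche"):
        summary = {}
        for lu, samples in groups.items():
            sub = CommunityTable(table.data.loc[samples], table.feature_kind,
                                 table.normalization)
            nb = niche_breadth(sub)
            summary[lu] = {"bcom": nb.bcom, "n_taxa": int(nb.b.size)}
        _dump_json(summary, emit("niche_breadth.json"))
        manifest["stages_run"].append("niche")

    if stages.get("network"):
        params = config.get("network", {})
        for lu, samples in groups.items():
            sub = CommunityTable(table.data.loc[samples], table.feature_kind,
                                 table.normalization)
            try:
                graph = build_network(
                    sub,
                    prevalence_min=params.get("prevalence_min", 0.25),
                    abundance_min=params.get("abundance_min", 1e-4),
                    r_min=params.get("r_min", 0.7),
                    p_max=params.get("p_max", 0.01),
                )
            except ValueError as exc:
                logger.warning("network stage skipped for %s: %s", lu, exc)
                continue
            if graph.number_of_edges() > 0:
                detect_modules(graph, seed=seed)
                roles = zi_pi(graph)
                roles.to_csv(emit(f"network_{lu}_roles.tsv"), sep="\t")
                if any(len(c) > 1 for c in nx.connected_components(graph)):
                    rep = stability(graph, removal="hubs", seed=seed)
                    _dump_json({"robustness_auc": rep.robustness_auc,
                                "vulnerability": rep.vulnerability,
                                "f_grid": rep.f_grid,
                                "robustness": rep.robustness},
                               emit(f"network_{lu}_stability.json"))
            write_edge_list(graph, emit(f"network_{lu}_edges.tsv"))
            write_node_attributes(graph, emit(f"network_{lu}_nodes.tsv"))
        manifest["stages_run"].append("network")

    if stages.get("yas") and trait_map is not None:
        gene_table = cpm_normalize(table)
        profile = cat_profile(gene_table, trait_map)
        profile.data.to_csv(emit("yas_profile.tsv"), sep="\t",
                            index_label="sample_id")
        comparison = compare_cat(profile, metadata)
        comparison.to_csv(emit("yas_compare.tsv"), sep="\t")
        manifest["stages_run"].append("yas")

    (out / "manifest.yaml").write_text(
        yaml.safe_dump(_jsonable(manifest), sort_keys=False))
    return out
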