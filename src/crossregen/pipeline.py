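"""End-to-end orchestration: config, validation, the full analysis cascade.

Stages run in the order of the underlying study: per-stratum differential
expression -> ortholog anchoring -> temporal-consistency filter ->
cross-species quadrant intersection -> gene-set and TF-target
overrepresentation -> interaction subnetworks with centrality/fold-change
correlation and TF-network fusion -> two-evidence pathway impact analysis.
Every filter logs its drop count and all tables land under the output
directory with a MANIFEST.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, intersect, io, network, spia

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    rat_expression: str
    axolotl_expression: str
    ortholog_map: str
    interactions: str
    go_gmt: str
    tft_gmt: str
    pathway_dir: str
    output_dir: str
    alpha: float = 0.05
    fc_cutoff: float = 1.5
    fc_scale: str = "linear"  # or "log"
    timepoints: tuple = ("d1", "d3", "d7")
    correlation: str = "spearman"
    score_min: float = 0.15
    score_max: float = 0.999
    n_boot: int = 2000
    seed: int = 0
    top_n: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "timepoints" in data:
            data["timepoints"] = tuple(data["timepoints"])
        return cls(**data)


@dataclass
class ValidationReport:
    errors: list = dc_field(default_factory=list)
    warnings: list = dc_field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(config: PipelineConfig) -> ValidationReport:
    """Schema-check every input file; distinguishes warnings from fatal errors."""
    rep = ValidationReport()
    if not (0.0 < config.alpha < 1.0):
        rep.errors.append(f"alpha must lie in (0, 1), got {config.alpha}")
    if config.fc_scale == "linear" and config.fc_cutoff <= 1.0:
        rep.errors.append("linear fold-change cutoff must exceed 1")
    if config.fc_scale == "log" and config.fc_cutoff <= 0.0:
        rep.errors.append("log fold-change cutoff must be positive")
    if config.fc_scale not in ("linear", "log"):
        rep.errors.append(f"unknown fc_scale {config.fc_scale!r}")
    for name in ("rat_expression", "axolotl_expression", "ortholog_map",
                 "interactions", "go_gmt", "tft_gmt", "pathway_dir"):
        if not Path(getattr(config, name)).exists():
            rep.errors.append(f"{name}: path {getattr(config, name)} does not exist")
    if rep.errors:
        return rep

    for name, species in (("rat_expression", "rat"), ("axolotl_expression", "axolotl")):
        try:
            expr = io.read_expression(getattr(config, name))
        except Exception as exc:  # pragma: no cover - defensive
            rep.errors.append(f"{name}: unreadable ({exc})")
            continue
        for tp in config.timepoints:
            for arm in ("injured", "control"):
                n = sum(c.startswith(f"{species}_{tp}_{arm}_") for c in expr.columns)
                if n < 2:
                    rep.errors.append(f"{name}: stratum {tp}/{arm} has {n} replicates (< 2)")
    try:
        io.read_ortholog_map(config.ortholog_map)
    except ValueError as exc:
        rep.errors.append(f"ortholog_map: {exc}")
    try:
        io.read_interactions(config.interactions)
    except ValueError as exc:
        rep.errors.append(f"interactions: {exc}")
    try:
        universe = set(io.read_ortholog_map(config.ortholog_map)["human_symbol"])
    except ValueError:
        universe = set()
    for name in ("go_gmt", "tft_gmt"):
        try:
            coll = io.read_gmt(getattr(config, name))
        except ValueError as exc:
            rep.errors.append(f"{name}: {exc}")
            continue
        if universe:
            _, dropped = enrichment.restrict_to_background(coll, universe)
            if dropped:
                rep.warnings.append(
                    f"{name}: {dropped} member genes outside the ortholog universe (dropped)"
                )
    pathways = sorted(Path(config.pathway_dir).glob("*.tsv"))
    if not pathways:
        rep.warnings.append(f"pathway_dir {config.pathway_dir} has no *.tsv pathways")
    for p in pathways:
        try:
            io.read_pathway(p)
        except ValueError as exc:
            rep.errors.append(f"pathway {p.name}: {exc}")
    return rep


def _anchor_strata(de_strata, ortho_map, species, drops):
    anchored = {}
    for tp, rec in de_strata.items():
        anchored[tp], n_drop = intersect.map_to_anchor(rec, ortho_map, species)
        drops[f"unmapped_{species}_{tp}"] = n_drop
    return anchored


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns a summary dict (also written as JSON).

    Deterministic given the config (including its seed). Any stage failure
    aborts with a stage-named error; outputs written so far stay on disk and
    the MANIFEST records the incompleteness.
    """
    rep = validate(config)
    if not rep.ok:
        raise ValueError("invalid config: " + "; ".join(rep.errors))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    drops: dict[str, int] = {}
    summary: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in vars(config).items()}}

    def emit(obj, name: str):
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=False)
        else:
            path.write_text(json.dumps(obj, indent=2, default=str) + "\n")
        manifest.append(name)

    def finish(complete: bool):
        (outdir / "MANIFEST").write_text(
            "\n".join([f"status\t{'complete' if complete else 'INCOMPLETE'}"] + manifest) + "\n"
        )

    stage = "load"
    try:
        rat_expr = io.read_expression(config.rat_expression)
        ax_expr = io.read_expression(config.axolotl_expression)
        ortho = intersect.OrthologMap(io.read_ortholog_map(config.ortholog_map))
        interactions = io.read_interactions(config.interactions)
        universe = set(io.read_ortholog_map(config.ortholog_map)["human_symbol"])
        go_coll, drops["go_gmt_outside_universe"] = enrichment.restrict_to_background(
            io.read_gmt(config.go_gmt, kind="go_like"), universe
        )
        tft_coll, drops["tft_gmt_outside_universe"] = enrichment.restrict_to_background(
            io.read_gmt(config.tft_gmt, kind="tft_like"), universe
        )
        pathway_files = sorted(Path(config.pathway_dir).glob("*.tsv"))
        pathways = [io.read_pathway(p) for p in pathway_files]

        stage = "diffexpr"
        de_kw = dict(alpha=config.alpha, fc_cutoff=config.fc_cutoff, fc_scale=config.fc_scale)
        rat_de = diffexpr.de_all_strata(rat_expr, "rat", config.timepoints, **de_kw)
        ax_de = diffexpr.de_all_strata(ax_expr, "axolotl", config.timepoints, **de_kw)
        for sp, strata in (("rat", rat_de), ("axolotl", ax_de)):
            for tp, table in strata.items():
                emit(table.reset_index(drop=True), f"de_{sp}_{tp}.tsv")

        stage = "intersect"
        rat_anchor = _anchor_strata(rat_de, ortho, "rat", drops)
        ax_anchor = _anchor_strata(ax_de, ortho, "axolotl", drops)
        quadrants = intersect.classify_quadrants(rat_anchor, ax_anchor)
        emit(quadrants.reset_index(drop=True), "shared_genes_quadrants.tsv")
        summary["group_summary"] = intersect.group_summary(quadrants).as_dict()
        emit(summary["group_summary"], "group_summary.json")
        for g in (1, 2, 3, 4):
            for sp in ("rat", "ax"):
                emit(intersect.top_genes(quadrants, g, config.top_n, sp).reset_index(drop=True),
                     f"top_genes_group{g}_{sp}.tsv")
        emit(intersect.parallel_coords(quadrants), "parallel_coordinates.tsv")
        shared_tp = {
            f"{label}_{tp}": sorted(genes)
            for label, direction in (("up", 1), ("down", -1))
            for tp, genes in intersect.shared_per_timepoint(rat_anchor, ax_anchor, direction).items()
        }
        emit({k: v for k, v in shared_tp.items()}, "shared_per_timepoint.json")
        summary["shared_per_timepoint_counts"] = {k: len(v) for k, v in shared_tp.items()}

        group_sets = {f"group{g}": set(quadrants.index[quadrants["group"] == g]) for g in (1, 2, 3, 4)}
        rat_up = group_sets["group2"] | group_sets["group4"]
        rat_down = group_sets["group1"] | group_sets["group3"]
        ax_up = group_sets["group1"] | group_sets["group2"]
        ax_down = group_sets["group3"] | group_sets["group4"]

        stage = "enrichment"
        summary["top_go_per_group"] = {}
        for label, genes in group_sets.items():
            table = enrichment.enrich(genes & go_coll.background, go_coll) if genes else pd.DataFrame()
            emit(table, f"go_enrichment_{label}.tsv")
            if len(table):
                summary["top_go_per_group"][label] = str(table.iloc[0]["term"])
        tft_classes = dict(group_sets, rat_up=rat_up, rat_down=rat_down,
                           ax_up=ax_up, ax_down=ax_down)
        tft_tables = enrichment.tft_rank(
            {k: v & tft_coll.background for k, v in tft_classes.items()}, tft_coll
        )
        summary["top_tf_per_class"] = {}
        for label, table in tft_tables.items():
            emit(table, f"tft_ranking_{label}.tsv")
            if len(table):
                summary["top_tf_per_class"][label] = str(table.iloc[0]["tf"])

        stage = "network"
        band = dict(score_min=config.score_min, score_max=config.score_max)
        corr_rows = []
        for label, genes in group_sets.items():
            sub = network.induce(interactions, genes, **band)
            io.write_network(sub, outdir / f"network_{label}")
            manifest += [f"network_{label}.graphml", f"network_{label}.tsv"]
        for sp, fc_col, strata in (
            ("rat", "avg_rat_fc", {"up": rat_up, "down": rat_down}),
            ("axolotl", "avg_ax_fc", {"up": ax_up, "down": ax_down}),
        ):
            for direction, genes in strata.items():
                sub = network.induce(interactions, genes, **band)
                if sub.number_of_nodes() == 0:
                    continue
                cents = network.centralities(sub)
                cents["avg_fc"] = quadrants.loc[cents.index, fc_col]
                emit(cents.reset_index(drop=True), f"centrality_{sp}_{direction}.tsv")
                corr = network.centrality_fc_correlation(cents, method=config.correlation)
                corr.insert(0, "species", sp)
                corr.insert(1, "direction", direction)
                corr_rows.append(corr)
        if corr_rows:
            corr_table = pd.concat(corr_rows, ignore_index=True)
            emit(corr_table, "centrality_fc_correlation.tsv")

        top_tf = summary["top_tf_per_class"].get("rat_up")
        if top_tf:
            rat_up_net = network.induce(interactions, rat_up, **band)
            fused, sizes = network.fuse_tf_network(
                top_tf, tft_coll.sets.get(top_tf, set()), rat_up_net, **band
            )
            io.write_network(fused, outdir / "fused_tf_network")
            manifest += ["fused_tf_network.graphml", "fused_tf_network.tsv"]
            summary["tf_fusion"] = {"tf": top_tf, **sizes}

        stage = "spia"
        rat_cons = intersect.consistent_set(rat_anchor)
        ax_cons = intersect.consistent_set(ax_anchor)
        spia_summaries = {}
        for sp, cons, fc_col in (("rat", rat_cons, "avg_rat_fc"), ("axolotl", ax_cons, "avg_ax_fc")):
            de_map = {
                g: float(quadrants.loc[g, fc_col]) for g in cons.index if g in quadrants.index
            }
            bg = set(ortho.table["human_symbol"])
            table = spia.spia_run(pathways, de_map, bg, n_boot=config.n_boot,
                                  alpha=config.alpha, seed=config.seed)
            emit(table, f"spia_{sp}.tsv")
            if len(table):
                best = table.iloc[0]
                spia_summaries[sp] = {"pathway": str(best["pathway"]),
                                      "p_g_adj": float(best["p_g_adj"]),
                                      "status": str(best["status"])}
        summary["spia_top"] = spia_summaries
        for pw in pathways:
            emit(spia.evidence_plot_data(pw, quadrants, rat_cons.index, ax_cons.index),
                 f"spia_evidence_{pw.name}.tsv")

        summary["drop_counts"] = drops
        emit(summary, "summary.json")
        finish(True)
        return summary
    except Exception as exc:
        finish(False)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
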