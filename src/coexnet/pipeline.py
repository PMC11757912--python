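"""End-to-end orchestration: preprocess -> dge -> wgcn -> coreprox -> ppin ->
association, with config validation, logging and a reproducible manifest."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import PipelineError, ValidationError
from .expression import ExpressionMatrix, read_gene_list
from . import association, coreprox, dge, ppin, preprocess, wgcn

STAGES = ("preprocess", "dge", "wgcn", "coreprox", "ppin", "association")

logger = logging.getLogger("coexnet")


@dataclass
class RunConfig:
    """All inputs and stage parameters for a full pipeline run."""

    counts: str = ""
    samples: str = ""
    edges: str = ""
    core_genes: str | None = None
    out_dir: str = "coexnet_out"
    seed: int = 0
    # preprocess
    min_count: int = 10
    min_fraction: float = 0.25
    per_batch_norm: bool = True
    skip_combat: bool = False
    # dge
    alpha: float = 0.05
    fc_min: float = 1.0
    # wgcn
    r_min: float = 0.7
    beta: float = 1.0
    # coreprox
    length_mode: str = "one_minus_sim"
    top_k_core: int = 10
    use_tom_lengths: bool = True
    # ppin
    min_combined_score: int = 400
    k_hub: float = ppin.K_HUB
    bc_hub: float = ppin.BC_HUB
    k_nonhub: float = ppin.K_NONHUB
    bc_nonhub: float = ppin.BC_NONHUB_DIRECT

    def violations(self, check_paths: bool = True) -> list[str]:
        errs = []
        if check_paths:
            for name in ("counts", "samples", "edges"):
                p = getattr(self, name)
                if not p:
                    errs.append(f"missing input path: {name}")
                elif not Path(p).exists():
                    errs.append(f"{name} path does not exist: {p}")
            if self.core_genes and not Path(self.core_genes).exists():
                errs.append(f"core_genes path does not exist: {self.core_genes}")
        if not (0.0 < self.alpha < 1.0):
            errs.append("alpha outside (0,1)")
        if self.fc_min < 0:
            errs.append("fc_min must be >= 0")
        if not (0.0 < self.r_min < 1.0):
            errs.append("r_min outside (0,1)")
        if self.beta < 1.0:
            errs.append("beta must be >= 1")
        if self.length_mode not in coreprox.LENGTH_MODES:
            errs.append(f"unknown length_mode {self.length_mode!r}")
        if self.min_combined_score < 0 or self.min_combined_score > 1000:
            errs.append("min_combined_score outside [0, 1000]")
        if not (0.0 <= self.min_fraction <= 1.0):
            errs.append("min_fraction outside [0,1]")
        if self.top_k_core < 1:
            errs.append("top_k_core must be >= 1")
        return errs


def validate_config(path) -> tuple[RunConfig | None, list[str]]:
    """Load a YAML config; return (config, []) or (None, all violations)."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except OSError as exc:
        return None, [f"cannot read config: {exc}"]
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    errs = [f"unknown config key: {k}" for k in unknown]
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    errs += cfg.violations()
    return (cfg, []) if not errs else (None, errs)


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default,
                               allow_nan=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing intermediate tables, a log and a manifest.

    The manifest (no timestamps, so reruns are byte-identical) records the
    parameters, per-stage row counts and output paths.  On stage failure a
    failure marker is written and PipelineError names the stage.
    """
    errs = config.violations()
    if errs:
        raise ValidationError("; ".join(errs))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {"package_version": __version__, "seed": config.seed,
                      "parameters": dataclasses.asdict(config), "stages": []}
    stage = "preprocess"
    try:
        # ------------------------------------------------------ preprocess
        logger.info("== stage preprocess ==")
        em = ExpressionMatrix.from_tsv(config.counts, config.samples)
        n_in = em.n_genes
        em = preprocess.filter_low_expression(em, config.min_count,
                                              config.min_fraction)
        factors = (preprocess.size_factors_per_batch(em) if config.per_batch_norm
                   else preprocess.size_factors(em))
        logem = preprocess.log_normalize(em, factors)
        single_batch = logem.batch_labels().nunique() == 1
        pc1_before = preprocess.pc_scores(logem, 1)["PC1"]
        r2_before = preprocess.batch_r_squared(pc1_before, logem.batch_labels())
        if config.skip_combat or single_batch:
            adjusted = logem.copy()
            adjusted.scale = "batch_adjusted"
        else:
            adjusted = preprocess.combat_adjust(logem)
        pc1_after = preprocess.pc_scores(adjusted, 1)["PC1"]
        r2_after = preprocess.batch_r_squared(pc1_after, adjusted.batch_labels())
        adjusted.to_tsv(out / "normalized.tsv")
        manifest["stages"].append({
            "name": "preprocess", "genes_in": n_in, "genes_out": adjusted.n_genes,
            "samples": adjusted.n_samples,
            "pc1_batch_r2_before": float(r2_before),
            "pc1_batch_r2_after": float(r2_after),
            "combat_applied": not (config.skip_combat or single_batch)})

        # ------------------------------------------------------------- dge
        stage = "dge"
        logger.info("== stage dge ==")
        results = dge.moderated_t(adjusted)
        table = dge.deg_table(results, alpha=config.alpha, fc_min=config.fc_min)
        table.index.name = "gene"
        table.to_csv(out / "deg_table.tsv", sep="\t")
        up = list(table.index[table["direction"] == dge.UP])
        down = list(table.index[table["direction"] == dge.DOWN])
        sig = list(table.index[table["padj"] < config.alpha])
        manifest["stages"].append({"name": "dge", "genes_tested": len(table),
                                   "significant": len(sig), "up": len(up),
                                   "down": len(down)})

        # ------------------------------------------------------------ wgcn
        stage = "wgcn"
        logger.info("== stage wgcn ==")
        deg_genes = up + down
        if len(deg_genes) < 3:
            raise ValidationError("fewer than 3 DEGs; cannot build a network")
        net = wgcn.correlation_network(adjusted, deg_genes,
                                       r_min=config.r_min, beta=config.beta)
        giant = wgcn.giant_component(net)
        wgcn.node_weights_from_edges(giant)
        tom_mat = wgcn.tom(giant)
        wgcn.write_edge_list(giant, out / "wgcn_edges.tsv")
        tom_out = tom_mat.copy()
        tom_out.index.name = "node"
        tom_out.to_csv(out / "tom.tsv", sep="\t")
        manifest["stages"].append({
            "name": "wgcn", "candidate_genes": len(deg_genes),
            "network_nodes": net.number_of_nodes(),
            "giant_nodes": giant.number_of_nodes(),
            "giant_edges": giant.number_of_edges()})

        # -------------------------------------------------------- coreprox
        stage = "coreprox"
        logger.info("== stage coreprox ==")
        giant_nodes = set(giant.nodes)
        core: list[str] = []
        if config.core_genes:
            core = [g for g in read_gene_list(config.core_genes)
                    if g in giant_nodes]
        if not core:
            ranked = table.loc[[g for g in giant_nodes if g in table.index]]
            ranked = ranked.reindex(ranked["log2fc"].abs()
                                    .sort_values(ascending=False).index)
            core = list(ranked.index[:min(config.top_k_core,
                                          max(1, len(ranked) - 1))])
        source = tom_mat if config.use_tom_lengths else giant
        lengths = coreprox.edge_lengths(source, mode=config.length_mode)
        sp = coreprox.all_pairs_dijkstra(lengths)
        dtable = coreprox.d_score(sp, core)
        dtable.to_csv(out / "dscores.tsv", sep="\t")
        subnet, counts = coreprox.core_subnetwork(giant, dtable)
        wgcn.write_edge_list(subnet, out / "core_subnetwork_edges.tsv")
        manifest["stages"].append({"name": "coreprox", **counts})

        # ------------------------------------------------------------ ppin
        stage = "ppin"
        logger.info("== stage ppin ==")
        graph = ppin.read_string_edges(config.edges,
                                       min_combined_score=config.min_combined_score)
        if graph.number_of_nodes() == 0:
            raise ValidationError("no interactions pass the score threshold")
        stats = ppin.node_stats(graph)
        labels = ppin.classify_nodes(stats, graph, k_hub=config.k_hub,
                                     bc_hub=config.bc_hub,
                                     k_nonhub=config.k_nonhub,
                                     bc_nonhub_direct=config.bc_nonhub)
        stats["label"] = labels
        stats.to_csv(out / "node_stats.tsv", sep="\t")
        metrics = ppin.network_metrics(graph)
        _write_json(out / "network_metrics.json", metrics)
        clustering = ppin.greedy_modularity_clusters(graph)
        pd.Series(clustering.assignments, name="cluster").rename_axis("node") \
            .sort_index().to_csv(out / "clusters.tsv", sep="\t")
        manifest["stages"].append({
            "name": "ppin", "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
            "hubs": int((labels == ppin.HUB).sum()),
            "nonhubs": int((labels == ppin.NONHUB).sum()),
            "clusters": len(set(clustering.assignments.values())),
            "modularity_q": float(clustering.modularity_q)})

        # ----------------------------------------------------- association
        stage = "association"
        logger.info("== stage association ==")
        in_matrix = set(adjusted.values.index)
        groups = {g: "hub" for g in labels.index[labels == ppin.HUB]
                  if g in in_matrix}
        groups.update({g: "nonhub" for g in labels.index[labels == ppin.NONHUB]
                       if g in in_matrix})
        focal_pool = table.loc[[g for g in table.index if g not in groups]]
        if len(focal_pool):
            focal = focal_pool["log2fc"].idxmin()
            groups[focal] = "focal"
        if len(groups) >= 2:
            report = association.pairwise_pearson(adjusted, groups)
            summary = association.sign_summary(report, alpha=config.alpha)
            report.to_csv(out / "correlations.tsv", sep="\t", index=False)
            _write_json(out / "correlation_summary.json",
                        summary.to_dict(orient="records"))
            manifest["stages"].append({"name": "association",
                                       "grouped_genes": len(groups),
                                       "pairs": len(report)})
        else:
            manifest["stages"].append({"name": "association",
                                       "grouped_genes": len(groups),
                                       "pairs": 0, "note": "too few grouped genes"})

        manifest["status"] = "ok"
        _write_json(out / "manifest.json", manifest)
        logger.info("pipeline complete: %d stages", len(manifest["stages"]))
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(out / "manifest.json", manifest)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
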