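"""Synthetic data with known ground truth for every downstream stage.

Generates negative-binomial count matrices for a two-condition, multi-batch
design with planted differentially expressed genes and a planted co-expressed
core module, plus interaction graphs with known hubs and nonhubs, and writes
them in the plain-text dialects the pipeline consumes.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .expression import ExpressionMatrix

GRAPH_MODELS = ("planted_hub", "erdos_renyi", "barabasi_albert")

# residual log2-scale noise added on top of the NB sampling noise; the
# per-batch scale effect multiplies this term so that location/scale
# adjustment has something to estimate
_BASE_EXTRA_SD = 0.15
_CORE_LOADING = 0.8


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the count and graph simulators; same seed, same bytes out."""

    n_genes: int = 2000
    n_tumor: int = 10
    n_normal: int = 10
    n_batches: int = 2
    de_fraction: float = 0.05
    log2fc_effect: float = 2.0
    nb_dispersion: float = 0.1
    batch_shift_sd: float = 0.0
    batch_scale_sd: float = 0.0
    libsize_range: tuple[float, float] = (0.7, 1.4)
    core_module_size: int = 15
    graph_model: str = "planted_hub"
    seed: int = 0
    # graph-model specific knobs
    n_hubs: int = 2
    n_nonhubs: int = 6
    n_fillers_per_hub: int = 14
    graph_nodes: int = 50
    er_p: float = 0.1
    ba_m: int = 2

    def __post_init__(self) -> None:
        errs = []
        for name in ("n_genes", "n_tumor", "n_normal"):
            if getattr(self, name) < 1:
                errs.append(f"{name} must be >= 1")
        if self.n_batches < 1:
            errs.append("n_batches must be >= 1")
        if not (0.0 <= self.de_fraction < 1.0):
            errs.append("de_fraction must lie in [0, 1)")
        elif self.de_fraction > 0 and self.de_fraction * self.n_genes < 1:
            errs.append("de_fraction * n_genes must be >= 1 when nonzero")
        if self.log2fc_effect < 0:
            errs.append("log2fc_effect must be >= 0")
        if self.nb_dispersion <= 0:
            errs.append("nb_dispersion must be > 0")
        if self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            errs.append("batch effect SDs must be >= 0")
        lo, hi = self.libsize_range
        if lo <= 0 or hi < lo:
            errs.append("libsize_range must be positive with lo <= hi")
        if not (2 <= self.core_module_size <= self.n_genes):
            errs.append("core_module_size must be in [2, n_genes]")
        if self.graph_model not in GRAPH_MODELS:
            errs.append(f"unknown graph_model {self.graph_model!r}")
        if self.graph_model == "barabasi_albert" and self.graph_nodes <= self.ba_m:
            errs.append("graph_nodes must exceed ba_m")
        if errs:
            raise ConfigurationError("; ".join(errs))


@dataclass
class GroundTruth:
    """What was planted: DE genes with signed effects, core module, hub roles."""

    de_genes: dict[str, float] = field(default_factory=dict)
    core_genes: list[str] = field(default_factory=list)
    planted_hubs: list[str] = field(default_factory=list)
    planted_nonhubs: list[str] = field(default_factory=list)
    batch_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.planted_hubs) & set(self.planted_nonhubs):
            raise ConfigurationError("planted hubs and nonhubs overlap")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def _sample_layout(cfg: SimulationConfig):
    """Sample ids, condition labels and round-robin batch assignment."""
    n = cfg.n_tumor + cfg.n_normal
    samples = [f"S{i + 1:03d}" for i in range(n)]
    conditions = ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal
    batches = []
    for cond_block in (range(cfg.n_tumor), range(cfg.n_normal)):
        for i in cond_block:
            batches.append(f"B{i % cfg.n_batches + 1}")
    return samples, conditions, batches


def simulate_counts(cfg: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a negative-binomial count matrix with planted structure.

    Mean model on the log2 scale: per-gene baseline + condition effect for
    planted DE genes + per-gene-per-batch additive shift + shared latent
    factor for the core module + residual noise whose SD is modulated per
    batch (the multiplicative scale effect).  Counts are NB with
    variance mu + mu^2 * dispersion, scaled by per-sample library sizes.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    samples, conditions, batches = _sample_layout(cfg)
    n_samples = len(samples)
    batch_levels = sorted(set(batches))
    batch_idx = np.array([batch_levels.index(b) for b in batches])

    base = rng.normal(7.0, 1.0, cfg.n_genes)

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = np.sort(rng.choice(cfg.n_genes, size=n_de, replace=False))
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    lfc = np.zeros(cfg.n_genes)
    lfc[de_idx] = signs * cfg.log2fc_effect

    up_idx = de_idx[signs > 0]
    if len(up_idx) >= cfg.core_module_size:
        core_pool = up_idx
    else:
        core_pool = np.setdiff1d(np.arange(cfg.n_genes), de_idx)
    core_idx = np.sort(rng.choice(core_pool, size=cfg.core_module_size, replace=False))
    loading = np.zeros(cfg.n_genes)
    loading[core_idx] = _CORE_LOADING

    shift = rng.normal(0.0, 1.0, (cfg.n_genes, len(batch_levels))) * cfg.batch_shift_sd
    scale = np.exp(rng.normal(0.0, 1.0, (cfg.n_genes, len(batch_levels)))
                   * cfg.batch_scale_sd)
    latent = rng.normal(0.0, 1.0, n_samples)
    extra_sd = _BASE_EXTRA_SD * scale[:, batch_idx]
    eps = rng.normal(0.0, 1.0, (cfg.n_genes, n_samples)) * extra_sd

    is_tumor = np.array([c == "tumor" for c in conditions], dtype=float)
    log2_mu = (base[:, None] + lfc[:, None] * is_tumor[None, :]
               + loading[:, None] * latent[None, :]
               + shift[:, batch_idx] + eps)

    lib = rng.uniform(cfg.libsize_range[0], cfg.libsize_range[1], n_samples)
    mu = np.exp2(log2_mu) * lib[None, :]
    r = 1.0 / cfg.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    values = pd.DataFrame(counts, index=genes, columns=samples)
    meta = pd.DataFrame({"condition": conditions, "batch": batches},
                        index=pd.Index(samples, name="sample"))
    em = ExpressionMatrix(values, meta, scale="raw_counts")
    truth = GroundTruth(
        de_genes={genes[i]: float(lfc[i]) for i in de_idx},
        core_genes=[genes[i] for i in core_idx],
        batch_assignment=dict(zip(samples, batches)),
    )
    return em, truth


def _planted_hub_graph(cfg: SimulationConfig, rng: np.random.Generator,
                       pool: list[str]) -> tuple[nx.Graph, GroundTruth]:
    """Hubs wired to each other and to pendant fillers; nonhubs hang off
    hubs directly or at distance two (via a filler)."""
    need = cfg.n_hubs + cfg.n_nonhubs + cfg.n_hubs * cfg.n_fillers_per_hub
    if len(pool) < need:
        pool = pool + [f"X{i + 1:05d}" for i in range(need - len(pool))]
    it = iter(pool)
    hubs = [next(it) for _ in range(cfg.n_hubs)]
    nonhubs = [next(it) for _ in range(cfg.n_nonhubs)]
    fillers = [[next(it) for _ in range(cfg.n_fillers_per_hub)]
               for _ in range(cfg.n_hubs)]

    g = nx.Graph()
    for i in range(cfg.n_hubs):
        for j in range(i + 1, cfg.n_hubs):
            g.add_edge(hubs[i], hubs[j], weight=0.9)
    for h, mine in zip(hubs, fillers):
        for f in mine:
            g.add_edge(h, f, weight=float(rng.uniform(0.5, 0.95)))
    for k, nh in enumerate(nonhubs):
        hub = hubs[k % cfg.n_hubs]
        if k % 2 == 0:  # direct neighbor of a hub
            g.add_edge(nh, hub, weight=float(rng.uniform(0.5, 0.95)))
        else:  # two-edge distance via one of the hub's fillers
            via = fillers[k % cfg.n_hubs][k % cfg.n_fillers_per_hub]
            g.add_edge(nh, via, weight=float(rng.uniform(0.5, 0.95)))
    truth = GroundTruth(planted_hubs=hubs, planted_nonhubs=nonhubs)
    return g, truth


def simulate_graph(cfg: SimulationConfig,
                   gene_pool: list[str] | None = None
                   ) -> tuple[nx.Graph, GroundTruth]:
    """Generate an interaction graph under the configured model.

    ``gene_pool`` supplies node identifiers in priority order so graph nodes
    can coincide with simulated gene ids; defaults to the gene-id universe.
    """
    rng = np.random.default_rng([cfg.seed, 17])
    pool = list(gene_pool) if gene_pool is not None else _gene_ids(cfg.n_genes)

    if cfg.graph_model == "planted_hub":
        return _planted_hub_graph(cfg, rng, pool)

    if cfg.graph_model == "erdos_renyi":
        g0 = nx.gnp_random_graph(cfg.graph_nodes, cfg.er_p,
                                 seed=int(rng.integers(2**31)))
    elif cfg.graph_model == "barabasi_albert":
        g0 = nx.barabasi_albert_graph(cfg.graph_nodes, cfg.ba_m,
                                      seed=int(rng.integers(2**31)))
    else:  # pragma: no cover - blocked by config validation
        raise ConfigurationError(f"unknown graph_model {cfg.graph_model!r}")

    if len(pool) < g0.number_of_nodes():
        pool = pool + [f"X{i + 1:05d}" for i in range(g0.number_of_nodes() - len(pool))]
    mapping = {i: pool[i] for i in g0.nodes}
    g = nx.relabel_nodes(g0, mapping)
    for u, v in g.edges:
        g.edges[u, v]["weight"] = float(rng.uniform(0.4, 1.0))
    return g, GroundTruth()


STRING_COLUMNS = ["protein1", "protein2", "coexpression", "experimental",
                  "database", "textmining", "combined_score"]


def write_string_edges(g: nx.Graph, path) -> pd.DataFrame:
    """Write a STRING-dialect edge TSV; scores in 0-1000 derived from weights."""
    rows = []
    for u, v in sorted((tuple(sorted(e)) for e in g.edges)):
        combined = int(round(g.edges[u, v].get("weight", 0.5) * 1000))
        rows.append({"protein1": u, "protein2": v,
                     "coexpression": combined,
                     "experimental": max(0, combined - 200),
                     "database": 0, "textmining": 0,
                     "combined_score": combined})
    df = pd.DataFrame(rows, columns=STRING_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_fixtures(cfg: SimulationConfig, directory) -> dict[str, Path]:
    """Emit the full fixture set: counts, sample sheet, STRING-dialect edges,
    core-gene list and ground-truth JSON.  Graph node ids are drawn from the
    simulated gene universe, core genes first, so the stages interlock."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    em, truth = simulate_counts(cfg)

    ordered, seen = [], set()
    de_sorted = sorted(truth.de_genes, key=lambda g: (-truth.de_genes[g], g))
    for gid in truth.core_genes + de_sorted + em.gene_ids:
        if gid not in seen:
            ordered.append(gid)
            seen.add(gid)
    graph, graph_truth = simulate_graph(cfg, gene_pool=ordered)
    truth.planted_hubs = graph_truth.planted_hubs
    truth.planted_nonhubs = graph_truth.planted_nonhubs

    paths = {
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "edges": directory / "string_edges.tsv",
        "core_genes": directory / "core_genes.txt",
        "ground_truth": directory / "ground_truth.json",
    }
    em.to_tsv(paths["counts"], paths["samples"])
    write_string_edges(graph, paths["edges"])
    paths["core_genes"].write_text("\n".join(truth.core_genes) + "\n")
    truth.to_json(paths["ground_truth"])
    return paths
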