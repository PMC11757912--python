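# coexnet

Batch-aware differential expression and network integration for
two-condition (tumor/normal) RNA-seq, exercisable entirely on synthetic
data with known ground truth.

The pipeline runs six stages:

1. **preprocess** — median-of-ratios size factors (optionally per batch),
   `log2(count/factor + 1)` transformation, low-expression filtering, and a
   parametric empirical-Bayes location/scale batch adjustment that keeps the
   condition as a covariate. PCA diagnostics (variance fractions, PC1
   batch-R²) quantify batch-effect removal.
2. **dge** — two-group moderated t statistics with method-of-moments
   variance shrinkage, Benjamini–Hochberg adjustment, and significance /
   fold-change filtering (defaults `padj < 0.05`, `|log2FC| >= 1`).
3. **wgcn** — weighted co-expression network over the DEGs
   (`|r| >= r_min`, weight `|r|^beta`), giant-component extraction,
   edge-to-node weight conversion (strength), and the topological overlap
   matrix (TOM).
4. **coreprox** — similarity-to-length conversion (`1 - sim` or `1/sim`),
   all-pairs Dijkstra shortest paths, the core-proximity score
   `D_j = (mean SP to noncore - mean SP to core) / mean SP to all`, and the
   positive-D subnetwork around a user-supplied core gene list.
5. **ppin** — STRING-dialect interaction parsing (combined-score threshold,
   evidence-channel filter, A–B/B–A dedup), per-node degree/betweenness/
   closeness/mean-distance statistics, hub/nonhub classification
   (hub: `K > 13` and `BC > 63.94`; nonhub: within the degree/BC bounds and
   within two edges of a hub), whole-network metrics (transitivity, density,
   mean distance, diameter), and deterministic greedy modularity clustering.
6. **association** — pairwise Pearson correlations among hub/nonhub/focal
   genes with t-based p-values, BH adjustment, and a signed significance
   summary.

A first-class synthetic-data module plants DE genes, a co-expressed core
module, batch effects, and interaction graphs with known hubs/nonhubs, so
every stage is testable offline.

## CLI

```sh
# generate a fixture set with ground truth
coexnet simulate --out-dir fx --seed 5 --n-genes 500 --de-fraction 0.08 \
    --batch-shift-sd 0.4

# run the whole pipeline
coexnet run-all --counts fx/counts.tsv --samples fx/samples.tsv \
    --edges fx/string_edges.tsv --core-genes fx/core_genes.txt \
    --out-dir out --seed 5
```

`run-all` writes every intermediate table (normalized matrix, DEG table,
WGCN edges, TOM, D-scores, node statistics, clusters, correlations), a run
log, and a timestamp-free `manifest.json` so reruns with the same config
are byte-identical. Individual stages are also available as subcommands
(`preprocess`, `dge`, `wgcn`, `coreprox`, `ppin`, `associate`); a YAML
config (`--config`) mirrors all flags, with CLI values taking precedence.

## File formats

* counts: TSV, genes as rows, first column `gene`, header = sample ids
* sample sheet: TSV with columns `sample`, `condition` (tumor/normal), `batch`
* interactions: STRING-dialect TSV with `protein1`, `protein2`, optional
  per-channel scores, `combined_score` in 0–1000
* core genes: plain text, one id per line

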