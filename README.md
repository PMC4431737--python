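# functree

Offline construction, analysis and visualization of a **Functional Tree** —
a five-layer circular dendrogram of biological functions (biological
category → biological process → pathway → module → KO, the KEGG Orthology
leaf unit) — for functional profiling of genomic, metagenomic and
transcriptomic data.

Functional annotation pipelines summarize omics data as KO-level
quantities: relative abundances of orthologous gene families in a
metagenome, per-organism gene counts in a pan-genome collection, or lists
of over-expressed genes mapped to KOs. Interpreting those numbers requires
rolling them up the functional hierarchy and asking which pathways and
modules are statistically enriched. `functree` does exactly that, entirely
offline:

* **Hierarchy construction** — builds the tree from plain membership tables
  (KO→module, KO→pathway, pathway→process→category). Module placement
  under pathways is inferred from KO inclusion: by default a module `M`
  becomes a child of every pathway `P` with `KO(M) ⊆ KO(P)` (an `overlap`
  policy — one shared KO — is also available, which can place the same
  module under several pathways). KOs in a pathway but in none of its
  modules attach directly to the pathway; KOs in no module and no pathway
  are kept under a hidden "Undefined Biological Category" subtree —
  excluded from drawing, included in every statistical universe.
* **Value mapping** — direct mapping of a node-value association list, and
  internal node calculation: each upper-layer function receives the sum or
  mean of the values of the distinct KOs in its subtree.
* **Enrichment statistics** — per-function coverage
  `cov_j = KO_exp,j / KO_total,j`; two-sample Wilcoxon rank-sum tests
  (exact for small groups, tie- and continuity-corrected normal
  approximation otherwise); one-sided Fisher's exact tests computed in
  log-factorial space; Bonferroni correction; and the display value
  `val_j = log10(1 / p_corrected,j) · cov_j` for significant functions
  (`p < 0.05`), `0` otherwise. Three pipelines wire these together:
  pan-genomic enrichment of focal organisms, two-stage metagenome
  enrichment (rank test per KO, Fisher on enriched-KO membership above),
  and gene-set enrichment of a gene list against its genome. A
  variability mode maps `σ_j · cov_j`, the across-sample standard
  deviation of each function's summed relative abundance.
* **Rendering** — a deterministic circular-dendrogram SVG: functions on
  concentric layer rings, leaves evenly spaced, one circle per placement
  with radius encoding the value (linear in radius or in area), plus color
  and opacity.
* **Synthetic fixtures** — a seeded generator for membership tables,
  abundance profiles, gene-count matrices and gene lists with a known
  planted signal, so every pipeline is testable without any database
  download.

## Worked example

Generate the standard synthetic scenario (300 KOs, 12 pathways, pathway
`P0001` planted at 3× abundance in 20 query vs 20 background samples), run
the metagenome enrichment and draw the map:

```sh
functree synth --preset standard --seed 7 -o fx/
functree enrich-meta --tree fx/tree.json \
    --query fx/query_profiles.tsv --background fx/background_profiles.tsv \
    -o fx/meta.tsv
head -3 fx/meta.tsv
```

```
function_id	name	layer	value	p_raw	p_corrected	coverage
P0001	Synthetic P0001	pathway	19.81878012561053	2.976114928245405e-22	1.5178186134051563e-20	1.0
M0013	Synthetic M0013	module	9.98544780250628	2.027598780737672e-12	1.0340753781762128e-10	1.0
```

The planted pathway `P0001` tops the table: its Fisher p-value after
Bonferroni correction is 1.5e-20, giving a display value of
`log10(1/1.5e-20) ≈ 19.8`; `M0013`, one of its modules, follows. All of its
KOs were observed in the query (`coverage = 1.0`). Render the result:

```sh
functree render --tree fx/tree.json --values fx/vals.tsv \
    --mode area --rmin 2 --rmax 14 -o fx/map.svg
```

where `fx/vals.tsv` is any two-column `node_id<TAB>value` list (for
instance the first and fourth columns of `fx/meta.tsv`). The same
subcommands cover the other workflows: `aggregate`, `variability`,
`enrich-genus`, `enrich-genes`, `map`, and `build-tree` to construct a tree
from your own membership TSVs. Every command writes a
`<output>.prov.json` sidecar recording parameters and inputs.

As a library:

```python
import functree as ft

cfg = ft.standard_config(seed=7)
tree = ft.build_tree(ft.make_membership(cfg))
query, background = ft.make_profiles(tree, cfg)
results = ft.enrich_metagenome(query, background, tree)
best = max((r for r in results if r.layer != "ko"), key=lambda r: r.val)
print(best.function_id, round(best.val, 2))   # P0001 19.82
```

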