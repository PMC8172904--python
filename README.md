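# lineatlas

Analysis toolkit for building a lineage atlas of the mammary epithelium
from multi-study single-cell RNA-seq — and for carrying the resulting
lineage gene sets over to bulk transcriptomes.

The mammary epithelium develops from a fetal stem state into three
lineages: basal, luminal alveolar (Alv) and luminal hormone-sensing
(Hor).  Given droplet scRNA-seq count matrices from several studies,
`lineatlas` provides the bespoke computations this kind of atlas needs:

* **QC and cluster-level multiplet detection.**  Barcodes are filtered on
  genes detected, UMI counts and mitochondrial fraction; clusters are then
  screened with four criteria — elevated sequencing depth, absence of
  exclusive marker genes, an optional external doublet-caller flag, and a
  near-perfect Pearson correlation (r ≥ 0.99) between the cluster's
  average expression and a *hypothetical doublet* built by averaging two
  other clusters.  The implied doublet rate is estimated from cluster
  frequencies as f_AB / (2 f_A f_B).
* **Tree trajectory and leaf pseudotime.**  A minimum-spanning tree over
  cluster centroids in PCA space, with cells projected onto edges; the
  pseudotime of a cell from any terminal state is its geodesic distance
  along the tree.  Leaves are anchored to lineages by canonical markers
  (Krt14/Acta2, Csn3/Elf5, Areg/Esr1/Ly6d) and the root by the stem
  program.
* **Gene-set curation.**  For each leaf state, genes are ranked by
  Spearman correlation between expression and distance-from-leaf,
  computed per study and averaged across studies; nested prefix sets
  (sizes 1…100, then 120…1000 in steps of 20) are scored per cell and the
  size maximising the cross-study mean score–pseudotime correlation is
  selected.
* **Single-sample enrichment scoring.**  A GSVA-style rank random walk:
  per gene, expression becomes its empirical CDF across the cohort; per
  unit, genes are ordered by decreasing CDF with position weights
  |p/2 − r|, and the score is max ν + min ν of the walk
  ν(l) = Σ_{r≤l, g∈S} w_r/W_S − #{r≤l, g∉S}/(p−|S|).
* **Ternary lineage inference.**  The three lineage scores are min-max
  rescaled and closed onto the probability simplex; the nearest vertex is
  the lineage call.  Works per cell and per bulk sample.
* **Pseudo-bulk robustness.**  Titration designs probing whether the
  calls survive bulk averaging: pool sizes 10–1000 cells and stromal
  contamination down to 50% epithelial content.
* **Synthetic atlas generator.**  A negative-binomial trifurcating-lineage
  simulator (one root, three branches, monotone marker programs, batch
  effects, stroma, mitochondrial fractions, injected same-droplet
  doublets) with full ground truth, so every stage is testable without
  external data.

Statistics used throughout: Wilcoxon rank-sum tests with Cliff's delta
effect sizes, Spearman rank correlations.

## Worked example

```python
import lineatlas as la
from lineatlas import qc, curation
from lineatlas.pipeline import lineage_pseudotime

adata, truth = la.simulate_atlas(la.AtlasConfig(seed=1))
qc_table = qc.compute_barcode_qc(adata)
retained, _ = qc.filter_barcodes(qc_table)
norm = qc.normalize_and_scale(adata[retained].copy())

res = lineage_pseudotime(norm)          # cluster, drop stroma, fit tree
ranked = curation.rank_genes_by_pseudotime(
    res["epi"], res["pt"]["Basal"], "Basal")
sets = curation.build_incremental_sets(ranked)
curve = curation.evaluate_selection_curve(
    res["epi"], sets, res["pt"]["Basal"])
print(curve.k_star)
```

On the default simulation this prints (sizes vary slightly with seed):

```
simulated 3294 barcodes x 3000 genes
QC retained 2820/3294 barcodes
epithelial cells on the tree: 2402
top-100 Basal ranking contains 97 of 100 planted markers
selected Basal gene-set size k* = 140
```

i.e. QC removes ~14% of barcodes (mostly the mitochondrial tail), the
tree keeps every epithelial cell while discarding annotated stroma, the
cross-study ranking recovers 97 of the 100 planted basal-program genes in
its top 100, and the selection curve peaks at 140 genes — slightly above
the planted program size, then plateaus.

The same stages are scriptable from the shell:

```sh
lineatlas simulate --seed 1 --out counts/
lineatlas qc counts/ --out qc.tsv
lineatlas trajectory counts/ --seed 1 --out traj/
lineatlas curate counts/ traj/pseudotime.tsv --leaf Basal --out curated/
lineatlas run --config pipeline.yaml          # everything, with a manifest
```

`lineatlas run` writes every intermediate artifact as headered TSV/GMT
plus a manifest with the configuration hash and a SHA-256 digest of each
output, so reruns with the same seed can be verified bit-for-bit.

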