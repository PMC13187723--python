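# splicerad

Comparative transcriptome evolution across adaptive radiations.

`splicerad` is a tested, reusable pipeline for asking how two layers of gene
regulation — gene expression level (GE) and alternative splicing (AS,
measured as isoform usage) — evolve during rapid ecological
diversification. It is built around the sampling design used in
comparative studies of lake-radiation fishes: several independent
radiations plus nonradiating sister lineages, ecologically contrasting
trophic guilds (herbivores vs carnivores) within each radiation, multiple
tissues, and biological replicates, all tied together by a species
phylogeny.

The pipeline consumes an isoform-level count matrix, a transcript-to-gene
map (TSV or GTF), a sample metadata table, and a Newick species tree.  A
truth-known synthetic-data generator emulating the full design (20 species
in 4 clades, 2 jaw tissues, 5 replicates, n = 200 samples) makes every
stage testable end to end without any external data.

## What it computes

* **PSI quantification** — percent spliced in: an isoform's abundance as a
  proportion of its gene's total, `PSI(i, s) = x_i,s / Σ_{j∈gene(i)} x_j,s`,
  on library-size-normalized expression (CPM).  PSI is missing, not zero,
  where a gene is silent.
* **Divergence profiling** — pairwise Spearman ρ of transcriptome-wide GE
  and PSI across samples; Welch comparison of the two ρ distributions;
  hierarchical clustering and neighbor-joining expression trees on 1 − ρ;
  PCA.
* **Phylogenetic expression models** — per-feature maximum-likelihood fits
  of Brownian motion (neutral drift, `dX = σ dB`) and Ornstein–Uhlenbeck
  (stabilizing selection toward an optimum, `dX = σ dB + α(θ − X) dt`) to
  species-mean log2 expression; likelihood-ratio regime classification with
  BH-FDR; the stationary OU variance σ²/(2α) ("evolutionary variance") as a
  readout of constraint; ML ancestral state reconstruction.
* **Differential usage and expression** — guild-label permutation tests on
  mean ΔPSI (exact enumeration at small n), Šidák/min-p gene aggregation
  into differentially spliced genes (DSGs); Welch tests on log2 CPM for
  differentially expressed genes (DEGs); hypergeometric overlaps,
  DEG∩DSG overlap, and cross-radiation convergence detection.
* **Isoform trajectories** — classification of each isoform's usage change
  from nonradiating lineages into each radiation (stable-ancestral,
  ancestral-gain/-loss, novel-low/-gain) at a configurable ΔPSI threshold
  (default 0.2), and counting of putatively novel isoforms (absent in every
  nonradiating species, present in ≥ 1 radiation).
* **Enrichment** — classic and elim Fisher term over-representation against
  a user-supplied term→gene map.

## Worked example

```python
import splicerad as sr

ds = sr.simulate_dataset(sr.SimulationConfig(n_genes=300, rng_seed=42))
expr = sr.normalize(ds.counts, "cpm")
genes = sr.gene_expression(expr, ds.counts.iso2gene)
psi = sr.compute_psi(expr, ds.counts.iso2gene)

rho_ge = sr.spearman_matrix(genes)
rho_psi = sr.spearman_matrix(psi.multi_isoform())
comp = sr.compare_rho_distributions(rho_ge, rho_psi)

ge = sr.hcluster(rho_ge)
ps = sr.hcluster(rho_psi)
iso_res, dsg = sr.diff_psi(psi, ds.metadata, "LV", "OJ", seed=1)
deg = sr.diff_expr(ds.counts, ds.metadata, "LV", "OJ")
```

This prints (via the obvious `print` calls):

```
samples: 200  isoforms: 618
mean rho GE = 0.730, mean rho PSI = 0.600, t = 68.6, p = 0.00e+00
GE top split = tissue? ARI: 1.0
PSI 4-way split = clade? ARI: 1.0
LV oral-jaw DSGs (q<0.05): 68 of 170 genes
LV oral-jaw DEGs (q<0.05): 31 of 300 genes
```

Reading the numbers: GE correlates more strongly across samples than
isoform usage (mean ρ 0.73 vs 0.60; the Welch t on the upper-triangle ρ
values is descriptive since sample pairs are not independent) — expression
level is the more conserved regulatory layer, isoform usage the more
labile one.  Clustering confirms the contrast: GE groups samples first by
tissue (adjusted Rand index 1.0 against the tissue factor at the 2-way
cut) while PSI groups them first by clade (ARI 1.0 against clade at the
4-way cut).  Within the Lake Victoria radiation's oral jaws, 68 of 170
multi-isoform genes are differentially spliced between herbivores and
carnivores and 31 of 300 genes differentially expressed at q < 0.05 —
both planted by the generator and recovered by the tests.

The same stages are available as a CLI for file-based workflows
(`splicerad simulate | psi | profile | fit-phylo | diff-expr | diff-psi |
sharing | classify-trajectories | converge | enrich`); every run writes a
manifest with its config, seed and input hashes.

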