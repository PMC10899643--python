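# neutraj

Analysis of neutrophil maturation trajectories from single-cell
transcriptomics, with cross-species alignment and signature scoring of bulk
samples.

Neutrophils mature through a continuum of transcriptional states
(granulopoiesis) rather than discrete textbook stages. Given a single-cell
expression matrix of neutrophils — for example from zebrafish whole kidney
marrow — this package orders cells along a maturation pseudotime, discovers
the gene programs (modules M1..Mk) and maturation phases (P1..Pg) that
structure the trajectory, ranks transcription factors as candidate
regulators of each module, aligns trajectories from other species
(mouse, human) onto the reference gene by gene, derives pan-species
maturation signatures, and scores bulk RNA-seq samples for the abundance of
maturing neutrophils. A synthetic-data generator with fully planted ground
truth makes every stage testable end to end.

## Methods at a glance

- **Pseudotime**: cells are ranked along the first latent component of the
  normalized expression (or along a principal curve in the top two
  components) and rescaled to [0, 1]; orientation is fixed by a decreasing
  (lysozyme-like) and an increasing (mmp9-like) marker.
- **Binning**: the trajectory is discretized into 100 bins of mean
  expression; bins with ≤ 3 cells are quality-flagged.
- **Association**: each gene's profile is modeled as a cubic B-spline
  (6 interior knots) of pseudotime and tested against a constant model
  (F-test); Benjamini–Hochberg-adjusted p < 0.05 genes are ranked by
  statistic and the top 1500 kept.
- **Modules and phases**: dynamic-time-warping (DTW) distances between
  z-scored binned profiles, Ward linkage, and the Kelley–Gardner–Sutcliffe
  (KGS) penalty to choose the number of clusters — applied to genes
  (modules) and to bins (phases).
- **Regulators**: per gene *i* and TF *l*, the scaled DTW similarity
  s_il = 1 − d_il / max_l(d_il); Kruskal–Wallis across modules with Dunn
  post-hoc contrasts (Holm-adjusted) flags module-specific TFs, which DTW's
  warping lets lead their targets.
- **Cross-species**: homologs are collapsed by detection rate, each gene's
  binned profile is aligned to the reference by cross-correlation, and the
  lag k maximizing r(k) = Σ_t x_{t+k} y_t / (n·s_x·s_y) is recorded. Genes
  with |mean lag| ≤ 50 bins that are not blacklisted cell-type markers form
  the pan-species signatures (M1pan, M2pan, M3pan).
- **Scoring**: single-sample GSEA (Barbie-style running-sum integral,
  α = 0.25), Seurat-style per-cell module scores with expression-matched
  controls, hypergeometric over-representation, and a mixing sensitivity
  analysis (1000-cell pseudo-bulk mixtures of maturation-stage and stromal
  cells, 20 replicates, median score per mixing ratio).

## Worked example

```python
import neutraj as nj

expr, truth = nj.simulate_trajectory_dataset(n_cells=2000, n_genes=300, seed=1)
norm = nj.normalize_expression(nj.filter_features(expr))
pt = nj.infer_pseudotime(norm, "lyz_like", "mmp9_like")
binned = nj.bin_trajectory(norm, pt)
assoc = nj.association_test(norm, pt, raw_counts=expr)
modules = nj.partition_genes(binned, assoc.selected_genes)
phases = nj.partition_phases(binned, assoc.selected_genes)
print(len(assoc.selected_genes), modules.k, phases.g)
```

prints `278 3 4`: 278 genes are called maturation-associated, and the KGS
penalty selects three gene modules and four maturation phases — exactly the
structure planted by the generator (the module assignment matches the truth
with adjusted Rand index 1.0). The same pipeline is driven from the shell
via the `neutraj` command (`simulate`, `trajectory`, `modules`,
`regulators`, `xspecies`, `score` subcommands).

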