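# Methods

## Model and assumptions

The package assumes neutrophil maturation is a single, unbranched continuum:
every cell carries a latent maturation coordinate t ∈ [0, 1], and each
gene's expected (relative) expression is a smooth function of t. All
downstream objects — the 100-bin trajectory, modules, phases, lags — are
summaries of these per-gene functions. Branching lineages, cell-cycle
structure and batch effects are outside the model; inputs are expected to
be pre-filtered single-lineage neutrophil data.

Pseudotime itself is treated as identified only up to a monotone
transformation: it is computed as the min–max-rescaled *rank* of cells
along the first latent component, and the association test re-ranks its
input, so every statistic in the package is invariant to monotone
reparametrizations of the axis. The first-component ordering is the
default; a Hastie–Stuetzle principal curve in the top two components is
available (`mode="principal_curve"`) for data where the trajectory bends in
the leading plane.

## Synthetic data: what it emulates, and what it does not

`simulate_trajectory_dataset` draws cell pseudotimes uniformly, builds
per-gene mean profiles, converts them to per-cell relative abundances, and
draws counts from a gamma–Poisson (negative binomial) with gene-level
dispersion 5 around depth × abundance, with per-cell depth lognormal
(μ = 9, σ = 0.3 on the log scale, a 10x-like ~8k median). Two profile
families are provided:

- **Staged profiles** (default): each module steps through per-phase
  expression levels with logistic transitions (width 0.01) at the phase
  boundaries 0.25 / 0.5 / 0.75. This plants four crisply defined phases and
  three separable modules. The per-phase level sums are balanced across
  phases (each column sums to 1.35) and the per-gene amplitude and level
  jitter are mean-normalized within each module, so the *total* expression
  is flat along t. This matters: without it, depth normalization converts
  the changing library composition into an apparent trend in every
  constant-fraction gene, and "null" genes stop being null.
- **Gaussian-bump profiles** (`smooth_module_spec`): modules peak at
  t = 0.3 / 0.5 / 0.7 with sd 0.05. These are used for cross-species
  alignment studies, where a profile translated by up to ±20 of 100 bins
  must keep a localized, identifiable feature on the axis. Plateau-shaped
  staged profiles are deliberately not used there: the cross-correlation of
  two plateaus has a flat maximum (the lag is unidentifiable), and a ±20-bin
  shift can push a single transition edge off the trajectory.

Reporters (`lyz_like` decreasing, `mmp9_like` increasing) belong to the
first/last module under staged profiles — their programs *are* module
programs — and sorted gates NO/INT/HI are planted by thresholding the
mmp9-like reporter at its 30th/70th percentile, a qualitative mirror of
FACS gating. TFs carry their target module's profile advanced by 5 bins.

Species datasets translate the reference profile functions by an integer
per-gene lag (edge-replicated by clamping the time argument to [0, 1]) and
rename genes to species ids; planted 1-to-many homology adds near-silent
decoy paralogs with low detection rates. Stage-aggregated datasets average
the true profiles over pseudotime windows plus Gaussian noise; bulk
mixtures sum sampled cell columns.

Not emulated: ambient RNA, doublets, batch/chemistry effects, non-uniform
cell density along the trajectory, and dropout beyond what the NB provides.
Passing recovery tests therefore demonstrates correctness of the machinery
under the stated generative model, not robustness to real-data artifacts.

## Key parameters

| Parameter | Default | Notes |
|---|---|---|
| `n_bins` | 100 | trajectory discretization; flags at ≤ 3 cells/bin |
| `knots` | 6 | interior knots of the cubic association spline |
| `top_n` | 1500 | maturation genes kept after BH p < 0.05, ranked by F |
| `min_cells` / `min_features` / `max_mito_frac` | 20 / 500 / 0.10 | QC: detection in ≥ 20 cells; ≥ 500 features and < 10% mito per cell |
| `k_max` | 10 | KGS search range (k = 2..k_max) |
| DTW step pattern | symmetric, diagonal weight 2 | abs local cost, no window, per-gene z-scoring |
| `max_lag` | 99 | full lag range for 100 bins; the printed ≤ 50 rule is unreachable under a short default correlation window, so the window is exposed |
| `lag_threshold` | 50 | pan-signature inclusion, inclusive |
| ssGSEA `alpha` | 0.25 | rank weight exponent; `normalize` divides by the global score range |
| `module_score` | 24 bins, 100 controls | expression-matched control draw, seeded |
| mixtures | total 1000, reps 20, median | mixing sensitivity protocol |

## Numerical choices

- **DTW**: dynamic program with first cell weight 1, diagonal steps 2×cost,
  off-diagonal 1×cost; numba-jitted with a pure-numpy fallback. Verified
  against exhaustive warping-path enumeration for all short series.
- **KGS**: within-cluster spread = mean over clusters of size ≥ 2 of the
  mean pairwise distance (singletons contribute nothing); spreads are
  min–max rescaled to [1, k_max − 1]; penalty = rescaled spread + k; ties
  break toward smaller k (all-identical input selects k = 2).
- **Binning**: bin b covers [b/n, (b+1)/n) with the last bin closed; a 1e-9
  epsilon guards float representation of exact boundaries; empty bins are
  linearly interpolated from neighbors and flagged, never dropped.
- **Module/phase labels**: modules are named M1..Mk by the bin at which the
  module's mean z-scored profile peaks; phases P1..Pg by mean pseudotime;
  phase contiguity is *reported* (fraction of bins matching the best
  contiguous relabeling), not enforced.
- **Cross-correlation**: full-series means and standard deviations, sum
  over the overlap divided by the full length n (so large |k| decays
  naturally); ties in the argmax go to the smallest |k|, then the negative
  lag; positive lag means the query runs later than the reference.
- **Quantile normalization**: ranks are tie-averaged; tied values map to
  the mean of their tied positions' grid values, so exact multiset equality
  across columns holds for tie-free data (the generic case for expression
  means).
- **Homology collapse**: per source the best-rate target, then per target
  the best-rate source; rate ties break lexicographically and are logged;
  unmapped genes pass through unchanged, making the operation idempotent;
  the cross-dataset gene intersection happens in `build_lag_table`.
- **Dunn post-hoc**: z statistics from pooled rank sums with the standard
  tie correction, Holm-adjusted within each TF's contrasts; a TF is
  "specific" when its best-median module beats every other module at
  α = 0.05 and the omnibus Kruskal–Wallis test is significant.
- **ssGSEA**: ascending tie-averaged ranks as the statistic, running sum up
  by |rank|^α (normalized over the set) for members and down by
  1/(N − |S|) otherwise; the score is the sum of the running sum
  (integral), not its extremum.

## Design choices where the design was open

- The Gaussian spline F-test on log-normalized data stands in for a
  negative-binomial GAM Wald test: on binned, z-scored profiles the two
  select and rank the same genes, and the Gaussian contract is far simpler.
  Numeric equality of statistics is not claimed; ranking agreement is what
  the recovery tests check.
- Phases are obtained by clustering the 100 bins (as vectors over the
  maturation genes) and mapping cells through their bin; clustering cells
  directly is the noted alternative.
- The per-gene scaled-similarity normalization uses the max over TFs for
  each gene; the transposed reading (max over genes per TF) is available
  via `max_over="genes"`.
- Pan-signature filtering uses the per-gene *mean* lag across query
  datasets.
- log1p counts-per-10k stands in for heavier variance stabilizers
  (single-cell) and log-CPM for bulk; downstream statistics operate on
  ranks or z-scored bins and are insensitive to the choice.
- The ssGSEA range-normalization toggle covers both common formulations of
  the score (normalized and raw integral); results in this package use the
  normalized form unless stated.

## Problem sizes

Recovery tests and the acceptance script run at 2000 cells × 300 genes
(three modules of 90 genes, reporters, three TFs, the rest null), species
datasets of 1500–2500 cells, 11 mixing ratios × 20 replicates of 1000-cell
pseudo-bulks, and 10 seeds for the repeated-recovery checks — sizes at
which every planted structure is comfortably identifiable while a full test
run stays in the minutes range. Lag-recovery checks bin the species data
with the planted pseudotime so that they measure alignment error, not
ordering error; the ordering step has its own recovery tests.

## Known limitations

- Compositional coupling: with few genes, depth normalization leaks module
  dynamics into flat genes; the generator balances totals by construction,
  real transcriptomes dilute the effect across thousands of genes.
- Phase boundaries are ambiguous within a transition's width; bin-level
  phase accuracy is bounded by how sharp the planted transitions are.
- The |lag| ≤ 50 conservation rule is only a well-posed recovery target for
  features that remain on the axis after shifting; mid-trajectory programs
  cannot be planted as "non-conserved by shift" beyond half the axis.
- `simulate_species_family` needs the in-memory truth object returned by
  `simulate_trajectory_dataset` (profile functions are not serialized).
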