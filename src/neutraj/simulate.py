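"""Synthetic granulopoiesis data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a single smooth maturation axis (pseudotime on [0, 1]);
* three gene modules whose programs switch at four phase boundaries
  (staged logistic transitions between per-phase expression levels);
* a reporter increasing along maturation (``mmp9_like``) and one decreasing
  (``lyz_like``), from which NO/INT/HI sorted gates are derived;
* transcription factors whose profiles lead their target module by a fixed
  number of bins;
* sibling "species" datasets whose per-gene profiles are the reference
  profiles translated by planted integer lags, with 1-to-many homology;
* stage-aggregated matrices and bulk mixtures of maturation stages with a
  stromal background.

Counts are negative-binomial (gamma-Poisson) around depth x relative
expression; every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, HomologyMap

logger = logging.getLogger("neutraj")

DEFAULT_PHASE_BOUNDARIES = (0.25, 0.5, 0.75)
DEFAULT_DISPERSION = 5.0
DEPTH_LOG_MEAN = 9.0   # lognormal depth, plausible 10x scale (median ~8100 UMIs)
DEPTH_LOG_SD = 0.3


@dataclass
class ModuleSpec:
    """One gene module.

    ``shape="staged"`` steps through ``phase_levels`` at the phase boundaries
    with logistic transitions of width ``transition_width`` — the default,
    giving crisply planted phases.  ``shape="gauss"`` /
    ``"logistic_up"`` / ``"logistic_down"`` place a localized bump or ramp at
    ``center`` with scale ``width`` — used for alignment studies where a
    translated profile must remain identifiable.
    """

    name: str
    n_genes: int
    phase_levels: tuple = ()
    transition_width: float = 0.01
    amplitude: float = 1.0
    shape: str = "staged"
    center: float = 0.5
    width: float = 0.08


def default_module_spec(n_genes: int) -> list:
    """Three maturation modules splitting ~60% of the genes equally.

    The per-phase level patterns make each of the four phases a distinct
    column vector (early program high in P1, a transient mid program, and a
    late program rising through P3 into P4), so both the gene partition
    (k = 3) and the bin partition (g = 4) are genuinely planted.
    """
    per = max(3, int(round(n_genes * 0.3)))
    per = min(per, max(3, (n_genes - 5) // 3))  # leave room for reporters/TFs
    # per-phase sums are equal across phases (1.35) so that the total
    # expression is flat along pseudotime and non-module genes are true nulls
    return [
        ModuleSpec("M1", per, (1.25, 0.40, 0.05, 0.05)),
        ModuleSpec("M2", per, (0.05, 0.90, 0.45, 0.05)),
        ModuleSpec("M3", per, (0.05, 0.05, 0.85, 1.25)),
    ]


def smooth_module_spec(n_genes: int) -> list:
    """Three modules with localized Gaussian-bump programs (centers 0.3,
    0.5, 0.7).  Suited to cross-species alignment studies: a profile
    translated by up to +-20 of 100 bins keeps its feature on the
    trajectory, so the planted lag stays identifiable."""
    per = max(3, int(round(n_genes * 0.3)))
    per = min(per, max(3, (n_genes - 5) // 3))
    return [
        ModuleSpec("M1", per, shape="gauss", center=0.3, width=0.05),
        ModuleSpec("M2", per, shape="gauss", center=0.5, width=0.05),
        ModuleSpec("M3", per, shape="gauss", center=0.7, width=0.05),
    ]


@dataclass
class TrajectoryTruth:
    """Planted ground truth accompanying a simulated dataset."""

    cell_pseudotime: pd.Series
    gene_modules: pd.Series           # gene -> M1/M2/M3/none
    bin_phases: pd.Series             # bin index -> P1..P4
    tf_table: pd.DataFrame            # tf, target_module, lead_bins
    profiles: pd.DataFrame            # true mean relative expression, genes x bins
    phase_boundaries: tuple = DEFAULT_PHASE_BOUNDARIES
    n_bins: int = 100
    gene_lags: pd.DataFrame | None = None   # gene x dataset planted lag (bins)
    mixture_design: pd.DataFrame | None = None
    profile_fns: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for b in self.phase_boundaries:
            if not 0 < b < 1:
                raise ValueError("phase boundaries must lie inside (0, 1)")
        if self.gene_lags is not None:
            lags = self.gene_lags.to_numpy()
            if np.abs(lags).max() >= self.n_bins:
                raise ValueError("|lag| must be < n_bins")

    def to_dir(self, path) -> None:
        """Emit truth as plain TSVs so recovery tests can read it from disk."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.cell_pseudotime.rename("pseudotime").to_csv(path / "cell_pseudotime.tsv", sep="\t")
        self.gene_modules.rename("module").to_csv(path / "gene_modules.tsv", sep="\t")
        self.bin_phases.rename("phase").to_csv(path / "bin_phases.tsv", sep="\t")
        self.tf_table.to_csv(path / "tf_table.tsv", sep="\t", index=False)
        self.profiles.to_csv(path / "profiles.tsv", sep="\t")
        if self.gene_lags is not None:
            self.gene_lags.to_csv(path / "gene_lags.tsv", sep="\t")
        if self.mixture_design is not None:
            self.mixture_design.to_csv(path / "mixture_design.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "TrajectoryTruth":
        path = Path(path)
        kw = {}
        if (path / "gene_lags.tsv").exists():
            kw["gene_lags"] = pd.read_csv(path / "gene_lags.tsv", sep="\t", index_col=0)
        if (path / "mixture_design.tsv").exists():
            kw["mixture_design"] = pd.read_csv(path / "mixture_design.tsv", sep="\t")
        return cls(
            cell_pseudotime=pd.read_csv(path / "cell_pseudotime.tsv", sep="\t", index_col=0)["pseudotime"],
            gene_modules=pd.read_csv(path / "gene_modules.tsv", sep="\t", index_col=0)["module"],
            bin_phases=pd.read_csv(path / "bin_phases.tsv", sep="\t", index_col=0)["phase"],
            tf_table=pd.read_csv(path / "tf_table.tsv", sep="\t"),
            profiles=pd.read_csv(path / "profiles.tsv", sep="\t", index_col=0),
            **kw,
        )


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _staged_profile(levels, boundaries, width):
    """Smooth curve stepping through per-phase levels at the boundaries."""
    levels = np.asarray(levels, dtype=float)

    def f(t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, levels[0])
        for j, b in enumerate(boundaries):
            out = out + (levels[j + 1] - levels[j]) * _sigmoid((t - b) / width)
        return out

    return f


def _logistic(center, width, rising=True, lo=0.02, hi=1.0):
    if not 0 <= center <= 1:
        raise ValueError("profile center must lie in [0, 1]")
    sign = 1.0 if rising else -1.0

    def f(t):
        t = np.asarray(t, dtype=float)
        return lo + (hi - lo) * _sigmoid(sign * (t - center) / width)

    return f


def _gaussian(center, width, lo=0.02, hi=1.0):
    if not 0 <= center <= 1:
        raise ValueError("profile center must lie in [0, 1]")

    def f(t):
        t = np.asarray(t, dtype=float)
        return lo + (hi - lo) * np.exp(-0.5 * ((t - center) / width) ** 2)

    return f


def _nb_counts(rng, mean, dispersion):
    """Gamma-Poisson draw: mean ``mean``, variance mean + mean^2/dispersion."""
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 0) / dispersion)
    return rng.poisson(lam)


def _phase_of_bins(n_bins, boundaries):
    centers = (np.arange(n_bins) + 0.5) / n_bins
    idx = np.searchsorted(boundaries, centers)
    return pd.Series([f"P{i + 1}" for i in idx], index=range(n_bins))


# ---------------------------------------------------------------------------
# reference dataset
# ---------------------------------------------------------------------------

def simulate_trajectory_dataset(
    n_cells: int = 2000,
    n_genes: int = 300,
    module_spec: list | None = None,
    dispersion: float = DEFAULT_DISPERSION,
    tf_spec: list | None = None,
    n_bins: int = 100,
    phase_boundaries=DEFAULT_PHASE_BOUNDARIES,
    amplitude_jitter_sd: float = 0.3,
    level_jitter_sd: float = 0.08,
    seed: int = 0,
    dataset: str = "ref",
    species: str = "zebrafish",
):
    """Simulate one single-cell dataset along a maturation trajectory.

    Returns ``(ExpressionMatrix, TrajectoryTruth)``.  Gene content: the
    module genes from ``module_spec``, an increasing ``mmp9_like`` and a
    decreasing ``lyz_like`` reporter, the TFs from ``tf_spec`` (default one
    per module leading its targets by 5 bins), and flat "none" genes filling
    up to ``n_genes``.  Sorted gates NO/INT/HI are planted by thresholding
    the depth-normalized ``mmp9_like`` reporter at its 30th/70th percentile.
    """
    rng = np.random.default_rng(seed)
    if module_spec is None:
        module_spec = default_module_spec(n_genes)
    if tf_spec is None:
        tf_spec = [(f"tf_{m.name.lower()}", m.name, 5) for m in module_spec]
    for lead in (s[2] for s in tf_spec):
        if abs(lead) >= n_bins:
            raise ValueError("|TF lead| must be < n_bins")

    profile_fns: dict = {}
    modules: dict = {}

    def _base_fn(m: ModuleSpec, center=None, width=None):
        if m.shape == "staged":
            return _staged_profile(m.phase_levels, phase_boundaries, m.transition_width)
        c = m.center if center is None else center
        w = m.width if width is None else width
        if m.shape == "gauss":
            return _gaussian(c, w, lo=0.0, hi=1.0)
        if m.shape in ("logistic_up", "logistic_down"):
            return _logistic(c, w, rising=m.shape == "logistic_up", lo=0.0, hi=1.0)
        raise ValueError(f"unknown module shape {m.shape!r}")

    base_fns = {m.name: _base_fn(m) for m in module_spec}

    for m in module_spec:
        # jitter is mean-normalized within the module so the planted per-phase
        # balance (constant total along pseudotime) survives gene-level noise
        amps = m.amplitude * rng.lognormal(0.0, amplitude_jitter_sd, m.n_genes)
        if amps.mean() > 0:
            amps = amps / amps.mean() * m.amplitude
        if m.shape == "staged":
            jits = np.clip(rng.normal(1.0, level_jitter_sd, (m.n_genes, len(m.phase_levels))), 0.1, None)
            jits /= jits.mean(axis=0, keepdims=True)
        for g in range(m.n_genes):
            gene = f"{m.name.lower()}_g{g:03d}"
            if m.shape == "staged":
                f = _staged_profile(np.asarray(m.phase_levels) * jits[g], phase_boundaries,
                                    m.transition_width)
            else:
                f = _base_fn(m, center=m.center + rng.normal(0, 0.01),
                             width=m.width * rng.uniform(0.9, 1.1))
            profile_fns[gene] = (lambda f=f, a=amps[g]: (lambda t: 0.02 + a * f(t)))()
            modules[gene] = m.name

    # reporters: a decreasing lysozyme-like early-program gene and an
    # increasing mmp9-like late-program gene.  With staged modules they are
    # members of the first/last program; otherwise plain monotone ramps.
    first, last = module_spec[0], module_spec[-1]
    if first.shape == "staged":
        profile_fns["lyz_like"] = (lambda f=base_fns[first.name]: (lambda t: 0.02 + 2.0 * f(t)))()
        modules["lyz_like"] = first.name
        profile_fns["mmp9_like"] = (lambda f=base_fns[last.name]: (lambda t: 0.02 + 1.5 * f(t)))()
        modules["mmp9_like"] = last.name
    else:
        profile_fns["lyz_like"] = _logistic(0.5, 0.05, rising=False, lo=0.02, hi=2.0)
        modules["lyz_like"] = "none"
        profile_fns["mmp9_like"] = _logistic(0.5, 0.05, rising=True, lo=0.02, hi=1.5)
        modules["mmp9_like"] = "none"

    tf_rows = []
    for tf_name, target, lead in tf_spec:
        base = base_fns.get(target)
        if base is None:
            raise ValueError(f"TF {tf_name} targets unknown module {target}")
        shift = lead / n_bins
        profile_fns[tf_name] = (lambda b=base, s=shift: (lambda t: 0.02 + b(np.clip(np.asarray(t) + s, 0, 1))))()
        modules[tf_name] = target  # a leading TF still belongs to its module's program
        tf_rows.append({"tf": tf_name, "target_module": target, "lead_bins": lead})

    n_null = n_genes - len(profile_fns)
    if n_null < 0:
        raise ValueError("n_genes too small for the requested modules/TFs/reporters")
    for g in range(n_null):
        gene = f"null_g{g:03d}"
        lvl = rng.uniform(0.05, 1.0)
        profile_fns[gene] = (lambda v=lvl: (lambda t: np.full_like(np.asarray(t, dtype=float), v)))()
        modules[gene] = "none"

    genes = list(profile_fns)
    t_cells = rng.uniform(0, 1, n_cells)
    cell_ids = [f"{dataset}_c{i:05d}" for i in range(n_cells)]

    rel = np.vstack([profile_fns[g](t_cells) for g in genes])
    frac = rel / rel.sum(axis=0, keepdims=True)
    depth = rng.lognormal(DEPTH_LOG_MEAN, DEPTH_LOG_SD, n_cells)
    counts = _nb_counts(rng, depth * frac, dispersion)

    values = pd.DataFrame(counts.astype(float), index=genes, columns=cell_ids)

    reporter = values.loc["mmp9_like"].to_numpy() / values.to_numpy().sum(axis=0)
    lo, hi = np.quantile(reporter, [0.3, 0.7])
    gate = np.where(reporter <= lo, "NO", np.where(reporter >= hi, "HI", "INT"))
    obs = pd.DataFrame(
        {"species": species, "dataset": dataset, "sorted_gate": gate},
        index=cell_ids,
    )

    centers = (np.arange(n_bins) + 0.5) / n_bins
    profiles = pd.DataFrame(
        np.vstack([profile_fns[g](centers) for g in genes]), index=genes, columns=range(n_bins)
    )
    truth = TrajectoryTruth(
        cell_pseudotime=pd.Series(t_cells, index=cell_ids),
        gene_modules=pd.Series(modules),
        bin_phases=_phase_of_bins(n_bins, phase_boundaries),
        tf_table=pd.DataFrame(tf_rows, columns=["tf", "target_module", "lead_bins"]),
        profiles=profiles,
        phase_boundaries=tuple(phase_boundaries),
        n_bins=n_bins,
        profile_fns=profile_fns,
    )
    return ExpressionMatrix(values, obs), truth


# ---------------------------------------------------------------------------
# species family
# ---------------------------------------------------------------------------

def simulate_species_family(
    reference_truth: TrajectoryTruth,
    lag_spec: dict | None = None,
    homology_spec: dict | None = None,
    n_cells: int = 1500,
    dispersion: float = DEFAULT_DISPERSION,
    datasets=("mouse_a", "human_a"),
    lag_range: tuple = (-20, 20),
    seed: int = 0,
):
    """Simulate sibling species datasets with planted per-gene temporal lags.

    Each dataset's gene profiles are the reference profiles translated along
    pseudotime by an integer number of bins (edge-replicated: the shifted
    time axis is clamped to [0, 1]) and renamed to species-specific ids.
    ``lag_spec`` maps dataset -> {reference gene -> lag}; by default module
    genes get an integer lag drawn uniformly from ``lag_range`` and all other
    genes lag 0.  ``homology_spec`` controls planted 1-to-many homology
    (default: fraction 0.1 of genes get a low-detection-rate decoy paralog).

    Returns a list of ``(ExpressionMatrix, HomologyMap, TrajectoryTruth)``.
    """
    if not reference_truth.profile_fns:
        raise ValueError("reference_truth must come from simulate_trajectory_dataset "
                         "(carries the profile functions)")
    rng = np.random.default_rng(seed)
    hspec = {"one_to_many_fraction": 0.1, "decoy_rate": (0.01, 0.3),
             "primary_rate": (0.5, 0.95)}
    if homology_spec:
        hspec.update(homology_spec)
    n_bins = reference_truth.n_bins
    genes = list(reference_truth.profile_fns)
    module_genes = [g for g in genes if reference_truth.gene_modules.get(g, "none") != "none"]

    out = []
    lag_records = {}
    for d_idx, dname in enumerate(datasets):
        if lag_spec is not None and dname in lag_spec:
            lags = {g: int(lag_spec[dname].get(g, 0)) for g in genes}
        else:
            lags = {g: 0 for g in genes}
            for g in module_genes:
                lags[g] = int(rng.integers(lag_range[0], lag_range[1] + 1))
        if max(abs(v) for v in lags.values()) >= n_bins:
            raise ValueError("|lag| must be < n_bins")
        lag_records[dname] = lags

        species = dname.split("_")[0]
        t_cells = rng.uniform(0, 1, n_cells)
        cell_ids = [f"{dname}_c{i:05d}" for i in range(n_cells)]

        hom_rows = []
        sp_genes, rel_rows = [], []
        decoy_mask = rng.random(len(genes)) < hspec["one_to_many_fraction"]
        for gi, g in enumerate(genes):
            fn = reference_truth.profile_fns[g]
            shift = lags[g] / n_bins
            prof = fn(np.clip(t_cells - shift, 0, 1))
            primary = f"{species}_{g}"
            rate = rng.uniform(*hspec["primary_rate"])
            sp_genes.append(primary)
            rel_rows.append(prof)
            hom_rows.append({"source_gene": primary, "target_gene": g, "detection_rate": rate})
            if decoy_mask[gi]:
                decoy = f"{species}_{g}_b"
                drate = rng.uniform(*hspec["decoy_rate"])
                sp_genes.append(decoy)
                rel_rows.append(np.full(n_cells, 0.02))   # near-silent paralog
                hom_rows.append({"source_gene": decoy, "target_gene": g, "detection_rate": drate})

        rel = np.vstack(rel_rows)
        frac = rel / rel.sum(axis=0, keepdims=True)
        depth = rng.lognormal(DEPTH_LOG_MEAN, DEPTH_LOG_SD, n_cells)
        counts = _nb_counts(rng, depth * frac, dispersion)
        values = pd.DataFrame(counts.astype(float), index=sp_genes, columns=cell_ids)
        obs = pd.DataFrame({"species": species, "dataset": dname}, index=cell_ids)

        hmap = HomologyMap(pd.DataFrame(hom_rows), source_species=species,
                           target_species="zebrafish")
        lag_df = pd.DataFrame({dname: pd.Series(lags)})
        truth = TrajectoryTruth(
            cell_pseudotime=pd.Series(t_cells, index=cell_ids),
            gene_modules=reference_truth.gene_modules.copy(),
            bin_phases=reference_truth.bin_phases.copy(),
            tf_table=reference_truth.tf_table.copy(),
            profiles=reference_truth.profiles.copy(),
            phase_boundaries=reference_truth.phase_boundaries,
            n_bins=n_bins,
            gene_lags=lag_df,
        )
        out.append((ExpressionMatrix(values, obs), hmap, truth))
    return out


# ---------------------------------------------------------------------------
# stage-aggregated datasets
# ---------------------------------------------------------------------------

def simulate_stage_datasets(
    reference_truth: TrajectoryTruth,
    stage_grid: dict | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Stage-aggregated matrices: each stage is the mean of the true profiles
    over its pseudotime window plus Gaussian noise.

    ``stage_grid`` maps dataset name -> ordered list of ``(stage_label, lo, hi)``
    windows; default is four datasets with three matched stages each.
    Returns a list of ``(dataset_name, DataFrame genes x stages, stage_labels)``.
    """
    rng = np.random.default_rng(seed)
    if stage_grid is None:
        windows = [("early", 0.0, 0.3), ("mid", 0.35, 0.65), ("late", 0.7, 1.0)]
        stage_grid = {f"ds{i}": windows for i in range(4)}
    profiles = reference_truth.profiles
    n_bins = reference_truth.n_bins
    centers = (np.arange(n_bins) + 0.5) / n_bins

    out = []
    for dname, windows in stage_grid.items():
        spans = sorted((lo, hi) for _, lo, hi in windows)
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            if l2 < h1:
                raise ValueError(f"overlapping stage windows in dataset {dname}")
        cols = {}
        for label, lo, hi in windows:
            mask = (centers >= lo) & (centers <= hi)
            if not mask.any():
                raise ValueError(f"stage window ({lo}, {hi}) covers no bins")
            mean_prof = profiles.loc[:, mask].mean(axis=1)
            cols[label] = mean_prof + rng.normal(0, noise_sd, len(mean_prof))
        df = pd.DataFrame(cols).clip(lower=0)
        out.append((dname, df, [w[0] for w in windows]))
    return out


# ---------------------------------------------------------------------------
# bulk mixtures
# ---------------------------------------------------------------------------

def simulate_stromal_pool(
    reference_truth: TrajectoryTruth,
    n_cells: int = 1000,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
) -> ExpressionMatrix:
    """A stromal background pool over the same gene universe: maturation-module
    genes near-silent, its own random program over the remaining genes."""
    rng = np.random.default_rng(seed)
    genes = list(reference_truth.profiles.index)
    is_module = reference_truth.gene_modules.reindex(genes).fillna("none") != "none"
    rel = np.where(is_module.to_numpy(), 0.03, rng.lognormal(0.0, 1.0, len(genes)))
    rel = np.tile(rel[:, None], (1, n_cells))
    frac = rel / rel.sum(axis=0, keepdims=True)
    depth = rng.lognormal(DEPTH_LOG_MEAN, DEPTH_LOG_SD, n_cells)
    counts = _nb_counts(rng, depth * frac, dispersion)
    ids = [f"stromal_c{i:05d}" for i in range(n_cells)]
    obs = pd.DataFrame({"species": "human", "dataset": "stroma", "cell_type": "stromal"},
                       index=ids)
    return ExpressionMatrix(pd.DataFrame(counts.astype(float), index=genes, columns=ids), obs)


def simulate_bulk_mixtures(
    stage_cells: pd.DataFrame,
    stromal_cells: pd.DataFrame,
    ratios,
    total: int = 1000,
    reps: int = 20,
    seed: int = 0,
):
    """Pseudo-bulk mixtures: for each (ratio, rep), draw ``ratio * total``
    neutrophil-stage cells and the rest stromal cells, and sum their counts.

    Sampling is without replacement when the pool is large enough, otherwise
    with replacement (logged).  Returns ``(bulk genes x samples, design)``
    where the design table records ratio, replicate and seed.
    """
    if not stage_cells.index.equals(stromal_cells.index):
        raise ValueError("stage and stromal pools must share the same gene index")
    rng = np.random.default_rng(seed)
    cols, rows = {}, []
    for ratio in ratios:
        if not 0 <= ratio <= 1:
            raise ValueError("ratios must lie in [0, 1]")
        n_neu = int(round(ratio * total))
        for rep in range(reps):
            parts = []
            for pool, n in ((stage_cells, n_neu), (stromal_cells, total - n_neu)):
                if n == 0:
                    continue
                replace = pool.shape[1] < n
                if replace:
                    logger.info("bulk mixture: pool of %d smaller than draw %d; "
                                "sampling with replacement", pool.shape[1], n)
                idx = rng.choice(pool.shape[1], size=n, replace=replace)
                parts.append(pool.to_numpy()[:, idx].sum(axis=1))
            name = f"mix_r{ratio:.2f}_rep{rep:02d}"
            cols[name] = np.sum(parts, axis=0)
            rows.append({"sample": name, "ratio": ratio, "replicate": rep, "seed": seed})
    bulk = pd.DataFrame(cols, index=stage_cells.index)
    return bulk, pd.DataFrame(rows)
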