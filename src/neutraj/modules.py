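"""Gene modules and maturation phases by DTW hierarchical clustering.

Profiles are z-scored per gene across bins, pairwise dynamic-time-warping
distances are computed under the symmetric step pattern with diagonal weight
2 and absolute-difference local cost, the distance matrix is clustered with
Ward linkage, and the number of clusters is chosen by the
Kelley-Gardner-Sutcliffe penalty.  Gene clusters become modules M1..Mk
ordered by the pseudotime of their mean-profile peak; bin clusters become
phases P1..Pg ordered by mean pseudotime, with cells inheriting the phase of
their bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io import BinnedTrajectory, PseudotimeAssignment

logger = logging.getLogger("neutraj")

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class DTWConfig:
    """DTW settings: absolute-difference local cost, symmetric step pattern
    with diagonal weight 2, no warping window, per-profile z-scoring."""

    local_cost: str = "abs"
    step_pattern: str = "symmetric2"
    window: int | None = None
    zscore: bool = True

    def __post_init__(self) -> None:
        if self.local_cost != "abs":
            raise ValueError("only absolute-difference local cost is supported")
        if self.step_pattern != "symmetric2":
            raise ValueError("only the symmetric (diagonal weight 2) step pattern is supported")


@dataclass
class KGSCurve:
    """Kelley-Gardner-Sutcliffe penalty per candidate k; chosen k = argmin."""

    ks: np.ndarray
    penalties: np.ndarray
    chosen_k: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.penalties).all():
            raise ValueError("KGS penalties must be finite")


@dataclass
class ModulePartition:
    labels: pd.Series                 # gene -> "M1"..
    linkage: np.ndarray
    kgs: KGSCurve
    k: int


@dataclass
class PhasePartition:
    bin_labels: pd.Series             # bin index -> "P1"..
    linkage: np.ndarray
    kgs: KGSCurve
    g: int
    contiguity: float                 # fraction of bins matching a contiguous relabeling
    low_quality_flag: np.ndarray = field(default=None)

    def assign_cells(self, pt: PseudotimeAssignment) -> pd.Series:
        """Cells inherit the phase of the bin their pseudotime falls in."""
        n_bins = len(self.bin_labels)
        idx = np.minimum((pt.pseudotime.to_numpy() * n_bins).astype(int), n_bins - 1)
        return pd.Series(self.bin_labels.to_numpy()[idx], index=pt.pseudotime.index)


# ---------------------------------------------------------------------------
# DTW
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dtw_core(a, b):
    n, m = a.shape[0], b.shape[0]
    big = 1e300
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        c = abs(a[0] - b[j])
        prev[j] = c if j == 0 else prev[j - 1] + c
    for i in range(1, n):
        for j in range(m):
            c = abs(a[i] - b[j])
            best = prev[j] + c
            if j > 0:
                diag = prev[j - 1] + 2.0 * c
                if diag < best:
                    best = diag
                horiz = cur[j - 1] + c
                if horiz < best:
                    best = horiz
            cur[j] = best
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=True)
def _dtw_pairwise_core(X):
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _dtw_core(X[i], X[j])
            out[i, j] = d
            out[j, i] = d
    return out


def _dtw_py(a, b):
    # numpy fallback mirroring _dtw_core
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            D[i, j] = cost[i, j] + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1] + cost[i, j])
    return D[n - 1, m - 1]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def dtw_distance(profile_a, profile_b, config: DTWConfig | None = None) -> float:
    """Dynamic-time-warping distance between two equal-axis profiles.

    Dynamic program over the full (unwindowed) alignment lattice; diagonal
    steps pay the local cost twice, vertical/horizontal steps once, so the
    distance is symmetric in its arguments.
    """
    config = config or DTWConfig()
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN in profile")
    if config.zscore:
        a, b = _zscore(a), _zscore(b)
    if _HAVE_NUMBA:
        return float(_dtw_core(a, b))
    return float(_dtw_py(a, b))


def dtw_pairwise(profiles: np.ndarray, config: DTWConfig | None = None) -> np.ndarray:
    """Symmetric matrix of DTW distances between the rows of ``profiles``."""
    config = config or DTWConfig()
    X = np.asarray(profiles, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in profiles")
    if config.zscore:
        X = np.apply_along_axis(_zscore, 1, X)
    if _HAVE_NUMBA:
        return _dtw_pairwise_core(np.ascontiguousarray(X))
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _dtw_py(X[i], X[j])
    return out


def dtw_cross(rows_a: np.ndarray, rows_b: np.ndarray, config: DTWConfig | None = None) -> np.ndarray:
    """DTW distances between every row of ``rows_a`` and every row of ``rows_b``."""
    config = config or DTWConfig()
    A = np.asarray(rows_a, dtype=float)
    B = np.asarray(rows_b, dtype=float)
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("NaN in profiles")
    if config.zscore:
        A = np.apply_along_axis(_zscore, 1, A)
        B = np.apply_along_axis(_zscore, 1, B)
    fn = _dtw_core if _HAVE_NUMBA else _dtw_py
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            out[i, j] = fn(A[i], B[j])
    return out


# ---------------------------------------------------------------------------
# KGS cluster-number selection
# ---------------------------------------------------------------------------

def kgs_select(linkage: np.ndarray, distance_matrix: np.ndarray, k_max: int = 10) -> KGSCurve:
    """Kelley-Gardner-Sutcliffe penalty over k = 2..k_max.

    For each k: the average over clusters of size >= 2 of the mean pairwise
    within-cluster distance (singletons contribute nothing); these spreads
    are min-max rescaled to [1, k_max - 1] across k, and penalty(k) =
    rescaled spread + k.  Ties in the argmin break toward smaller k.
    """
    n = distance_matrix.shape[0]
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds item count {n}")
    ks = np.arange(2, k_max + 1)
    spreads = np.empty(len(ks))
    for i, k in enumerate(ks):
        labels = sch.fcluster(linkage, t=k, criterion="maxclust")
        vals = []
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            if len(members) < 2:
                continue
            sub = distance_matrix[np.ix_(members, members)]
            vals.append(sub[np.triu_indices(len(members), 1)].mean())
        spreads[i] = np.mean(vals) if vals else 0.0
    rng_ = spreads.max() - spreads.min()
    if rng_ > 1e-12 and k_max > 2:
        rescaled = 1.0 + (spreads - spreads.min()) / rng_ * (k_max - 2)
    else:
        rescaled = np.ones_like(spreads)
    penalties = rescaled + ks
    chosen = int(ks[int(np.argmin(penalties))])
    return KGSCurve(ks, penalties, chosen)


def _ward_linkage(dmat: np.ndarray) -> np.ndarray:
    return sch.linkage(squareform(dmat, checks=False), method="ward")


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def partition_genes(
    binned: BinnedTrajectory,
    maturation_genes,
    k_max: int = 10,
    config: DTWConfig | None = None,
    k: int | None = None,
) -> ModulePartition:
    """Cluster maturation-gene profiles into modules M1..Mk.

    ``k`` overrides the KGS choice when given.  Modules are labeled in order
    of the pseudotime bin at which each module's mean z-scored profile peaks
    (earliest peak = M1).
    """
    genes = pd.Index(maturation_genes)
    missing = genes.difference(binned.gene_ids)
    if len(missing):
        raise ValueError(f"genes not in binned trajectory: {missing.tolist()[:5]}")
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to partition")
    config = config or DTWConfig()
    X = binned.values.loc[genes].to_numpy()
    Xz = np.apply_along_axis(_zscore, 1, X)
    dmat = dtw_pairwise(Xz, DTWConfig(zscore=False))
    Z = _ward_linkage(dmat)
    kgs = kgs_select(Z, dmat, k_max=k_max)
    k_use = k if k is not None else kgs.chosen_k
    raw = sch.fcluster(Z, t=k_use, criterion="maxclust")

    peaks = {}
    for lab in np.unique(raw):
        peaks[lab] = Xz[raw == lab].mean(axis=0).argmax()
    order = sorted(peaks, key=lambda lab: (peaks[lab], lab))
    rename = {lab: f"M{i + 1}" for i, lab in enumerate(order)}
    labels = pd.Series([rename[lab] for lab in raw], index=genes)
    return ModulePartition(labels, Z, kgs, k_use)


def _contiguity_fraction(labels: np.ndarray) -> float:
    """Fraction of bins consistent with the best contiguous relabeling that
    preserves cluster sizes and mean-position order."""
    uniq, counts = np.unique(labels, return_counts=True)
    means = {u: np.flatnonzero(labels == u).mean() for u in uniq}
    order = sorted(uniq, key=lambda u: means[u])
    ideal = np.concatenate([[u] * int(counts[list(uniq).index(u)]) for u in order])
    return float((ideal == labels).mean())


def partition_phases(
    binned: BinnedTrajectory,
    maturation_genes,
    k_max: int = 10,
    config: DTWConfig | None = None,
    g: int | None = None,
) -> PhasePartition:
    """Cluster the trajectory bins into maturation phases P1..Pg.

    Bins are represented as vectors over the (z-scored) maturation genes and
    clustered with the same DTW + Ward + KGS machinery used for genes.
    Phases are labeled by mean pseudotime; contiguity along the bin axis is
    reported (not enforced).  Low-quality bins are assigned like any other
    and their flag propagated.
    """
    genes = pd.Index(maturation_genes)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    X = binned.values.loc[genes].to_numpy()
    Xz = np.apply_along_axis(_zscore, 1, X)     # z-score per gene across bins
    bins_as_rows = Xz.T                          # one row per bin
    dmat = dtw_pairwise(bins_as_rows, DTWConfig(zscore=False))
    Z = _ward_linkage(dmat)
    kgs = kgs_select(Z, dmat, k_max=k_max)
    g_use = g if g is not None else kgs.chosen_k
    raw = sch.fcluster(Z, t=g_use, criterion="maxclust")

    means = {lab: np.flatnonzero(raw == lab).mean() for lab in np.unique(raw)}
    order = sorted(means, key=lambda lab: means[lab])
    rename = {lab: f"P{i + 1}" for i, lab in enumerate(order)}
    labels = pd.Series([rename[lab] for lab in raw], index=range(binned.n_bins))
    return PhasePartition(
        labels, Z, kgs, g_use,
        contiguity=_contiguity_fraction(raw),
        low_quality_flag=binned.low_quality_flag.copy(),
    )


def summarize_modules(
    binned: BinnedTrajectory,
    modules: ModulePartition,
    phases: PhasePartition,
) -> pd.DataFrame:
    """Module x phase table of mean z-scored expression."""
    genes = modules.labels.index
    Xz = np.apply_along_axis(_zscore, 1, binned.values.loc[genes].to_numpy())
    df = pd.DataFrame(Xz, index=genes, columns=range(binned.n_bins))
    long = df.stack().rename("z").reset_index()
    long.columns = ["gene", "bin", "z"]
    long["module"] = modules.labels.loc[long["gene"]].to_numpy()
    long["phase"] = phases.bin_labels.loc[long["bin"]].to_numpy()
    table = long.pivot_table(index="module", columns="phase", values="z", aggfunc="mean")
    return table.sort_index().sort_index(axis=1)
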