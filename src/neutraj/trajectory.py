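"""Maturation pseudotime, trajectory binning and gene association testing.

Pseudotime is the min-max-rescaled rank of cells along the first latent
component of the normalized expression (``component1`` mode, the default),
or arc-length along a principal curve fitted in the top two components.
Orientation is fixed by two marker genes: one expected to fall along
maturation (lysozyme-like) and one expected to rise (mmp9-like); on
disagreement the rising marker wins.

Association of each gene with pseudotime is tested by regressing its
normalized expression on a cubic B-spline basis (6 interior knots) and
comparing against the intercept-only model with an F-test — a Gaussian
stand-in for a negative-binomial GAM that yields the same ranking on
log-normalized data.  Benjamini-Hochberg-adjusted p < 0.05 genes are ranked
by statistic and the top 1500 kept as maturation-associated genes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.interpolate import BSpline
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import BinnedTrajectory, ExpressionMatrix, PseudotimeAssignment

logger = logging.getLogger("neutraj")

# mitochondrial / ribosomal / hemoglobin exclusion, case-insensitive
DEFAULT_EXCLUDE_REGEXES = (r"^rp[sl]", r"^mt-", r"^hb[ba]")


@dataclass
class AssociationResult:
    """Per-gene association with pseudotime."""

    table: pd.DataFrame        # gene-indexed: statistic, pvalue, padj, selected
    excluded: list             # genes removed before testing

    def __post_init__(self) -> None:
        t = self.table
        if ((t["pvalue"] < 0) | (t["pvalue"] > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        if (t["padj"] + 1e-12 < t["pvalue"]).any():
            raise ValueError("adjusted p must be >= raw p")

    @property
    def selected_genes(self) -> list:
        return self.table.index[self.table["selected"]].tolist()


def _zscore_rows(arr: np.ndarray) -> np.ndarray:
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (arr - mean) / sd


def _rank_rescale(x: np.ndarray) -> np.ndarray:
    r = scipy.stats.rankdata(x, method="average") - 1
    return r / max(len(x) - 1, 1)


def _principal_curve_lambda(pts: np.ndarray, n_iter: int = 8) -> np.ndarray:
    """Hastie-Stuetzle principal curve in 2D; returns arc-length positions."""
    lam = pts[:, 0].copy()
    for _ in range(n_iter):
        order = np.argsort(lam, kind="stable")
        lam_s = lam[order]
        # smooth each coordinate against the current ordering (running mean)
        win = max(5, len(lam) // 50)
        kernel = np.ones(win) / win
        curve = np.column_stack([
            np.convolve(np.pad(pts[order, d], (win // 2, win - 1 - win // 2), mode="edge"),
                        kernel, mode="valid")
            for d in range(pts.shape[1])
        ])
        seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        arc = np.concatenate([[0], np.cumsum(seg)])
        # project each point to its nearest curve vertex
        d2 = ((pts[:, None, :] - curve[None, ::5, :]) ** 2).sum(axis=2)
        lam = arc[::5][np.argmin(d2, axis=1)]
    return lam


def infer_pseudotime(
    expr: ExpressionMatrix,
    orientation_marker_down: str,
    orientation_marker_up: str,
    mode: str = "component1",
) -> PseudotimeAssignment:
    """Order cells along maturation and rescale to [0, 1].

    ``component1``: rank of the first principal component of the per-gene
    z-scored normalized expression.  ``principal_curve``: arc-length along a
    principal curve fitted in the top two components.  The orientation is
    flipped so that ``orientation_marker_up`` increases along pseudotime; if
    ``orientation_marker_down`` does not then decrease, a warning is logged
    (the rising marker wins).
    """
    for marker in (orientation_marker_down, orientation_marker_up):
        if marker not in expr.gene_ids:
            raise ValueError(f"orientation marker {marker!r} not in expression matrix")
    X = _zscore_rows(expr.values.to_numpy()).T  # cells x genes
    n_comp = 1 if mode == "component1" else 2
    pca = PCA(n_components=n_comp, svd_solver="full")
    comps = pca.fit_transform(X)
    if pca.explained_variance_[0] < 1e-12:
        raise ValueError("degenerate first component (zero variance)")
    if mode == "component1":
        lam = comps[:, 0]
    elif mode == "principal_curve":
        lam = _principal_curve_lambda(comps)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pt = _rank_rescale(lam)

    up = expr.values.loc[orientation_marker_up].to_numpy()
    down = expr.values.loc[orientation_marker_down].to_numpy()
    rho_up = scipy.stats.spearmanr(up, pt).statistic
    if rho_up < 0:
        pt = 1.0 - pt
    rho_down = scipy.stats.spearmanr(down, pt).statistic
    if rho_down >= 0:
        logger.warning(
            "orientation markers disagree: %s does not decrease along pseudotime "
            "(rho=%.3f); orientation follows rising marker %s",
            orientation_marker_down, rho_down, orientation_marker_up,
        )
    return PseudotimeAssignment(
        pd.Series(pt, index=expr.cell_ids), orientation_marker_used=orientation_marker_up
    )


def bin_trajectory(expr: ExpressionMatrix, pt: PseudotimeAssignment, n_bins: int = 100) -> BinnedTrajectory:
    """Discretize the trajectory into ``n_bins`` bins of mean expression.

    Bin b covers [b/n_bins, (b+1)/n_bins), the last bin closed.  Empty bins
    are linearly interpolated from their neighbors and flagged; bins with
    <= 3 cells carry the low-quality flag.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    t = pt.pseudotime.reindex(expr.cell_ids)
    if t.isna().any():
        raise ValueError("pseudotime undefined for some cells")
    # epsilon guards against float representation of exact bin boundaries
    idx = np.minimum(np.floor(t.to_numpy() * n_bins + 1e-9).astype(int), n_bins - 1)
    arr = expr.values.to_numpy()
    sums = np.zeros((arr.shape[0], n_bins))
    counts = np.bincount(idx, minlength=n_bins)
    np.add.at(sums.T, idx, arr.T)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    empty = counts == 0
    if empty.any():
        filled = np.arange(n_bins)[~empty]
        for gi in range(means.shape[0]):
            means[gi, empty] = np.interp(np.arange(n_bins)[empty], filled, means[gi, ~empty])
    values = pd.DataFrame(means, index=expr.gene_ids, columns=range(n_bins))
    return BinnedTrajectory(values, counts)


def default_exclusion_mask(gene_ids: pd.Index, regexes=DEFAULT_EXCLUDE_REGEXES) -> np.ndarray:
    """True for genes matching any exclusion regex (case-insensitive)."""
    mask = np.zeros(len(gene_ids), dtype=bool)
    for rx in regexes:
        pat = re.compile(rx, re.IGNORECASE)
        mask |= np.fromiter((bool(pat.search(g)) for g in gene_ids), bool, len(gene_ids))
    return mask


def _bspline_basis(t: np.ndarray, knots: int) -> np.ndarray:
    """Cubic B-spline design matrix with ``knots`` interior knots at
    quantiles of ``t`` (plus an intercept column)."""
    interior = np.quantile(t, np.linspace(0, 1, knots + 2)[1:-1])
    interior = np.unique(interior)
    kv = np.concatenate([[t.min()] * 4, interior, [t.max()] * 4])
    basis = BSpline.design_matrix(np.clip(t, kv[0], kv[-1]), kv, 3).toarray()
    return np.column_stack([np.ones(len(t)), basis])


def association_test(
    expr: ExpressionMatrix,
    pt: PseudotimeAssignment,
    knots: int = 6,
    exclusions=DEFAULT_EXCLUDE_REGEXES,
    raw_counts: ExpressionMatrix | None = None,
    min_cells_expressing: int = 5,
    min_reads: int = 3,
    alpha: float = 0.05,
    top_n: int = 1500,
) -> AssociationResult:
    """Test each gene for association with pseudotime.

    Mitochondrial/ribosomal/hemoglobin genes (``exclusions`` regexes) and —
    when ``raw_counts`` is supplied — genes with fewer than
    ``min_cells_expressing`` cells at >= ``min_reads`` reads are removed
    before testing.  Genes with BH-adjusted p < ``alpha`` are ranked by
    descending F statistic; the top ``top_n`` carry the selected flag.
    """
    # rank-rescale so the statistic is invariant to monotone reparametrizations
    t = _rank_rescale(pt.pseudotime.reindex(expr.cell_ids).to_numpy())
    X = _bspline_basis(t, knots)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more cells ({n}) than spline degrees of freedom ({p})")

    excl_mask = default_exclusion_mask(expr.gene_ids, exclusions)
    if raw_counts is not None:
        cnt = raw_counts.values.reindex(index=expr.gene_ids, columns=expr.cell_ids)
        n_expressing = (cnt.to_numpy() >= min_reads).sum(axis=1)
        excl_mask |= n_expressing < min_cells_expressing
    excluded = expr.gene_ids[excl_mask].tolist()
    genes = expr.gene_ids[~excl_mask]
    Y = expr.values.loc[genes].to_numpy().T  # cells x genes

    Q, _ = np.linalg.qr(X)
    fitted_ss = (Q.T @ Y) ** 2
    total_ss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    rss1 = np.maximum((Y ** 2).sum(axis=0) - fitted_ss.sum(axis=0), 0.0)
    rss0 = total_ss
    df1, df2 = p - 1, n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / np.where(rss1 > 0, rss1 / df2, np.nan)
    F = np.where(np.isfinite(F), F, 0.0)
    constant = total_ss < 1e-12
    pvals = scipy.stats.f.sf(F, df1, df2)
    pvals[constant] = 1.0
    F[constant] = 0.0
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")

    table = pd.DataFrame({"statistic": F, "pvalue": pvals, "padj": padj}, index=genes)
    sig = table.index[table["padj"] < alpha]
    top = table.loc[sig].sort_values("statistic", ascending=False).head(top_n).index
    table["selected"] = table.index.isin(top)
    logger.info("association_test: %d tested, %d excluded, %d selected",
                len(genes), len(excluded), int(table["selected"].sum()))
    return AssociationResult(table, excluded)
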