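"""Signature scoring: ssGSEA, per-cell module scores, over-representation
and the mixing sensitivity analysis.

ssGSEA follows the Barbie-style running-sum integral: genes are ranked per
sample by expression, the running sum steps up by the normalized
|rank statistic|^alpha for in-set genes and down by 1/(N - |S|) otherwise,
and the score is the sum of the running sum over all positions.  Being
rank-based, the score is invariant to any strictly monotone transform of a
sample's expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SignatureSet
from .simulate import simulate_bulk_mixtures

logger = logging.getLogger("neutraj")


@dataclass
class EnrichmentTable:
    """Samples x signatures enrichment scores."""

    scores: pd.DataFrame
    normalized: bool = True
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("scores must be finite")
        if self.scores.index.duplicated().any() or self.scores.columns.duplicated().any():
            raise ValueError("sample and signature ids must be unique")


def _as_sets(signatures) -> dict:
    if isinstance(signatures, SignatureSet):
        return signatures.sets
    return dict(signatures)


def _ssgsea_sample(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum integral for one sample.

    ``expr`` is the sample's expression vector, ``in_set`` the membership
    mask.  The rank statistic is the (tie-averaged) ascending rank, so the
    most expressed gene carries the largest weight.
    """
    n = len(expr)
    ranks = scipy.stats.rankdata(expr, method="average")
    order = np.lexsort((np.arange(n), -ranks))  # descending expression, stable
    r_sorted = ranks[order]
    mask = in_set[order]
    n_set = int(mask.sum())
    weights = np.abs(r_sorted) ** alpha
    up = np.where(mask, weights, 0.0)
    denom = up.sum()
    p_in = np.cumsum(up) / denom
    p_out = np.cumsum(np.where(mask, 0.0, 1.0)) / (n - n_set)
    return float(np.sum(p_in - p_out))


def ssgsea(
    bulk: pd.DataFrame,
    signatures,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentTable:
    """Single-sample gene set enrichment over a genes x samples matrix.

    With ``normalize`` the full score matrix is divided by its global range
    (max - min over all scores), the GSVA-style convention; without it the
    raw running-sum integrals are returned.
    """
    sets = _as_sets(signatures)
    genes = bulk.index
    masks = {}
    for name, members in sets.items():
        mask = np.asarray(genes.isin(set(members)))
        n_in = int(mask.sum())
        if n_in == 0:
            raise ValueError(f"signature {name!r} shares no genes with the matrix")
        if n_in == len(genes):
            raise ValueError(f"signature {name!r} covers every gene")
        masks[name] = mask
    arr = bulk.to_numpy(dtype=float)
    out = np.empty((bulk.shape[1], len(masks)))
    for j in range(bulk.shape[1]):
        for s_idx, (name, mask) in enumerate(masks.items()):
            out[j, s_idx] = _ssgsea_sample(arr[:, j], mask, alpha)
    scores = pd.DataFrame(out, index=bulk.columns, columns=list(masks))
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return EnrichmentTable(scores, normalized=normalize, alpha=alpha)


def module_score(
    sc_expr: ExpressionMatrix | pd.DataFrame,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score: mean set expression minus the mean expression
    of expression-matched control genes.

    All genes are grouped into ``n_bins`` bins of average expression; each
    set gene contributes up to ``n_ctrl`` control genes drawn (without
    replacement) from its bin.  Deterministic given ``seed``.
    """
    values = sc_expr.values if isinstance(sc_expr, ExpressionMatrix) else sc_expr
    rng = np.random.default_rng(seed)
    present = [g for g in gene_set if g in values.index]
    absent = [g for g in gene_set if g not in values.index]
    if absent:
        logger.info("module_score: %d set gene(s) absent, dropped: %s", len(absent), absent[:3])
    if not present:
        raise ValueError("no set gene present in the matrix")
    means = values.mean(axis=1)
    bins = pd.qcut(means.rank(method="first"), q=min(n_bins, len(means)), labels=False)
    ctrl_genes: set = set()
    for g in present:
        pool = means.index[(bins == bins[g]).to_numpy()]
        pool = pool[pool != g] if len(pool) > 1 else pool
        take = min(n_ctrl, len(pool))
        ctrl_genes.update(rng.choice(pool, size=take, replace=False))
    ctrl_genes = sorted(ctrl_genes - set(present)) or sorted(ctrl_genes)
    set_mean = values.loc[present].mean(axis=0)
    ctrl_mean = values.loc[ctrl_genes].mean(axis=0)
    return set_mean - ctrl_mean


def hypergeom_enrichment(
    module_genes,
    gene_set_collection,
    background,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Upper one-tailed hypergeometric over-representation of a gene module
    against a collection of gene sets, with BH FDR."""
    background = pd.Index(dict.fromkeys(background))
    module = pd.Index(dict.fromkeys(module_genes))
    if not module.isin(background).all():
        raise ValueError("module genes must be a subset of the background")
    sets = _as_sets(gene_set_collection)
    M, n = len(background), len(module)
    rows = []
    for name, members in sets.items():
        in_bg = background.intersection(pd.Index(members))
        if len(in_bg) == 0:
            logger.info("hypergeom_enrichment: set %s disjoint from background; skipped", name)
            continue
        K = len(in_bg)
        k = len(module.intersection(in_bg))
        p = float(scipy.stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"set": name, "set_size": K, "overlap": k,
                     "overlap_ratio": k / K, "pvalue": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
        table["significant"] = table["fdr"] < fdr_threshold
        table = table.sort_values(["fdr", "pvalue"]).reset_index(drop=True)
    return table


def mixing_sensitivity(
    stage_cells: pd.DataFrame,
    stromal_cells: pd.DataFrame,
    signatures,
    ratios=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    total: int = 1000,
    reps: int = 20,
    seed: int = 0,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """ssGSEA sensitivity to the neutrophil fraction of pseudo-bulk mixtures.

    Cells from the maturation-stage pool are mixed with stromal cells at the
    given ratios to ``total`` cells, ``reps`` times; mixtures are log-CPM
    normalized, scored by ssGSEA, and the median over replicates reported
    per (ratio, signature).
    """
    bulk, design = simulate_bulk_mixtures(stage_cells, stromal_cells, ratios,
                                          total=total, reps=reps, seed=seed)
    totals = bulk.sum(axis=0)
    logcpm = np.log1p(bulk / totals * 1e6)
    enr = ssgsea(logcpm, signatures, alpha=alpha)
    scores = enr.scores.copy()
    scores["ratio"] = design.set_index("sample").loc[scores.index, "ratio"].to_numpy()
    return scores.groupby("ratio").median().sort_index()
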