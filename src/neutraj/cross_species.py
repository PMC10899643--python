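"""Cross-dataset stage integration and cross-species trajectory alignment.

Stage-level: per-stage mean profiles from each dataset are quantile
normalized together, scaled within each dataset, clustered on Pearson
distance with Ward linkage, and every stage carries a 0-1 maturation score
(its rank among its own dataset's stages); dendrogram leaves are reordered
within the tree constraints by ascending score.

Gene-level: homologs are collapsed onto the reference namespace (1-to-many
resolved by the highest detection rate), each gene's binned profile in each
query dataset is aligned to the reference by cross-correlation, and the lag
maximizing the correlation is recorded.  Positive lag means the query
pattern occurs later than the reference.  Genes whose mean lag across query
datasets stays within a threshold (default 50 bins of 100) and that are not
on a cell-type marker blacklist form the pan-species module signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, HomologyMap, SignatureSet

logger = logging.getLogger("neutraj")


@dataclass
class StageProfileMatrix:
    """Genes x (dataset, stage) profiles with per-stage maturation scores."""

    values: pd.DataFrame              # columns: MultiIndex (dataset, stage)
    scores: pd.Series                 # per (dataset, stage) in [0, 1]
    linkage: np.ndarray | None = None
    leaf_order: list = field(default_factory=list)
    normalization: str = "raw"


@dataclass
class LagTable:
    """Cross-correlation alignment of query datasets onto the reference."""

    per_gene_dataset: pd.DataFrame    # gene, dataset, lag, coefficient
    mean_lag: pd.Series               # per gene, mean over query datasets
    module_coefficient: pd.DataFrame  # dataset x module mean peak coefficient
    max_lag: int = 99
    dataset_linkage: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.per_gene_dataset["lag"].abs() > self.max_lag).any():
            raise ValueError("|lag| exceeds max_lag")
        coef = self.per_gene_dataset["coefficient"]
        if ((coef < -1 - 1e-9) | (coef > 1 + 1e-9)).any():
            raise ValueError("coefficient outside [-1, 1]")


# ---------------------------------------------------------------------------
# stage-level integration
# ---------------------------------------------------------------------------

def aggregate_stages(values: pd.DataFrame, stage_labels: pd.Series) -> pd.DataFrame:
    """Mean-aggregate columns (cells/samples) per maturation stage, keeping
    the stage order of first appearance."""
    labels = stage_labels.reindex(values.columns)
    if labels.isna().any():
        raise ValueError("every column needs a stage label")
    order = list(dict.fromkeys(labels))
    for stage in order:
        if (labels == stage).sum() == 0:
            raise ValueError(f"stage {stage!r} is empty")
    out = {stage: values.loc[:, (labels == stage).to_numpy()].mean(axis=1) for stage in order}
    return pd.DataFrame(out)[order]


def quantile_normalize(joined: pd.DataFrame) -> pd.DataFrame:
    """Rank-based quantile normalization across columns.

    Each column is sorted, values are averaged across columns at each sort
    position, and the averages are mapped back through each column's
    original (average-tie) ranks — afterwards tie-free columns share an
    identical multiset of values (tied values land on the mean of their
    tied positions' grid values).
    """
    if joined.isna().any().any():
        raise ValueError("missing values not allowed")
    if joined.shape[1] == 1:
        logger.info("quantile_normalize: single column, returning input unchanged")
        return joined.copy()
    arr = joined.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    positions = np.arange(1, arr.shape[0] + 1, dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = pd.Series(arr[:, j]).rank(method="average").to_numpy()
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    return pd.DataFrame(out, index=joined.index, columns=joined.columns)


def _reorder_leaves_by_score(Z: np.ndarray, scores: np.ndarray) -> list:
    """Leaf order with subtrees swapped so mean score ascends, within the
    constraints of the tree."""
    n = Z.shape[0] + 1

    def walk(node):
        if node < n:
            return [node], scores[node]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        lo, lm = walk(left)
        ro, rm = walk(right)
        if lm <= rm:
            order = lo + ro
        else:
            order = ro + lo
        total = (lm * len(lo) + rm * len(ro)) / (len(lo) + len(ro))
        return order, total

    order, _ = walk(2 * n - 2)
    return order


def cluster_stages(stage_matrix: pd.DataFrame, normalization: str = "quantile_normalized") -> StageProfileMatrix:
    """Cluster maturation stages across datasets.

    ``stage_matrix`` has genes as rows and a (dataset, stage) MultiIndex of
    columns whose stage order within each dataset reflects maturation.
    Profiles are z-scored per gene within each dataset, stages are clustered
    on Pearson distance (1 - r) with Ward linkage, each stage gets a 0-1
    maturation score from its rank within its own dataset (a single-stage
    dataset scores 0), and leaves are reordered by ascending mean score.
    """
    if not isinstance(stage_matrix.columns, pd.MultiIndex):
        raise ValueError("columns must be a (dataset, stage) MultiIndex")
    scaled = stage_matrix.copy().astype(float)
    for ds in stage_matrix.columns.get_level_values(0).unique():
        block = scaled[ds]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0).replace(0, 1.0)
        scaled[ds] = block.sub(mu, axis=0).div(sd, axis=0).to_numpy()
    const = scaled.std(axis=1, ddof=0) < 1e-12
    if const.any() and not const.all():
        logger.warning("cluster_stages: dropping %d constant gene rows before correlation",
                       int(const.sum()))
        scaled = scaled.loc[~const]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(scaled.to_numpy().T)
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns (single-stage datasets)
    dmat = 1.0 - corr
    np.fill_diagonal(dmat, 0.0)
    dmat = np.clip((dmat + dmat.T) / 2, 0, None)
    Z = sch.linkage(squareform(dmat, checks=False), method="ward")

    scores = {}
    for ds in stage_matrix.columns.get_level_values(0).unique():
        stages = [c for c in stage_matrix.columns if c[0] == ds]
        if len(stages) == 1:
            logger.info("cluster_stages: dataset %s has one stage; score 0 by convention", ds)
            scores[stages[0]] = 0.0
        else:
            for i, c in enumerate(stages):
                scores[c] = i / (len(stages) - 1)
    score_ser = pd.Series([scores[c] for c in stage_matrix.columns], index=stage_matrix.columns)
    order_idx = _reorder_leaves_by_score(Z, score_ser.to_numpy())
    leaf_order = [stage_matrix.columns[i] for i in order_idx]
    return StageProfileMatrix(stage_matrix, score_ser, Z, leaf_order, normalization)


# ---------------------------------------------------------------------------
# homology collapse
# ---------------------------------------------------------------------------

def collapse_homology(expr: ExpressionMatrix, hmap: HomologyMap) -> ExpressionMatrix:
    """Rename query genes to their reference homolog.

    A source gene mapping to several targets keeps the target with the
    highest detection rate; several sources competing for one target keep
    the source with the highest rate (others dropped and logged).  Ties
    break lexicographically (logged).  Genes without a mapping pass through
    unchanged (so the operation is idempotent); cross-dataset intersection
    happens downstream.
    """
    rec = hmap.records.copy()
    rec = rec[rec["source_gene"].isin(expr.gene_ids)]

    # per source: best target by rate, lexicographic tie-break
    rec = rec.sort_values(["source_gene", "detection_rate", "target_gene"],
                          ascending=[True, False, True])
    tied = rec.duplicated(subset=["source_gene", "detection_rate"], keep=False)
    if tied.any():
        logger.info("collapse_homology: detection-rate ties for %s broken lexicographically",
                    rec.loc[tied, "source_gene"].unique().tolist()[:5])
    best_t = rec.drop_duplicates("source_gene", keep="first")

    # per target: best source by rate
    best = best_t.sort_values(["target_gene", "detection_rate", "source_gene"],
                              ascending=[True, False, True])
    dropped = best[best.duplicated("target_gene", keep="first")]
    if len(dropped):
        logger.info("collapse_homology: dropped %d lower-rate homolog(s): %s",
                    len(dropped), dropped["source_gene"].tolist()[:5])
    best = best.drop_duplicates("target_gene", keep="first")

    mapping = dict(zip(best["source_gene"], best["target_gene"]))
    losers = set(hmap.records["source_gene"]) - set(mapping)
    targets = set(mapping.values())
    keep = [g for g in expr.gene_ids
            if g in mapping or (g not in losers and g not in targets)]
    values = expr.values.loc[keep].rename(index=mapping)
    return ExpressionMatrix(values, expr.obs.copy(), expr.norm)


# ---------------------------------------------------------------------------
# cross-correlation alignment
# ---------------------------------------------------------------------------

def cross_correlate(ref_profile, query_profile, max_lag: int = 99):
    """Best alignment lag of a query profile onto the reference.

    r(k) = sum_t (x_{t+k} - xbar)(y_t - ybar) / (n * s_x * s_y) over the
    overlapping positions, with y the reference and x the query; the
    returned lag maximizes r (ties: smallest |k|, then the negative lag).
    Positive lag = the query pattern occurs later than the reference.
    """
    y = np.asarray(ref_profile, dtype=float)
    x = np.asarray(query_profile, dtype=float)
    if len(x) != len(y):
        raise ValueError("profiles must have equal length")
    n = len(x)
    sx, sy = x.std(), y.std()
    if sx < 1e-12 or sy < 1e-12:
        raise ValueError("zero-variance profile")
    xc = (x - x.mean()) / sx
    yc = (y - y.mean()) / sy
    max_lag = min(max_lag, n - 1)
    best_lag, best_r = 0, -np.inf
    for k in range(-max_lag, max_lag + 1):
        if k >= 0:
            r = float(np.dot(xc[k:], yc[: n - k])) / n
        else:
            r = float(np.dot(xc[: n + k], yc[-k:])) / n
        if r > best_r + 1e-15 or (
            abs(r - best_r) <= 1e-15 and (abs(k) < abs(best_lag) or
                                          (abs(k) == abs(best_lag) and k < best_lag))
        ):
            best_lag, best_r = k, r
    return best_lag, best_r


def build_lag_table(
    ref_binned: pd.DataFrame,
    dataset_binneds: dict,
    modules: pd.Series,
    max_lag: int = 99,
    cluster_datasets: bool = False,
) -> LagTable:
    """Per-gene per-dataset cross-correlation lags against the reference.

    ``ref_binned`` and each entry of ``dataset_binneds`` are genes x bins
    mean-profile frames on the collapsed (reference) gene namespace; only
    genes common to the reference and every dataset are used.  Also reports
    the per-gene mean lag across datasets and the per-(dataset, module)
    mean peak coefficient.
    """
    common = ref_binned.index
    for name, df in dataset_binneds.items():
        common = common.intersection(df.index)
    if len(common) == 0:
        raise ValueError("empty common gene set across datasets")
    rows = []
    for name, df in dataset_binneds.items():
        for gene in common:
            try:
                lag, coef = cross_correlate(
                    ref_binned.loc[gene].to_numpy(), df.loc[gene].to_numpy(), max_lag
                )
            except ValueError:
                logger.info("build_lag_table: zero-variance profile for %s in %s; skipped",
                            gene, name)
                continue
            rows.append({"gene": gene, "dataset": name, "lag": lag, "coefficient": coef})
    per = pd.DataFrame(rows)
    mean_lag = per.groupby("gene")["lag"].mean()
    per["module"] = modules.reindex(per["gene"]).fillna("none").to_numpy()
    module_coef = per.pivot_table(index="dataset", columns="module",
                                  values="coefficient", aggfunc="mean")
    Z = None
    if cluster_datasets and module_coef.shape[0] > 2:
        from scipy.spatial.distance import pdist
        Z = sch.linkage(pdist(module_coef.fillna(0).to_numpy()), method="ward")
    return LagTable(per, mean_lag, module_coef, max_lag=max_lag, dataset_linkage=Z)


def derive_pan_signature(
    lag_table: LagTable,
    modules: pd.Series,
    blacklist=(),
    lag_threshold: float = 50,
) -> SignatureSet:
    """Pan-species module signatures: per module, the genes whose |mean lag|
    is <= ``lag_threshold`` (inclusive) and that are not blacklisted cell-type
    markers.  Emitted GMT-compatible with per-gene provenance."""
    blacklist = set(blacklist)
    sets, rows = {}, []
    for module in sorted(m for m in modules.unique() if m != "none"):
        genes = modules.index[modules == module]
        kept = []
        for g in genes:
            lag = lag_table.mean_lag.get(g, np.nan)
            black = g in blacklist
            ok = bool(np.isfinite(lag) and abs(lag) <= lag_threshold and not black)
            rows.append({"signature": f"{module}pan", "gene": g, "module": module,
                         "mean_lag": lag, "blacklisted": black, "included": ok})
            if ok:
                kept.append(g)
        if kept:
            sets[f"{module}pan"] = kept
        else:
            logger.warning("derive_pan_signature: module %s yields an empty pan set", module)
    provenance = pd.DataFrame(rows)
    desc = {name: "pan-species maturation signature" for name in sets}
    return SignatureSet(sets, desc, provenance)
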