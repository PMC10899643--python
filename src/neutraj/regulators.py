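"""Candidate-regulator ranking by scaled DTW similarity.

For every transcription factor l and maturation gene i, the DTW distance
d_il between their binned profiles is rescaled per gene across TFs into a
similarity s_il = 1 - d_il / max_l(d_il), so the most distant TF scores 0
and a perfectly matching TF scores 1.  DTW's warping absorbs the expected
lead of a regulator over its targets.  A TF is called a candidate regulator
of the module where its similarities are highest (by median) when a
Kruskal-Wallis test across modules followed by Dunn's post-hoc contrasts
(Holm-adjusted) confirms that module stands apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import BinnedTrajectory
from .modules import DTWConfig, ModulePartition, dtw_cross

logger = logging.getLogger("neutraj")


@dataclass
class RegulatorScoreTable:
    """TF x gene scaled DTW similarities, optionally with per-module stats."""

    similarity: pd.DataFrame          # TFs (rows) x genes (columns), values in [0, 1]
    stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        s = self.similarity.to_numpy()
        if ((s < -1e-9) | (s > 1 + 1e-9)).any():
            raise ValueError("similarities must lie in [0, 1]")


def scaled_dtw_similarity(
    tf_binned: BinnedTrajectory | pd.DataFrame,
    target_binned: BinnedTrajectory | pd.DataFrame,
    config: DTWConfig | None = None,
    max_over: str = "tfs",
) -> RegulatorScoreTable:
    """Scaled DTW similarity between each TF and each target gene.

    ``max_over="tfs"`` (default) normalizes each gene's distances by its
    maximum over TFs; ``max_over="genes"`` normalizes each TF's distances by
    its maximum over genes (the alternative reading, behind this flag).
    """
    tfs = tf_binned.values if isinstance(tf_binned, BinnedTrajectory) else tf_binned
    targets = target_binned.values if isinstance(target_binned, BinnedTrajectory) else target_binned
    if tfs.shape[0] < 2 and max_over == "tfs":
        raise ValueError("need >= 2 TFs for the per-gene max normalization")
    if not tfs.columns.equals(targets.columns):
        raise ValueError("TF and target profiles must share the binned axis")
    d = dtw_cross(tfs.to_numpy(), targets.to_numpy(), config)
    if max_over == "tfs":
        denom = d.max(axis=0, keepdims=True)
    elif max_over == "genes":
        denom = d.max(axis=1, keepdims=True)
    else:
        raise ValueError("max_over must be 'tfs' or 'genes'")
    degenerate = denom <= 1e-12
    if degenerate.any():
        logger.warning("scaled_dtw_similarity: zero max distance for %d gene(s); "
                       "similarity defined as 1", int(degenerate.sum()))
    s = np.where(degenerate, 1.0, 1.0 - d / np.where(degenerate, 1.0, denom))
    return RegulatorScoreTable(pd.DataFrame(s, index=tfs.index, columns=targets.index))


def _dunn_pairwise(groups: dict) -> pd.DataFrame:
    """Dunn's post-hoc z statistics from pooled rank sums with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n = len(pooled)
    ranks = scipy.stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_ranks = {g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(names)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    rows = []
    for a, b in combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        rows.append({"group_a": a, "group_b": b, "z": z,
                     "p": 2 * scipy.stats.norm.sf(abs(z))})
    return pd.DataFrame(rows)


def rank_regulators(
    scores: RegulatorScoreTable,
    modules: ModulePartition | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-TF module specificity: Kruskal-Wallis across modules, Dunn
    post-hoc with Holm adjustment, and a within-module ranking by median
    similarity.

    A TF is flagged ``specific`` for the module where its median similarity
    is highest when every Dunn contrast of that module against the others is
    significant at ``alpha`` after Holm adjustment.
    """
    labels = modules.labels if isinstance(modules, ModulePartition) else modules
    labels = labels[labels.index.isin(scores.similarity.columns)]
    module_names = sorted(labels.unique())
    for m in module_names:
        if (labels == m).sum() < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")

    rows = []
    for tf in scores.similarity.index:
        sims = scores.similarity.loc[tf]
        groups = {m: sims[labels.index[labels == m]].to_numpy() for m in module_names}
        if len(module_names) > 1:
            kw_stat, kw_p = scipy.stats.kruskal(*groups.values())
        else:
            kw_stat, kw_p = 0.0, 1.0
        medians = {m: float(np.median(groups[m])) for m in module_names}
        best = max(medians, key=lambda m: (medians[m], m))
        dunn = _dunn_pairwise(groups) if len(module_names) > 1 else pd.DataFrame()
        if len(dunn):
            dunn["p_holm"] = multipletests(dunn["p"], method="holm")[1]
            vs_best = dunn[(dunn["group_a"] == best) | (dunn["group_b"] == best)]
            specific = bool((vs_best["p_holm"] < alpha).all()) and kw_p < alpha
        else:
            specific = False
        for m in module_names:
            rows.append({
                "tf": tf, "module": m, "median_similarity": medians[m],
                "kw_statistic": kw_stat, "kw_pvalue": kw_p,
                "best_module": best, "specific": specific and m == best,
            })
    table = pd.DataFrame(rows)
    table["rank"] = (
        table.groupby("module")["median_similarity"]
        .rank(ascending=False, method="min")
        .astype(int)
    )
    return table.sort_values(["module", "rank"]).reset_index(drop=True)


def load_tf_list(path, genes, pattern_overrides=None) -> list:
    """Read a TF id list (first TSV column), deduplicate, intersect with the
    expression genes; missing TFs are logged.  ``pattern_overrides`` adds
    regex-matched genes from the matrix."""
    tf = pd.read_csv(path, sep="\t", header=None)
    if tf.empty:
        raise ValueError("empty TF list file")
    wanted = list(dict.fromkeys(tf[0].astype(str)))
    genes = pd.Index(genes)
    if pattern_overrides:
        import re
        for rx in pattern_overrides:
            pat = re.compile(rx, re.IGNORECASE)
            wanted.extend(g for g in genes if pat.search(g) and g not in wanted)
    present = [g for g in wanted if g in genes]
    missing = [g for g in wanted if g not in genes]
    if missing:
        logger.warning("load_tf_list: %d TFs absent from matrix (e.g. %s)",
                       len(missing), missing[:3])
    if not present:
        raise ValueError("no TF from the list is present in the expression matrix")
    return present
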