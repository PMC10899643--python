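"""Domain containers and file I/O.

Expression data are held genes x cells throughout the package; every reader
and writer documents that orientation.  Counts matrices are exchanged as
1-based MTX coordinate triplets (with separate gene/cell id files) or as
dense TSV with genes as rows; gene sets travel as GMT; homology tables as
three-column TSV (source_gene, target_gene, detection_rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("neutraj")

MITO_PREFIXES = ("mt-",)  # zebrafish-style; human is "MT-", matched case-insensitively


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x cells expression with aligned per-cell metadata.

    ``values`` is a DataFrame indexed by gene id with cell ids as columns.
    ``obs`` holds one row per cell (species, dataset, sorted_gate, stage_label,
    cell_type ... whatever is known).  ``norm`` records the normalization
    state: "counts", "log1p_cp10k" or "none".
    """

    values: pd.DataFrame
    obs: pd.DataFrame | None = None
    norm: str = "counts"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate cell ids: {dups}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.obs is None:
            self.obs = pd.DataFrame(index=v.columns)
        elif not self.obs.index.equals(v.columns):
            if set(self.obs.index) != set(v.columns):
                raise ValueError("metadata rows do not align with cell ids")
            self.obs = self.obs.loc[v.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def is_counts(self) -> bool:
        arr = self.values.to_numpy()
        return bool(np.allclose(arr, np.round(arr)))

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.obs.copy(), self.norm)

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[cells], self.obs.loc[cells], self.norm)


@dataclass
class PseudotimeAssignment:
    """Per-cell pseudotime on [0, 1] plus the marker used to orient it."""

    pseudotime: pd.Series
    orientation_marker_used: str = ""

    def __post_init__(self) -> None:
        pt = self.pseudotime.to_numpy(dtype=float)
        if not np.isfinite(pt).all():
            raise ValueError("pseudotime must be finite")
        if pt.min() < 0 or pt.max() > 1:
            raise ValueError("pseudotime must lie in [0, 1]")


@dataclass
class BinnedTrajectory:
    """Genes x ordered pseudotime bins of mean expression.

    ``bin_counts[b]`` is the number of cells falling in bin b; bins with
    <= 3 cells carry ``low_quality_flag`` and empty bins are additionally
    marked ``interpolated`` (their values come from linear interpolation
    of flanking bins).
    """

    values: pd.DataFrame
    bin_counts: np.ndarray
    low_quality_flag: np.ndarray = field(default=None)
    interpolated: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        if self.bin_counts.shape[0] != self.values.shape[1]:
            raise ValueError("bin_counts length must equal number of bins")
        expect = self.bin_counts <= 3
        if self.low_quality_flag is None:
            self.low_quality_flag = expect
        self.low_quality_flag = np.asarray(self.low_quality_flag, dtype=bool)
        if not np.array_equal(self.low_quality_flag, expect):
            raise ValueError("low_quality_flag must mark exactly bins with <= 3 cells")
        if self.interpolated is None:
            self.interpolated = self.bin_counts == 0
        self.interpolated = np.asarray(self.interpolated, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def bin_centers(self) -> np.ndarray:
        n = self.n_bins
        return (np.arange(n) + 0.5) / n


@dataclass
class HomologyMap:
    """(source_gene, target_gene, detection_rate) records for one species pair."""

    records: pd.DataFrame
    source_species: str = ""
    target_species: str = ""

    def __post_init__(self) -> None:
        need = {"source_gene", "target_gene", "detection_rate"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"homology table must have columns {sorted(need)}")
        rates = self.records["detection_rate"].to_numpy(dtype=float)
        if ((rates < 0) | (rates > 1)).any() or not np.isfinite(rates).all():
            raise ValueError("detection_rate must lie in [0, 1]")


@dataclass
class SignatureSet:
    """Named gene lists with optional per-gene provenance.

    ``provenance`` (if present) has one row per (signature, gene) with
    columns such as module, mean_lag and blacklisted.
    """

    sets: dict
    descriptions: dict = field(default_factory=dict)
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cleaned = {}
        for name, genes in self.sets.items():
            genes = list(genes)
            if not genes:
                raise ValueError(f"signature {name!r} is empty")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                logger.warning("signature %s contained duplicate genes; deduplicated", name)
            cleaned[name] = uniq
        self.sets = cleaned

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def names(self) -> list:
        return list(self.sets)


# ---------------------------------------------------------------------------
# expression readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, format: str = "mtx_triplet", metadata=None) -> ExpressionMatrix:
    """Read an expression matrix (genes x cells).

    format "mtx_triplet": ``path`` is a directory containing ``matrix.mtx``
    (1-based coordinate triplets), ``genes.tsv`` and ``cells.tsv`` (one id per
    line; extra tab-separated columns of cells.tsv become per-cell metadata).
    format "dense_tsv": ``path`` is a TSV with genes as rows, a header row of
    cell ids and the gene id in the first column.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        cells_f = path / "cells.tsv"
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise FileNotFoundError(str(f))
        m = scipy.io.mmread(str(mtx))
        genes = pd.read_csv(genes_f, sep="\t", header=None)
        cells = pd.read_csv(cells_f, sep="\t", header=None)
        if m.shape[0] != len(genes) or m.shape[1] != len(cells):
            raise ValueError(
                f"matrix is {m.shape} but id files list {len(genes)} genes / {len(cells)} cells"
            )
        dense = np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=float)
        if (dense < 0).any():
            raise ValueError("negative count in MTX file")
        values = pd.DataFrame(dense, index=genes[0].astype(str), columns=cells[0].astype(str))
        values.index.name = None
        values.columns.name = None
        obs = None
        if cells.shape[1] > 1:
            obs = cells.set_index(0)
            obs.index = obs.index.astype(str)
            obs.index.name = None
            obs.columns = [f"col{i}" for i in range(1, cells.shape[1])]
    elif format == "dense_tsv":
        if not path.exists():
            raise FileNotFoundError(str(path))
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        values.index.name = None
        values.columns.name = None
        obs = None
    else:
        raise ValueError(f"unknown format {format!r}")
    if metadata is not None:
        obs = pd.read_csv(metadata, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    return ExpressionMatrix(values, obs)


def write_expression(expr: ExpressionMatrix, path, format: str = "dense_tsv") -> None:
    """Write genes x cells expression; inverse of :func:`read_expression`."""
    path = Path(path)
    if format == "dense_tsv":
        expr.values.to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        sp = scipy.sparse.coo_matrix(expr.values.to_numpy())
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp)
        pd.Series(expr.gene_ids).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
        cells = expr.obs.reset_index()
        cells.to_csv(path / "cells.tsv", sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC filters and normalization
# ---------------------------------------------------------------------------

def _require_counts(expr: ExpressionMatrix, op: str) -> None:
    if expr.norm != "counts" or not expr.is_counts():
        raise ValueError(f"{op} expects raw counts")


def filter_features(expr: ExpressionMatrix, min_cells: int = 20) -> ExpressionMatrix:
    """Keep genes detected (nonzero) in at least ``min_cells`` cells."""
    _require_counts(expr, "filter_features")
    detected = (expr.values.to_numpy() > 0).sum(axis=1)
    keep = detected >= min_cells
    out = ExpressionMatrix(expr.values.loc[keep], expr.obs.copy(), expr.norm)
    logger.info("filter_features: retained %d of %d features (min_cells=%d)",
                keep.sum(), expr.n_genes, min_cells)
    return out


def filter_cells(
    expr: ExpressionMatrix,
    min_features: int = 500,
    max_mito_frac: float = 0.10,
    mito_prefixes=MITO_PREFIXES,
) -> ExpressionMatrix:
    """Keep cells with >= ``min_features`` detected genes and a mitochondrial
    read fraction strictly below ``max_mito_frac``.

    Mitochondrial genes are recognized by a case-insensitive id prefix
    (default ``mt-``); doublet filtering is deliberately not part of this
    step — pre-filtered input is assumed for real data.
    """
    _require_counts(expr, "filter_cells")
    arr = expr.values.to_numpy()
    n_feat = (arr > 0).sum(axis=0)
    lowered = expr.gene_ids.str.lower()
    mito_mask = np.zeros(expr.n_genes, dtype=bool)
    for pref in mito_prefixes:
        mito_mask |= np.asarray(lowered.str.startswith(pref.lower()))
    if not mito_mask.any() and max_mito_frac < 1:
        logger.warning("filter_cells: no gene matches mito prefixes %s; "
                       "mitochondrial fraction treated as 0", list(mito_prefixes))
    totals = arr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, arr[mito_mask].sum(axis=0) / np.maximum(totals, 1), 0.0)
    keep = (n_feat >= min_features) & (mito_frac < max_mito_frac)
    out = expr.subset_cells(expr.cell_ids[keep])
    logger.info("filter_cells: retained %d of %d cells", int(keep.sum()), expr.n_cells)
    return out


def normalize_expression(expr: ExpressionMatrix, method: str = "log1p_cp10k") -> ExpressionMatrix:
    """Depth-normalize counts to 10,000 per cell and log1p-transform.

    This is the package's variance-stabilization stand-in: downstream
    statistics operate on binned, z-scored profiles and are insensitive to
    the specific stabilizer.  ``method="none"`` returns the input unchanged.
    """
    if method == "none":
        return ExpressionMatrix(expr.values.copy(), expr.obs.copy(), expr.norm)
    if method != "log1p_cp10k":
        raise ValueError(f"unknown normalization {method!r}")
    _require_counts(expr, "normalize_expression")
    totals = expr.values.to_numpy().sum(axis=0)
    if (totals == 0).any():
        bad = expr.cell_ids[totals == 0].tolist()[:5]
        raise ValueError(f"all-zero cells cannot be normalized: {bad}")
    scaled = np.log1p(expr.values.to_numpy() / totals * 1e4)
    values = pd.DataFrame(scaled, index=expr.gene_ids, columns=expr.cell_ids)
    return ExpressionMatrix(values, expr.obs.copy(), "log1p_cp10k")


# ---------------------------------------------------------------------------
# GMT / homology / tabular helpers
# ---------------------------------------------------------------------------

def read_gmt(path) -> SignatureSet:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets, desc = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name, description, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            sets[name] = genes
            desc[name] = description
    return SignatureSet(sets, desc)


def write_gmt(sig: SignatureSet, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sig.sets.items():
            desc = sig.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_homology(path, source_species: str = "", target_species: str = "") -> HomologyMap:
    df = pd.read_csv(path, sep="\t")
    return HomologyMap(df, source_species, target_species)


def write_homology(hmap: HomologyMap, path) -> None:
    hmap.records.to_csv(path, sep="\t", index=False)


def read_pseudotime(path) -> PseudotimeAssignment:
    df = pd.read_csv(path, sep="\t", index_col=0)
    marker = df.attrs.get("orientation_marker_used", "")
    return PseudotimeAssignment(df.iloc[:, 0].astype(float), marker)


def write_pseudotime(pt: PseudotimeAssignment, path) -> None:
    pt.pseudotime.rename("pseudotime").to_csv(path, sep="\t")


def read_binned(path) -> BinnedTrajectory:
    """Read a binned-trajectory TSV written by :func:`write_binned`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.loc["__bin_counts__"].to_numpy(dtype=int)
    values = df.drop(index="__bin_counts__")
    return BinnedTrajectory(values, counts)


def write_binned(binned: BinnedTrajectory, path) -> None:
    df = binned.values.copy()
    df.loc["__bin_counts__"] = binned.bin_counts
    df.to_csv(path, sep="\t")
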