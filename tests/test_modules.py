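import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import neutraj as nj
from neutraj.io import BinnedTrajectory
from neutraj.modules import DTWConfig, _ward_linkage, dtw_pairwise
from conftest import brute_force_dtw

RAW = DTWConfig(zscore=False)


def make_binned(values: np.ndarray, genes=None) -> BinnedTrajectory:
    n_bins = values.shape[1]
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=genes, columns=range(n_bins))
    return BinnedTrajectory(df, np.full(n_bins, 10))


class TestDTW:
    def test_identical_profiles_zero(self):
        x = np.array([0.3, 1.2, 0.7, 2.0])
        assert nj.dtw_distance(x, x, RAW) == 0.0

    def test_worked_example_matches_enumeration(self):
        a, b = (0, 1, 2), (0, 2, 2)
        assert nj.dtw_distance(a, b, RAW) == pytest.approx(brute_force_dtw(a, b))

    def test_shift_absorbed_below_euclidean(self):
        x = np.exp(-0.5 * ((np.arange(50) - 20) / 4.0) ** 2)
        y = np.roll(x, 1)
        assert nj.dtw_distance(x, y, RAW) < np.abs(x - y).sum()

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=4),
           st.lists(st.integers(0, 2), min_size=1, max_size=4))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_oracle_and_symmetric(self, a, b):
        d = nj.dtw_distance(a, b, RAW)
        assert d == pytest.approx(brute_force_dtw(a, b))
        assert d == pytest.approx(nj.dtw_distance(b, a, RAW))
        assert d >= 0

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            nj.dtw_distance([0.0, np.nan], [0.0, 1.0], RAW)

    def test_pairwise_matches_single(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 12))
        D = dtw_pairwise(X, RAW)
        assert D[1, 3] == pytest.approx(nj.dtw_distance(X[1], X[3], RAW))
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


class TestKGS:
    def planted_blobs(self, seed, k=3, per=20, sep=10.0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(loc=i * sep, scale=1.0, size=(per, 2))
                         for i in range(k)])
        return squareform(pdist(pts))

    def test_recovers_planted_k(self):
        hits = 0
        for seed in range(10):
            dmat = self.planted_blobs(seed)
            Z = _ward_linkage(dmat)
            hits += nj.kgs_select(Z, dmat, k_max=10).chosen_k == 3
        assert hits >= 9

    def test_identical_points_tie_break_to_two(self):
        dmat = np.zeros((8, 8))
        Z = _ward_linkage(dmat)
        curve = nj.kgs_select(Z, dmat, k_max=5)
        assert curve.chosen_k == 2

    def test_k_max_two_single_entry(self):
        dmat = self.planted_blobs(0)
        Z = _ward_linkage(dmat)
        curve = nj.kgs_select(Z, dmat, k_max=2)
        assert len(curve.ks) == 1 and curve.ks[0] == 2

    def test_k_max_exceeds_items(self):
        dmat = self.planted_blobs(0, per=2)
        Z = _ward_linkage(dmat)
        with pytest.raises(ValueError):
            nj.kgs_select(Z, dmat, k_max=100)


class TestPartitionGenes:
    def test_recovers_planted_modules(self, pipeline):
        truth, binned, assoc = pipeline["truth"], pipeline["binned"], pipeline["assoc"]
        sel = assoc.selected_genes
        part = nj.partition_genes(binned, sel)
        common = [g for g in sel if truth.gene_modules.get(g, "none") != "none"]
        ari = adjusted_rand_score(truth.gene_modules[common], part.labels[common])
        assert part.k == 3 and ari >= 0.9

    def test_duplicate_gene_same_module(self, pipeline):
        binned = pipeline["binned"]
        sel = pipeline["assoc"].selected_genes[:30]
        vals = binned.values.loc[sel].copy()
        vals.loc["dup_of_first"] = vals.iloc[0]
        b2 = make_binned(vals.to_numpy(), list(vals.index))
        part = nj.partition_genes(b2, list(vals.index), k=3)
        assert part.labels["dup_of_first"] == part.labels[sel[0]]

    def test_labels_invariant_to_gene_order(self, pipeline):
        binned = pipeline["binned"]
        sel = pipeline["assoc"].selected_genes
        a = nj.partition_genes(binned, sel, k=3).labels
        b = nj.partition_genes(binned, sel[::-1], k=3).labels
        assert (a.sort_index() == b.sort_index()).all()

    def test_too_few_genes(self, pipeline):
        with pytest.raises(ValueError):
            nj.partition_genes(pipeline["binned"], pipeline["assoc"].selected_genes[:2])


class TestPartitionPhases:
    def test_recovers_planted_phases(self, pipeline):
        truth, binned = pipeline["truth"], pipeline["binned"]
        ph = nj.partition_phases(binned, pipeline["assoc"].selected_genes)
        acc = (ph.bin_labels.to_numpy() == truth.bin_phases.to_numpy()).mean()
        assert ph.g == 4 and acc >= 0.9
        assert ph.contiguity >= 0.9

    def test_reversed_pseudotime_reverses_labels(self, pipeline):
        binned = pipeline["binned"]
        sel = pipeline["assoc"].selected_genes
        fwd = nj.partition_phases(binned, sel, g=4)
        rev_vals = binned.values.iloc[:, ::-1]
        rev_vals.columns = range(rev_vals.shape[1])
        rev_binned = BinnedTrajectory(rev_vals, binned.bin_counts[::-1])
        rev = nj.partition_phases(rev_binned, sel, g=4)
        n = len(fwd.bin_labels)
        flipped = fwd.bin_labels.iloc[::-1].to_numpy()
        mapping = {"P1": "P4", "P2": "P3", "P3": "P2", "P4": "P1"}
        assert (rev.bin_labels.to_numpy() == np.array([mapping[x] for x in flipped])).all()

    def test_low_quality_flag_propagated(self, pipeline):
        binned = pipeline["binned"]
        counts = binned.bin_counts.copy()
        counts[5] = 2
        counts[0] += binned.bin_counts[5] - 2
        b2 = BinnedTrajectory(binned.values.copy(), counts)
        ph = nj.partition_phases(b2, pipeline["assoc"].selected_genes, g=4)
        assert ph.low_quality_flag[5]
        assert ph.bin_labels.loc[5] in {"P1", "P2", "P3", "P4"}

    def test_cells_inherit_bin_phase(self, pipeline):
        ph = nj.partition_phases(pipeline["binned"], pipeline["assoc"].selected_genes, g=4)
        cells = ph.assign_cells(pipeline["pt"])
        pt = pipeline["pt"].pseudotime
        first_bin_cells = pt.index[pt < 0.01]
        assert (cells.loc[first_bin_cells] == ph.bin_labels.loc[0]).all()


class TestSummarizeModules:
    def test_matches_group_by_oracle(self, pipeline):
        binned = pipeline["binned"]
        sel = pipeline["assoc"].selected_genes
        part = nj.partition_genes(binned, sel, k=3)
        ph = nj.partition_phases(binned, sel, g=4)
        table = nj.summarize_modules(binned, part, ph)
        # oracle: direct nested loops over z-scored values
        X = binned.values.loc[part.labels.index].to_numpy()
        Xz = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        for mod in table.index:
            for phase in table.columns:
                gmask = (part.labels == mod).to_numpy()
                bmask = (ph.bin_labels == phase).to_numpy()
                assert table.loc[mod, phase] == pytest.approx(Xz[np.ix_(gmask, bmask)].mean())

    def test_single_gene_module_row(self, pipeline):
        binned = pipeline["binned"]
        genes = pipeline["assoc"].selected_genes[:12]
        part = nj.partition_genes(binned, genes, k=3)
        ph = nj.partition_phases(binned, genes, g=4)
        table = nj.summarize_modules(binned, part, ph)
        assert np.isfinite(table.to_numpy()).all()
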