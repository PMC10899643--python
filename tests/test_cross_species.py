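import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import neutraj as nj
from neutraj.cross_species import LagTable
from neutraj.io import ExpressionMatrix, HomologyMap
from conftest import brute_force_ccf


class TestAggregateStages:
    def test_one_cell_per_stage_identity(self):
        vals = pd.DataFrame(np.arange(6.0).reshape(2, 3), index=["g1", "g2"],
                            columns=["a", "b", "c"])
        labels = pd.Series(["s1", "s2", "s3"], index=vals.columns)
        out = nj.aggregate_stages(vals, labels)
        np.testing.assert_allclose(out.to_numpy(), vals.to_numpy())

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(5, 12)),
                            index=[f"g{i}" for i in range(5)],
                            columns=[f"c{i}" for i in range(12)])
        labels = pd.Series(rng.choice(["s1", "s2", "s3"], 12), index=vals.columns)
        out = nj.aggregate_stages(vals, labels)
        for stage in out.columns:
            np.testing.assert_allclose(
                out[stage].to_numpy(),
                vals.loc[:, (labels == stage).to_numpy()].mean(axis=1).to_numpy())

    def test_unlabeled_column_errors(self):
        vals = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            nj.aggregate_stages(vals, pd.Series({"a": "s1"}))


class TestQuantileNormalize:
    def test_worked_example(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [4.0, 5.0, 6.0]})
        out = nj.quantile_normalize(df)
        np.testing.assert_allclose(out["x"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["y"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"x": [3.0, 1.0, 2.0], "y": [3.0, 1.0, 2.0]})
        out = nj.quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    @given(arrays(np.float64, (7, 3), unique=True,
                  elements=st.floats(-50, 50, allow_nan=False)))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_columns_share_sorted_values(self, arr):
        # exact multiset equality holds for tie-free columns; with ties the
        # average-rank convention can map tied values off the common grid
        out = nj.quantile_normalize(pd.DataFrame(arr))
        cols = [np.sort(out[c].to_numpy()) for c in out.columns]
        for c in cols[1:]:
            np.testing.assert_allclose(c, cols[0], atol=1e-9)

    def test_single_column_identity(self):
        df = pd.DataFrame({"x": [2.0, 1.0]})
        pd.testing.assert_frame_equal(nj.quantile_normalize(df), df)


class TestClusterStages:
    def matched_datasets(self, seed, noise=0.05):
        _, truth = nj.simulate_trajectory_dataset(n_cells=400, n_genes=120, seed=seed)
        out = nj.simulate_stage_datasets(truth, noise_sd=noise, seed=seed)
        return pd.concat({d: df for d, df, _ in out}, axis=1)

    def test_matched_stages_group_together(self):
        hits = 0
        for seed in range(3):
            joined = self.matched_datasets(seed)
            spm = nj.cluster_stages(nj.quantile_normalize(joined))
            order = [stage for _, stage in spm.leaf_order]
            # matched stages must be adjacent: order is 4x early, 4x mid, 4x late
            blocks = [order[i:i + 4] for i in range(0, 12, 4)]
            hits += all(len(set(b)) == 1 for b in blocks)
        assert hits >= 2

    def test_scores_span_unit_interval(self):
        joined = self.matched_datasets(0)
        spm = nj.cluster_stages(nj.quantile_normalize(joined))
        for ds in {d for d, _ in spm.scores.index}:
            sub = spm.scores[ds]
            assert sub.min() == 0.0 and sub.max() == 1.0

    def test_single_stage_dataset_scores_zero(self):
        rng = np.random.default_rng(0)
        cols = pd.MultiIndex.from_tuples(
            [("d1", "a"), ("d1", "b"), ("d2", "only")])
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=cols)
        spm = nj.cluster_stages(df)
        assert spm.scores[("d2", "only")] == 0.0

    def test_two_leaf_reorder_ascending(self):
        rng = np.random.default_rng(1)
        cols = pd.MultiIndex.from_tuples([("d1", "late"), ("d2", "early")])
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=cols)
        spm = nj.cluster_stages(df)
        assert [spm.scores[c] for c in spm.leaf_order] == sorted(
            spm.scores[c] for c in spm.leaf_order)


class TestCollapseHomology:
    def expr_of(self, genes):
        rng = np.random.default_rng(0)
        return ExpressionMatrix(pd.DataFrame(
            rng.integers(0, 9, (len(genes), 4)).astype(float),
            index=genes, columns=list("abcd")))

    def test_pure_rename(self):
        expr = self.expr_of(["hsA", "hsB"])
        hmap = HomologyMap(pd.DataFrame({
            "source_gene": ["hsA", "hsB"], "target_gene": ["zfA", "zfB"],
            "detection_rate": [0.5, 0.6]}))
        out = nj.collapse_homology(expr, hmap)
        assert out.gene_ids.tolist() == ["zfA", "zfB"]
        np.testing.assert_allclose(out.values.to_numpy(), expr.values.to_numpy())

    def test_one_to_many_keeps_higher_rate(self):
        expr = self.expr_of(["hsA1", "hsA2"])
        hmap = HomologyMap(pd.DataFrame({
            "source_gene": ["hsA1", "hsA2"], "target_gene": ["zfA", "zfA"],
            "detection_rate": [0.9, 0.2]}))
        out = nj.collapse_homology(expr, hmap)
        assert out.gene_ids.tolist() == ["zfA"]
        np.testing.assert_allclose(out.values.loc["zfA"],
                                   expr.values.loc["hsA1"])

    def test_planted_counts(self):
        rng = np.random.default_rng(2)
        targets = [f"zf{i}" for i in range(100)]
        sources, rows = [], []
        for i, t in enumerate(targets):
            sources.append(f"hs{i}")
            rows.append({"source_gene": f"hs{i}", "target_gene": t,
                         "detection_rate": rng.uniform(0.5, 1.0)})
            if i < 10:  # plant ten 1-to-many cases
                sources.append(f"hs{i}_b")
                rows.append({"source_gene": f"hs{i}_b", "target_gene": t,
                             "detection_rate": rng.uniform(0.0, 0.4)})
        out = nj.collapse_homology(self.expr_of(sources), HomologyMap(pd.DataFrame(rows)))
        assert out.n_genes == 100
        assert sorted(out.gene_ids) == sorted(targets)

    def test_idempotent_and_never_grows(self):
        expr = self.expr_of(["hsA1", "hsA2", "hsB"])
        hmap = HomologyMap(pd.DataFrame({
            "source_gene": ["hsA1", "hsA2", "hsB"],
            "target_gene": ["zfA", "zfA", "zfB"],
            "detection_rate": [0.9, 0.2, 0.7]}))
        once = nj.collapse_homology(expr, hmap)
        twice = nj.collapse_homology(once, hmap)
        assert once.n_genes <= expr.n_genes
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestCrossCorrelate:
    def bump(self, center, n=100, width=5.0):
        x = np.arange(n, dtype=float)
        return np.exp(-0.5 * ((x - center) / width) ** 2)

    def test_identity(self):
        x = self.bump(40)
        lag, r = nj.cross_correlate(x, x, 99)
        assert lag == 0 and r == pytest.approx(1.0, abs=1e-9)

    def test_shifted_bump_matches_oracle(self):
        ref, query = self.bump(40), self.bump(50)
        lag, r = nj.cross_correlate(ref, query, 30)
        oracle = brute_force_ccf(ref, query, 30)
        assert lag == max(oracle, key=lambda k: (oracle[k], -abs(k)))
        assert lag == 10
        assert r == pytest.approx(oracle[10])

    def test_anticorrelated_reports_negative_peak(self):
        x = np.sin(np.linspace(0, 4 * np.pi, 60))
        lag, r = nj.cross_correlate(x, -x, 0)
        assert r < 0

    def test_lag_antisymmetry(self):
        a, b = self.bump(40), self.bump(47)
        assert nj.cross_correlate(a, b, 30)[0] == -nj.cross_correlate(b, a, 30)[0]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            nj.cross_correlate(np.ones(10), np.arange(10.0), 5)


class TestLagTableAndPanSignature:
    def profiles(self, n_genes=30, n_bins=100, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(25, 75, n_genes)
        x = np.arange(n_bins, dtype=float)
        vals = np.exp(-0.5 * ((x[None, :] - centers[:, None]) / 5.0) ** 2)
        return pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)])

    def test_identical_datasets_all_zero(self):
        ref = self.profiles()
        modules = pd.Series("M1", index=ref.index)
        table = nj.build_lag_table(ref, {"ds1": ref.copy(), "ds2": ref.copy()}, modules)
        assert (table.per_gene_dataset["lag"] == 0).all()
        assert np.allclose(table.module_coefficient.to_numpy(), 1.0)

    def test_planted_lags_average(self):
        ref = self.profiles()
        shifted = {
            "ds1": pd.DataFrame(np.array([np.roll(r, 10) for r in ref.to_numpy()]),
                                index=ref.index),
            "ds2": pd.DataFrame(np.array([np.roll(r, 20) for r in ref.to_numpy()]),
                                index=ref.index),
        }
        modules = pd.Series("M1", index=ref.index)
        table = nj.build_lag_table(ref, shifted, modules, max_lag=40)
        ok = (table.mean_lag - 15).abs() <= 2
        assert ok.mean() > 0.9

    def test_single_gene_module_mean(self):
        ref = self.profiles(n_genes=4)
        modules = pd.Series(["M1", "M1", "M1", "M2"], index=ref.index)
        table = nj.build_lag_table(ref, {"ds": ref.copy()}, modules)
        g = ref.index[3]
        coef = table.per_gene_dataset.query("gene == @g")["coefficient"].iloc[0]
        assert table.module_coefficient.loc["ds", "M2"] == pytest.approx(coef)

    def test_pan_signature_boundary_and_blacklist(self):
        genes = ["keep0", "keep50", "drop51", "blacklisted"]
        per = pd.DataFrame({"gene": genes, "dataset": "ds",
                            "lag": [0, 50, 51, 0],
                            "coefficient": [0.9] * 4})
        table = LagTable(per, per.set_index("gene")["lag"].astype(float),
                         pd.DataFrame(), max_lag=99)
        modules = pd.Series("M1", index=genes)
        sig = nj.derive_pan_signature(table, modules, blacklist=["blacklisted"])
        assert set(sig["M1pan"]) == {"keep0", "keep50"}

    def test_planted_conserved_counts(self):
        rng = np.random.default_rng(5)
        rows, modules = [], {}
        for m in ("M1", "M2", "M3"):
            for i in range(30):   # conserved
                g = f"{m}_cons{i}"
                rows.append((g, rng.integers(-50, 51)))
                modules[g] = m
            for i in range(10):   # shifted beyond threshold
                g = f"{m}_shift{i}"
                rows.append((g, int(rng.choice([-1, 1])) * int(rng.integers(51, 90))))
                modules[g] = m
            for i in range(5):    # conserved but blacklisted
                g = f"{m}_black{i}"
                rows.append((g, 0))
                modules[g] = m
        per = pd.DataFrame({"gene": [g for g, _ in rows], "dataset": "ds",
                            "lag": [l for _, l in rows], "coefficient": 0.8})
        table = LagTable(per, per.set_index("gene")["lag"].astype(float),
                         pd.DataFrame(), max_lag=99)
        blacklist = [g for g in modules if "_black" in g]
        sig = nj.derive_pan_signature(table, pd.Series(modules), blacklist)
        for m in ("M1", "M2", "M3"):
            assert len(sig[f"{m}pan"]) == 30
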