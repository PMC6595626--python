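import numpy as np
import pandas as pd
import pytest

import seedomics as s
from seedomics import coexpression as cx
from tests.conftest import exact_correlation_data, two_block_correlation


class TestAdjacency:
    def test_closed_forms(self):
        corr = np.array([[1.0, 1.0, -0.5], [1.0, 1.0, -0.5], [-0.5, -0.5, 1.0]])
        data = exact_correlation_data(corr, 12, seed=0)
        adj = cx.adjacency(data, 2)
        assert adj.iloc[0, 1] == pytest.approx(1.0, abs=1e-8)
        assert adj.iloc[0, 2] == pytest.approx(0.25, abs=1e-8)

    def test_orthogonal_profiles_zero(self):
        corr = np.eye(2)
        data = exact_correlation_data(corr, 10, seed=1)
        adj = cx.adjacency(data, 6)
        assert adj.iloc[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_zero_variance_dropped(self):
        data = pd.DataFrame(
            {"a": np.arange(8.0), "b": np.ones(8), "c": np.arange(8.0)[::-1]}
        ).T
        adj = cx.adjacency(data, 6)
        assert list(adj.index) == ["a", "c"]


class TestTom:
    def test_hand_three_gene(self):
        a = np.array([[1.0, 0.8, 0.4], [0.8, 1.0, 0.2], [0.4, 0.2, 1.0]])
        adj = pd.DataFrame(a, index=list("xyz"), columns=list("xyz"))
        tom = cx.tom_similarity(adj)
        # L_12 = 0.4*0.2, k = (1.2, 1.0, 0.6)
        expected = (0.4 * 0.2 + 0.8) / (min(1.2, 1.0) + 1 - 0.8)
        assert tom.loc["x", "y"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.88 / 1.2)

    def test_identity_adjacency(self):
        adj = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        tom = cx.tom_similarity(adj)
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        n = 10
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.tom_similarity(pd.DataFrame(a)).to_numpy()
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                expected = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.normal(size=(15, 18)))
        adj = cx.adjacency(data, 6)
        tom = cx.tom_similarity(adj).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestSoftThreshold:
    def _scale_free_data(self, seed=1, p=200, plant_beta=6):
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.05, 1, p)
        c = (u**2) ** (1 / plant_beta)
        corr = np.outer(c, c)
        np.fill_diagonal(corr, 1.0)
        return exact_correlation_data(corr, p + 20, seed=seed + 10)

    def test_planted_scale_free_selects_low_beta(self):
        data = self._scale_free_data()
        beta, table = cx.pick_soft_threshold(data)
        assert beta <= 8
        row = table[table.beta == beta].iloc[0]
        assert row.r2 >= 0.8 and row.slope < 0

    def test_degenerate_two_genes_falls_back(self):
        data = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)))
        with pytest.warns(UserWarning):
            beta, _ = cx.pick_soft_threshold(data)
        assert beta >= 1

    def test_determinism(self):
        data = self._scale_free_data(seed=2, p=60)
        b1, _ = cx.pick_soft_threshold(data)
        b2, _ = cx.pick_soft_threshold(data)
        assert b1 == b2


class TestModules:
    def test_two_planted_blocks_recovered_exactly(self):
        corr = two_block_correlation(block=8, within=0.9)
        data = exact_correlation_data(corr, 24, seed=4)
        tom = cx.tom_similarity(cx.adjacency(data, 2))
        modules = cx.detect_modules(tom, min_size=8)
        labels = modules.module_of_gene
        first, second = labels.iloc[:8], labels.iloc[8:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]
        assert cx.UNASSIGNED not in set(labels)
        # larger-first color ordering
        assert set(labels) == {"turquoise", "blue"}

    def test_orthogonal_genes_all_grey(self):
        data = exact_correlation_data(np.eye(10), 16, seed=5)
        tom = cx.tom_similarity(cx.adjacency(data, 6))
        modules = cx.detect_modules(tom, min_size=3)
        assert set(modules.module_of_gene) == {cx.UNASSIGNED}

    def test_min_size_larger_than_n_genes(self):
        data = exact_correlation_data(np.eye(5), 10, seed=6)
        tom = cx.tom_similarity(cx.adjacency(data, 6))
        modules = cx.detect_modules(tom, min_size=50)
        assert set(modules.module_of_gene) == {cx.UNASSIGNED}

    def test_permutation_invariance(self):
        corr = two_block_correlation(block=8, within=0.9)
        data = exact_correlation_data(corr, 24, seed=4)
        tom = cx.tom_similarity(cx.adjacency(data, 2))
        perm = np.random.default_rng(0).permutation(len(tom))
        tom_p = tom.iloc[perm, perm]
        a = cx.detect_modules(tom, min_size=8).module_of_gene
        b = cx.detect_modules(tom_p, min_size=8).module_of_gene
        assert (a.loc[b.index] == b).all()


class TestEigengene:
    def test_identical_genes(self, expr_design):
        profile = np.sin(np.arange(18.0))
        data = pd.DataFrame(
            [profile, profile, profile],
            index=list("abc"),
            columns=expr_design.samples,
        )
        me, ve = cx.module_eigengene(data, list("abc"))
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert abs(np.corrcoef(me, z)[0, 1]) == pytest.approx(1.0)
        assert ve == pytest.approx(1.0)
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_orientation_rule(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.normal(size=(10, 18)))
        me, _ = cx.module_eigengene(data, list(range(10)))
        cors = [np.corrcoef(data.loc[g], me)[0, 1] for g in data.index]
        assert np.mean(cors) > 0
        # flipping every profile keeps the eigengene subspace and the rule
        me_f, _ = cx.module_eigengene(-data, list(range(10)))
        assert abs(np.corrcoef(me, me_f)[0, 1]) == pytest.approx(1.0)
        cors_f = [np.corrcoef(-data.loc[g], me_f)[0, 1] for g in data.index]
        assert np.mean(cors_f) > 0

    def test_power_iteration_oracle(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.normal(size=(20, 18)))
        me, ve = cx.module_eigengene(data, list(range(20)))
        z = data.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        cov = z.T @ z
        v = np.ones(18) / np.sqrt(18)
        for _ in range(500):
            v = cov @ v
            v /= np.linalg.norm(v)
        assert abs(np.corrcoef(me, v)[0, 1]) > 0.999

    def test_no_random_direction_beats_eigengene(self):
        rng = np.random.default_rng(10)
        data = pd.DataFrame(rng.normal(size=(12, 18)))
        me, _ = cx.module_eigengene(data, list(range(12)))
        z = data.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        explained_me = np.sum((z @ me) ** 2)
        for _ in range(100):
            v = rng.normal(size=18)
            v /= np.linalg.norm(v)
            assert np.sum((z @ v) ** 2) <= explained_me + 1e-9

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            cx.module_eigengene(pd.DataFrame(np.eye(3)), [])


class TestModuleStageStats:
    def test_printed_value_arithmetic(self):
        # r = 0.75 over 18 samples -> p = 3e-4 at one significant figure
        p = cx.correlation_pvalue(0.75, 18)
        assert p == pytest.approx(3e-4, rel=0.2)

    def test_zero_correlation_p_one(self):
        assert cx.correlation_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_t_cdf_oracle(self):
        from scipy.special import betainc

        r, n = 0.5, 18
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        df = n - 2
        # incomplete-beta form of the two-sided t p-value
        expected = betainc(df / 2, 0.5, df / (df + t * t))
        assert cx.correlation_pvalue(r, n) == pytest.approx(expected, rel=1e-12)

    def test_full_table(self, expr_design):
        rng = np.random.default_rng(11)
        me = pd.DataFrame(
            {"blue": rng.normal(size=18)}, index=expr_design.samples
        )
        stats_table = cx.module_stage_correlation(me, expr_design)
        assert len(stats_table) == 6
        assert stats_table["r"].between(-1, 1).all()
        assert stats_table["p"].between(0, 1).all()


class TestConnectivityAndHubs:
    def test_hand_sum(self):
        a = np.array([[1.0, 0.8, 0.4], [0.8, 1.0, 0.2], [0.4, 0.2, 1.0]])
        adj = pd.DataFrame(a, index=list("xyz"), columns=list("xyz"))
        kw = cx.intramodular_connectivity(adj, list("xyz"))
        assert np.allclose(kw.to_numpy(), [1.2, 1.0, 0.6])
        assert cx.top_hubs(kw, 1) == ["x"]

    def test_singleton_module(self):
        adj = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        kw = cx.intramodular_connectivity(adj, ["a"])
        assert kw["a"] == 0.0

    def test_tie_breaks_by_gene_id(self):
        adj = pd.DataFrame(
            np.full((4, 4), 0.5) + 0.5 * np.eye(4),
            index=["d", "b", "a", "c"],
            columns=["d", "b", "a", "c"],
        )
        kw = cx.intramodular_connectivity(adj, ["d", "b", "a", "c"])
        assert cx.top_hubs(kw, 2) == ["a", "b"]


class TestExport:
    def test_roundtrip_and_counts(self, tmp_path):
        import networkx as nx

        rng = np.random.default_rng(12)
        n = 6
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        weights = pd.DataFrame(w, index=[f"g{i}" for i in range(n)],
                               columns=[f"g{i}" for i in range(n)])
        paths = cx.export_network(weights, tmp_path, weight_threshold=0.0)
        g = nx.read_graphml(paths["graphml"])
        assert g.number_of_edges() == n * (n - 1) // 2
        for a, b, d in g.edges(data=True):
            assert d["weight"] == pytest.approx(weights.loc[a, b])
        sif_lines = paths["sif"].read_text().strip().splitlines()
        assert len(sif_lines) == g.number_of_edges()

    def test_threshold_one_keeps_only_unit_edges(self, tmp_path):
        w = pd.DataFrame(
            [[1.0, 1.0, 0.2], [1.0, 1.0, 0.3], [0.2, 0.3, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        paths = cx.export_network(w, tmp_path, weight_threshold=1.0)
        edges = pd.read_csv(paths["tsv"], sep="\t")
        assert len(edges) == 1
        assert {edges.source[0], edges.target[0]} == {"a", "b"}
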