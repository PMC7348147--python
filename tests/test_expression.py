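import networkx as nx
import numpy as np
import pandas as pd
import pytest

from proxisig.errors import ConfigurationError, DegenerateDataError
from proxisig.expression import (
    CountMatrix,
    DEGTable,
    FPKMMatrix,
    cluster_profiles,
    compare_centrality,
    detect_degs,
    fpkm_normalize,
    summarize_degs,
)
from tests.conftest import make_count_matrix


class TestFPKM:
    def test_closed_form(self):
        # counts=10, length=1000 bp, total=1e6 -> FPKM = 10
        counts = np.zeros((2, 2), dtype=int)
        counts[0] = [10, 10]
        counts[1] = [999_990, 999_990]
        cm = make_count_matrix(counts, lengths=[1000, 500])
        fm = fpkm_normalize(cm)
        assert fm.values.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        counts = np.array([[0, 5], [10, 10]])
        cm = make_count_matrix(counts, lengths=[100, 100])
        fm = fpkm_normalize(cm)
        assert fm.values.iloc[0, 0] == 0.0
        assert (fm.values.values == 0) == pytest.approx(counts == 0)

    def test_matches_reference_computation(self):
        # independent two-line recomputation of the same formula
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 1000, size=(50, 6))
        lengths = rng.integers(200, 5000, size=50)
        cm = make_count_matrix(counts, lengths=lengths)
        fm = fpkm_normalize(cm)
        expected = counts * 1e9 / (counts.sum(axis=0)[None, :] * lengths[:, None])
        np.testing.assert_allclose(fm.values.values, expected, rtol=1e-12)

    def test_gene_doubling_linearity(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 100, size=(5, 4))
        counts[4] += 200  # headroom for compensation below
        lengths = [500] * 5
        cm = make_count_matrix(counts, lengths=lengths)
        doubled = counts.copy()
        doubled[2] *= 2
        # keep per-sample totals fixed by compensating another gene
        doubled[4] -= counts[2]
        assert (doubled[4] >= 0).all()
        cm2 = make_count_matrix(doubled, lengths=lengths)
        f1 = fpkm_normalize(cm).values.values
        f2 = fpkm_normalize(cm2).values.values
        np.testing.assert_allclose(f2[2], 2 * f1[2], rtol=1e-12)

    def test_missing_length_error(self):
        counts = np.ones((2, 2), dtype=int)
        cm = make_count_matrix(counts, lengths=[100, 100])
        cm.gene_lengths = cm.gene_lengths.drop("g1")
        with pytest.raises(ConfigurationError, match="g1"):
            fpkm_normalize(cm)

    def test_zero_depth_sample_error(self):
        counts = np.array([[0, 5], [0, 5]])
        cm = make_count_matrix(counts, lengths=[100, 100])
        with pytest.raises(ConfigurationError, match="zero-depth"):
            fpkm_normalize(cm)

    def test_no_lengths_error(self):
        cm = make_count_matrix(np.ones((2, 2), dtype=int))
        with pytest.raises(ConfigurationError, match="gene_lengths"):
            fpkm_normalize(cm)


class TestDetectDegs:
    def test_identical_groups_no_degs(self):
        rng = np.random.default_rng(2)
        block = rng.integers(0, 500, size=(100, 3))
        counts = np.hstack([block, block])  # treated == control
        cm = make_count_matrix(counts)
        table = detect_degs(cm, "liverish", alpha=0.99)
        assert (table.rows["direction"] == "ns").all()
        assert (table.rows["p_value"] > 0.95).all()

    def test_all_zero_gene(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        cm = make_count_matrix(counts)
        table = detect_degs(cm, "liverish")
        assert table.rows.iloc[0]["p_value"] == 1.0
        assert table.rows.iloc[0]["log2fc"] == 0.0

    def test_too_few_replicates(self):
        counts = np.ones((5, 3), dtype=int)
        cm = make_count_matrix(counts)  # 1 treated, 2 control
        with pytest.raises(ConfigurationError, match="replicates"):
            detect_degs(cm, "liverish")

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(10, 0.1, size=(60, 6))
        cm = make_count_matrix(counts)
        swapped = make_count_matrix(counts)
        swapped.annotations["group"] = (
            swapped.annotations["group"]
            .map({"treated": "control", "control": "treated"})
        )
        t1 = detect_degs(cm, "liverish")
        t2 = detect_degs(swapped, "liverish")
        np.testing.assert_allclose(
            t1.rows["log2fc"].values, -t2.rows["log2fc"].values, atol=1e-9
        )
        np.testing.assert_allclose(
            t1.rows["p_value"].values, t2.rows["p_value"].values, atol=1e-9
        )

    def test_direction_consistent_with_threshold(self):
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(5, 0.05, size=(80, 6))
        counts[:10, :3] *= 8  # strong planted ups
        cm = make_count_matrix(counts)
        t = detect_degs(cm, "liverish", alpha=0.05)
        sig = t.rows["p_value"] < 0.05
        up = t.rows["direction"] == "up"
        down = t.rows["direction"] == "down"
        assert (up == (sig & (t.rows["log2fc"] > 0))).all()
        assert (down == (sig & (t.rows["log2fc"] < 0))).all()

    def test_planted_direction_recovered(self, small_simulation):
        cfg, cm, truth, _, _ = small_simulation
        tissue = cfg.tissue_names()[0]
        table = detect_degs(cm, tissue)
        up, down = truth.planted_deg_sets[tissue]
        sets = table.gene_sets()
        recovered_up = up & (sets["up"] | sets["down"])
        # every recovered planted gene carries the planted direction
        assert up & sets["down"] == set()
        assert down & sets["up"] == set()
        assert len(recovered_up) > 0


def table_from_sets(tissue, up, down, universe):
    rows = pd.DataFrame(
        {
            "log2fc": [1.0 if g in up else -1.0 if g in down else 0.0
                       for g in universe],
            "p_value": [0.01 if g in up | down else 0.9 for g in universe],
            "direction": ["up" if g in up else "down" if g in down else "ns"
                          for g in universe],
        },
        index=pd.Index(universe),
    )
    return DEGTable(tissue=tissue, rows=rows, alpha=0.05)


class TestSummarize:
    universe = [f"g{i}" for i in range(12)]

    def test_identical_vectors_cosine_one(self):
        up, down = {"g0", "g1"}, {"g2"}
        t1 = table_from_sets("a", up, down, self.universe)
        t2 = table_from_sets("b", up, down, self.universe)
        s = summarize_degs([t1, t2])
        assert s.cosine.loc["a", "b"] == pytest.approx(1.0)

    def test_sign_flip_cosine_minus_one(self):
        genes = {"g0", "g1", "g2"}
        t1 = table_from_sets("a", genes, set(), self.universe)
        t2 = table_from_sets("b", set(), genes, self.universe)
        s = summarize_degs([t1, t2])
        assert s.cosine.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_built_three_tissues_vs_bruteforce(self):
        # exhaustive hand computation over <=20 genes
        t1 = table_from_sets("a", {"g0", "g1"}, {"g2"}, self.universe)
        t2 = table_from_sets("b", {"g0"}, {"g3"}, self.universe)
        t3 = table_from_sets("c", {"g4"}, {"g0", "g2"}, self.universe)
        s = summarize_degs([t1, t2, t3])
        union = {"g0", "g1", "g2", "g3", "g4"}
        assert s.union_size == len(union)
        # multiplicities: g0 in 3, g2 in 2, g1/g3/g4 in 1
        assert s.sharing_histogram == {1: 3, 2: 1, 3: 1}
        vec = {}
        for name, t in (("a", t1), ("b", t2), ("c", t3)):
            gs = t.gene_sets()
            vec[name] = np.array(
                [1 if g in gs["up"] else -1 if g in gs["down"] else 0
                 for g in sorted(union)]
            )
        for x in "abc":
            for y in "abc":
                expected = vec[x] @ vec[y] / (
                    np.linalg.norm(vec[x]) * np.linalg.norm(vec[y])
                )
                assert s.cosine.loc[x, y] == pytest.approx(expected)

    def test_conservation_invariants(self):
        t1 = table_from_sets("a", {"g0", "g1"}, {"g2"}, self.universe)
        t2 = table_from_sets("b", {"g5"}, set(), self.universe)
        s = summarize_degs([t1, t2])
        assert sum(s.sharing_histogram.values()) == s.union_size
        for t in (t1, t2):
            row = s.per_tissue.loc[t.tissue]
            assert row["up"] + row["down"] == row["total"]
        assert np.allclose(s.cosine.values, s.cosine.values.T)
        assert np.allclose(np.diag(s.cosine.values), 1.0)

    def test_duplicate_tissue_error(self):
        t1 = table_from_sets("a", {"g0"}, set(), self.universe)
        with pytest.raises(ConfigurationError, match="duplicate"):
            summarize_degs([t1, t1])

    def test_module_labels(self):
        up_t = table_from_sets("upt", {"g0", "g1", "g2"}, set(), self.universe)
        up_t2 = table_from_sets("upt2", {"g0", "g1", "g3"}, set(), self.universe)
        down_t = table_from_sets("dnt", set(), {"g5", "g6", "g7"}, self.universe)
        mid = table_from_sets("mid", {"g8"}, {"g9"}, self.universe)
        s = summarize_degs([up_t, up_t2, down_t, mid])
        assert s.modules["upt"] == "Mod_up"
        assert s.modules["upt2"] == "Mod_up"
        assert s.modules["dnt"] in ("Mod_down", "Mod_inbetween")
        assert set(s.modules.values()) == {"Mod_up", "Mod_down", "Mod_inbetween"}


class TestClusterProfiles:
    def make_fpkm(self, values, samples=None):
        samples = samples or [f"s{i}" for i in range(values.shape[1])]
        return FPKMMatrix(
            values=pd.DataFrame(
                values, index=[f"g{i}" for i in range(values.shape[0])],
                columns=samples,
            )
        )

    def test_duplicate_samples_join_first(self):
        rng = np.random.default_rng(5)
        base = rng.random((30, 3)) * 100
        dup = np.hstack([base, base[:, [0]]])  # s3 duplicates s0
        fm = self.make_fpkm(dup)
        res = cluster_profiles(fm, fm.genes)
        first_merge = res.linkage[0]
        assert set(first_merge[:2]) == {0.0, 3.0}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_pca_matches_eigendecomposition(self):
        rng = np.random.default_rng(6)
        vals = rng.random((4, 3)) * 50
        fm = self.make_fpkm(vals)
        res = cluster_profiles(fm, fm.genes)
        x = np.log2(vals + 1)
        xc = (x - x.mean(axis=1, keepdims=True)).T  # samples x genes
        cov = xc @ xc.T
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        # squared PC scores projected norms must match eigenvalues
        got = (res.pca_scores.values ** 2).sum(axis=0)
        np.testing.assert_allclose(got, evals[: got.shape[0]], atol=1e-8)

    def test_separated_tissues_on_pc1(self, small_simulation):
        cfg, cm, truth, _, _ = small_simulation
        from proxisig.expression import fpkm_normalize

        fm = fpkm_normalize(cm)
        res = cluster_profiles(fm, fm.genes)
        tissues = cm.annotations.loc[res.sample_ids, "tissue"].values
        pc1 = res.pca_scores["PC1"].values
        a = pc1[tissues == tissues[0]]
        b = pc1[tissues != tissues[0]]
        # tissue means separated beyond within-tissue spread
        gap = abs(a.mean() - b.mean())
        assert gap > 2 * max(a.std(), b.std())

    def test_constant_matrix_degenerate(self):
        fm = self.make_fpkm(np.full((5, 4), 7.0))
        with pytest.raises(DegenerateDataError):
            cluster_profiles(fm, fm.genes)

    def test_newick_written(self):
        rng = np.random.default_rng(7)
        fm = self.make_fpkm(rng.random((10, 4)))
        res = cluster_profiles(fm, fm.genes)
        assert res.newick.endswith(";")
        for s in fm.samples:
            assert s in res.newick


class TestCentrality:
    def test_ring_symmetry(self):
        g = nx.cycle_graph(8)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(8)})
        rep = compare_centrality(g, ["N0", "N3"])
        pr = rep.node_values["pagerank"]
        np.testing.assert_allclose(pr.values, 1 / 8, atol=1e-6)
        bw = rep.node_values["betweenness"]
        assert bw.nunique() == 1

    def test_path_graph_middle_max(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {0: "A", 1: "B", 2: "C"})
        rep = compare_centrality(g, ["A"])
        bw = rep.node_values["betweenness"]
        assert bw.idxmax() == "B"
        assert (bw.drop("B") < bw["B"]).all()

    def test_betweenness_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        g = nx.gnp_random_graph(30, 0.15, seed=11)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes()})
        rep = compare_centrality(g, [f"N{i}" for i in range(5)])
        # brute force: enumerate all shortest paths for every pair
        nodes = sorted(g.nodes())
        counts = {v: 0.0 for v in nodes}
        for i, s in enumerate(nodes):
            for t in nodes[i + 1:]:
                if not nx.has_path(g, s, t):
                    continue
                paths = list(nx.all_shortest_paths(g, s, t))
                for v in nodes:
                    if v in (s, t):
                        continue
                    hits = sum(1 for p in paths if v in p)
                    counts[v] += hits / len(paths)
        norm = 2 / ((len(nodes) - 1) * (len(nodes) - 2))
        for v in nodes:
            assert rep.node_values.loc[v, "betweenness"] == pytest.approx(
                counts[v] * norm, abs=1e-9
            )

    def test_no_deg_in_network_error(self):
        g = nx.path_graph(3)
        with pytest.raises(ConfigurationError):
            compare_centrality(g, ["ZZZ"])
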