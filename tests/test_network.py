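import networkx as nx
import numpy as np
import pandas as pd
import pytest

from proxisig.errors import ConfigurationError, ParseError
from proxisig.network import (
    ConsensusCall,
    DrugTargetSet,
    ProximityResult,
    SignalingNetwork,
    consensus_calls,
    drug_deg_proximity,
    load_network,
    proximity_permutation_test,
    run_proximity_screen,
)


def net_from_edges(edges):
    return SignalingNetwork(edges)


def path_net(*names):
    return net_from_edges(
        [(names[i], names[i + 1], False) for i in range(len(names) - 1)]
    )


class TestLoad:
    def test_duplicate_edges_collapsed(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("source\ttarget\tdirected\nA\tB\ttrue\nA\tB\ttrue\n")
        net = load_network(p)
        assert net.n_edges == 1

    def test_self_loop_dropped(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("source\ttarget\tdirected\nA\tA\ttrue\nA\tB\ttrue\n")
        net = load_network(p)
        assert net.n_nodes == 2
        assert net.n_edges == 1

    def test_toy_counts(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text(
            "source\ttarget\tdirected\n"
            "A\tB\ttrue\nB\tC\ttrue\nC\tD\ttrue\nD\tE\ttrue\nE\tA\ttrue\n"
        )
        net = load_network(p)
        assert net.n_nodes == 5
        assert net.n_edges == 5
        assert net.summary()["largest_component"] == 5

    def test_symbols_uppercased(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("source\ttarget\nabc\tdef\n")
        net = load_network(p)
        assert set(net.nodes) == {"ABC", "DEF"}

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("")
        with pytest.raises(ParseError):
            load_network(p)

    def test_unknown_format_error(self, tmp_path):
        p = tmp_path / "net.bin"
        p.write_text("x")
        with pytest.raises(ParseError):
            load_network(p)

    def test_graphml_roundtrip(self, tmp_path):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        p = tmp_path / "net.graphml"
        nx.write_graphml(g, p)
        net = load_network(p)
        assert net.n_nodes == 3
        assert net.n_edges == 2

    def test_undirected_flag_reciprocates(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("source\ttarget\tdirected\nA\tB\tfalse\n")
        net = load_network(p)
        assert net.graph.has_edge("A", "B") and net.graph.has_edge("B", "A")


class TestProximity:
    def test_targets_superset_gives_zero(self):
        net = path_net("A", "B", "C", "D")
        assert drug_deg_proximity(net, {"A", "B"}, {"A", "B", "C"}) == 0.0

    def test_path_graph_distance(self):
        net = path_net("A", "B", "C", "D")
        assert drug_deg_proximity(net, {"A"}, {"D"}) == 3.0

    def test_directed_mode_respects_orientation(self):
        net = net_from_edges([("A", "B", True), ("B", "C", True)])
        assert drug_deg_proximity(net, {"A"}, {"C"}, mode="directed") == 2.0
        # C cannot reach A: penalty = SCC diameter + 1
        penalty = net.unreachable_penalty("directed")
        assert drug_deg_proximity(net, {"C"}, {"A"}, mode="directed") == penalty

    def test_random_graph_matches_bfs_oracle(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(25, 0.12, seed=5)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes()})
        net = net_from_edges([(u, v, False) for u, v in g.edges()])
        nodes = sorted(g.nodes())
        degs = [nodes[i] for i in rng.choice(len(nodes), 4, replace=False)]
        targets = [nodes[i] for i in rng.choice(len(nodes), 3, replace=False)]
        got = drug_deg_proximity(net, degs, targets)
        # exhaustive BFS oracle via networkx
        penalty = net.unreachable_penalty("undirected")
        und = net.graph.to_undirected()
        total = 0.0
        for d in degs:
            best = min(
                (nx.shortest_path_length(und, d, t)
                 for t in targets if nx.has_path(und, d, t)),
                default=penalty,
            )
            total += best
        assert got == pytest.approx(total / len(degs))

    def test_monotone_in_targets(self):
        g = nx.gnp_random_graph(20, 0.15, seed=6)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes()})
        net = net_from_edges([(u, v, False) for u, v in g.edges()])
        degs = ["N0", "N1", "N2"]
        targets = ["N10", "N11"]
        d1 = drug_deg_proximity(net, degs, targets)
        d2 = drug_deg_proximity(net, degs, targets + ["N15"])
        assert d2 <= d1

    def test_empty_side_errors(self):
        net = path_net("A", "B")
        with pytest.raises(ConfigurationError, match="degs"):
            drug_deg_proximity(net, {"ZZ"}, {"A"})
        with pytest.raises(ConfigurationError, match="targets"):
            drug_deg_proximity(net, {"A"}, {"ZZ"})


class TestPermutationTest:
    def make_big_net(self):
        g = nx.barabasi_albert_graph(300, 2, seed=3)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes()})
        return net_from_edges([(u, v, False) for u, v in g.edges()])

    def test_minimum_p_when_observed_beats_all(self):
        net = self.make_big_net()
        # targets == degs: observed 0; 5-node null draws essentially never cover
        degs = [f"N{i}" for i in range(5)]
        res = proximity_permutation_test(net, degs, degs, n_perm=1000, seed=1)
        assert res.observed_dist == 0.0
        assert res.empirical_p == pytest.approx(1 / 1001)

    def test_seed_determinism(self):
        net = self.make_big_net()
        degs = [f"N{i}" for i in range(6)]
        targets = [f"N{i}" for i in range(50, 56)]
        a = proximity_permutation_test(net, degs, targets, n_perm=200, seed=9)
        b = proximity_permutation_test(net, degs, targets, n_perm=200, seed=9)
        assert a.empirical_p == b.empirical_p
        np.testing.assert_array_equal(a.null_dists, b.null_dists)

    def test_addone_estimator_range(self):
        net = self.make_big_net()
        degs = [f"N{i}" for i in range(6)]
        targets = [f"N{i}" for i in range(100, 106)]
        res = proximity_permutation_test(net, degs, targets, n_perm=99, seed=2)
        assert 1 / 100 <= res.empirical_p <= 1.0
        assert len(res.null_dists) == 99

    def test_degree_matched_null_runs(self):
        net = self.make_big_net()
        res = proximity_permutation_test(
            net, ["N0", "N1"], ["N5", "N6"], n_perm=50, seed=3,
            degree_matched_null=True,
        )
        assert 0 < res.empirical_p <= 1.0

    def test_targets_as_large_as_network_error(self):
        net = path_net("A", "B", "C")
        with pytest.raises(ConfigurationError):
            proximity_permutation_test(net, ["A"], ["A", "B", "C"], n_perm=10)


def make_result(drug, source, kind, fdr, tissue="t1"):
    return ProximityResult(
        drug=drug, tissue=tissue, deg_set_kind=kind, source_db=source,
        observed_dist=1.0, null_dists=np.array([2.0]), empirical_p=0.01,
        n_deg_in_network=5, n_targets_in_network=5, fdr=fdr,
    )


class TestConsensusRule:
    def test_significant_in_both_sources_retained(self):
        results = [
            make_result("d1", "dbA", "up", 0.01),
            make_result("d1", "dbB", "up", 0.04),
        ]
        calls = consensus_calls(results, ["dbA", "dbB"])
        assert calls[0].retained

    def test_one_source_only_not_retained(self):
        results = [
            make_result("d1", "dbA", "up", 0.01),
            make_result("d1", "dbA", "down", 0.01),
            make_result("d1", "dbA", "both", 0.01),
            make_result("d1", "dbB", "up", 0.50),
        ]
        calls = consensus_calls(results, ["dbA", "dbB"])
        assert not calls[0].retained

    def test_different_kinds_per_source_still_retained(self):
        results = [
            make_result("d1", "dbA", "up", 0.01),
            make_result("d1", "dbB", "down", 0.01),
        ]
        calls = consensus_calls(results, ["dbA", "dbB"])
        assert calls[0].retained


class TestScreen:
    def test_screen_end_to_end(self, small_simulation):
        cfg, cm, truth, net, targets = small_simulation
        tissue = cfg.tissue_names()[0]
        up, down = truth.planted_deg_sets[tissue]
        deg_sets = {tissue: {"up": up, "down": down, "both": up | down}}
        results, calls = run_proximity_screen(
            net, deg_sets, targets, n_perm=200, seed=5
        )
        # every runnable DEG kind crossed with both sources, for every drug
        node_set = set(net.nodes)
        runnable = [k for k, genes in deg_sets[tissue].items()
                    if genes & node_set]
        per_drug = {}
        for r in results:
            per_drug.setdefault(r.drug, set()).add((r.deg_set_kind, r.source_db))
        expected = {(k, s) for k in runnable for s in ("dbA", "dbB")}
        assert all(v == expected for v in per_drug.values())
        # hop-0 planting: targets sit inside the DEG set, so the planted drug
        # is at least as close as every random-target drug
        both = [r for r in results if r.deg_set_kind == "both"]
        planted = [r for r in both if r.drug == "drug01"]
        others = [r for r in both if r.drug != "drug01"]
        planted_targets = {
            t for ts in targets if ts.drug == "drug01" for t in ts.targets
        }
        assert planted_targets <= deg_sets[tissue]["both"]
        assert max(r.observed_dist for r in planted) <= min(
            r.observed_dist for r in others
        )

    def test_fdr_monotone_within_stratum(self, small_simulation):
        cfg, cm, truth, net, targets = small_simulation
        tissue = cfg.tissue_names()[0]
        up, down = truth.planted_deg_sets[tissue]
        deg_sets = {tissue: {"up": up, "down": down, "both": up | down}}
        results, _ = run_proximity_screen(net, deg_sets, targets, n_perm=100,
                                          seed=1)
        df = pd.DataFrame(
            [(r.tissue, r.deg_set_kind, r.source_db, r.empirical_p, r.fdr)
             for r in results],
            columns=["tissue", "kind", "source", "p", "fdr"],
        )
        for _, grp in df.groupby(["tissue", "kind", "source"]):
            g = grp.sort_values("p")
            assert (np.diff(g["fdr"].values) >= -1e-12).all()
            assert (g["fdr"].values >= g["p"].values - 1e-12).all()

    def test_screen_determinism(self, small_simulation):
        cfg, cm, truth, net, targets = small_simulation
        tissue = cfg.tissue_names()[0]
        up, down = truth.planted_deg_sets[tissue]
        deg_sets = {tissue: {"up": up, "down": down, "both": up | down}}
        r1, c1 = run_proximity_screen(net, deg_sets, targets, n_perm=50, seed=3)
        r2, c2 = run_proximity_screen(net, deg_sets, targets, n_perm=50, seed=3)
        assert [x.empirical_p for x in r1] == [x.empirical_p for x in r2]
        assert [x.retained for x in c1] == [x.retained for x in c2]

    def test_empty_source_error(self, small_simulation):
        cfg, cm, truth, net, _ = small_simulation
        tissue = cfg.tissue_names()[0]
        up, down = truth.planted_deg_sets[tissue]
        deg_sets = {tissue: {"up": up, "down": down, "both": up | down}}
        with pytest.raises(ConfigurationError):
            run_proximity_screen(net, deg_sets, [], n_perm=10, seed=0)
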