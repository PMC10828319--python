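import networkx as nx
import numpy as np
import pandas as pd
import pytest

from senkit import netmod, syndata
from senkit.netmod import (correlation_graph, degree_powerlaw, edge_census,
                           hub_genes, mcode_modules, mcode_vertex_weights)

from oracles import (mcode_modules_bruteforce, mcode_weights_bruteforce,
                     random_graph)


def _k4_pendant():
    G = nx.complete_graph(["v1", "v2", "v3", "v4"])
    G.add_edge("v1", "u")
    return G


def _expr(rows: dict) -> pd.DataFrame:
    return pd.DataFrame({g: np.asarray(v, dtype=float)
                         for g, v in rows.items()}).T


class TestCorrelationGraph:
    def test_monotone_pair_gets_positive_unit_edge(self):
        expr = _expr({"a": [1, 2, 3, 4, 5], "b": [2, 4, 5, 8, 10],
                      "c": [5, 4, 3, 2, 1]})
        ppi = pd.DataFrame({"gene_a": ["a", "a"], "gene_b": ["b", "c"]})
        G = correlation_graph(expr, ppi, rho_min=0.5)
        assert G["a"]["b"]["rho"] == pytest.approx(1.0)
        assert G["a"]["b"]["sign"] == "+"
        assert G["a"]["c"]["rho"] == pytest.approx(-1.0)
        assert G["a"]["c"]["sign"] == "-"

    def test_correlated_pair_outside_ppi_is_not_linked(self):
        expr = _expr({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4],
                      "c": [4, 1, 3, 2]})
        ppi = pd.DataFrame({"gene_a": ["a"], "gene_b": ["c"]})
        G = correlation_graph(expr, ppi, rho_min=0.5)
        assert not G.has_edge("a", "b")

    def test_constant_gene_pair_skipped_with_warning(self):
        expr = _expr({"a": [1, 2, 3, 4], "b": [5, 5, 5, 5]})
        ppi = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"]})
        with pytest.warns(UserWarning, match="constant"):
            G = correlation_graph(expr, ppi, rho_min=0.1)
        assert G.number_of_edges() == 0

    def test_raising_threshold_never_adds_edges(self, rng):
        expr = pd.DataFrame(rng.normal(size=(15, 30)),
                            index=[f"g{i}" for i in range(15)])
        ppi = pd.DataFrame([(f"g{i}", f"g{j}") for i in range(15)
                            for j in range(i + 1, 15)],
                           columns=["gene_a", "gene_b"])
        prev = None
        for rho_min in (0.1, 0.3, 0.5, 0.7):
            edges = set(map(frozenset,
                            correlation_graph(expr, ppi, rho_min).edges()))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_gene_subset_restricts_nodes(self):
        expr = _expr({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4],
                      "c": [1, 2, 3, 4]})
        ppi = pd.DataFrame({"gene_a": ["a", "b"], "gene_b": ["b", "c"]})
        G = correlation_graph(expr, ppi, rho_min=0.5,
                              gene_subset=["a", "b"])
        assert set(G.nodes()) == {"a", "b"}

    def test_too_few_cells_rejected(self):
        expr = _expr({"a": [1, 2], "b": [2, 1]})
        ppi = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"]})
        with pytest.raises(ValueError, match="3 cells"):
            correlation_graph(expr, ppi)


class TestMcodeWeights:
    def test_k4_with_pendant_hand_trace(self):
        w = mcode_vertex_weights(_k4_pendant())
        for v in ("v1", "v2", "v3", "v4"):
            assert w[v] == pytest.approx(3.0)
        assert w["u"] == pytest.approx(1.0)

    def test_single_edge_and_isolated_vertex(self):
        G = nx.Graph([("a", "b")])
        G.add_node("z")
        w = mcode_vertex_weights(G)
        assert w["a"] == w["b"] == pytest.approx(1.0)
        assert w["z"] == 0.0

    def test_agrees_with_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            nodes, edges = random_graph(rng)
            G = nx.Graph()
            G.add_nodes_from(nodes)
            G.add_edges_from(edges)
            expected = mcode_weights_bruteforce(nodes, edges)
            got = mcode_vertex_weights(G)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v]), (nodes, edges)


class TestMcodeModules:
    def test_k4_pendant_yields_single_clique_module(self):
        mods = mcode_modules(_k4_pendant())
        assert len(mods) == 1
        assert mods[0].nodes == frozenset({"v1", "v2", "v3", "v4"})
        assert mods[0].score == pytest.approx(1.0)

    def test_triangle_is_one_module(self):
        mods = mcode_modules(nx.cycle_graph(["a", "b", "c"]))
        assert len(mods) == 1
        assert mods[0].nodes == frozenset({"a", "b", "c"})

    def test_path_has_no_dense_module(self):
        assert mcode_modules(nx.path_graph(4)) == []

    def test_agrees_with_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(78)
        for _ in range(60):
            nodes, edges = random_graph(rng)
            G = nx.Graph()
            G.add_nodes_from(nodes)
            G.add_edges_from(edges)
            got = {(m.nodes, round(m.score, 9)) for m in mcode_modules(G)}
            expected = {(m, round(s, 9))
                        for m, s in mcode_modules_bruteforce(nodes, edges)}
            assert got == expected, (nodes, edges)

    def test_modules_are_connected_with_min_degree_two(self, rng):
        for _ in range(25):
            G = nx.gnp_random_graph(12, 0.35,
                                    seed=int(rng.integers(2 ** 31)))
            for m in mcode_modules(G):
                sub = G.subgraph(m.nodes)
                assert nx.is_connected(sub)
                assert min(d for _, d in sub.degree()) >= 2
                assert nx.k_core(sub, 2).number_of_nodes() > 0

    def test_bad_vwp_rejected(self):
        with pytest.raises(ValueError, match="vwp"):
            mcode_modules(nx.path_graph(3), vwp=1.5)


class TestDegreePowerlaw:
    def test_exact_powerlaw_histogram_recovered(self):
        # build a graph whose degree histogram is freq(d) = 256 * d^-2
        # realized exactly for d in {1, 2, 4, 8, 16}
        degrees = []
        for d in (1, 2, 4, 8, 16):
            degrees += [d] * (256 // d ** 2)
        if sum(degrees) % 2:
            degrees[0] += 0  # even sum holds for this sequence
        G = nx.configuration_model(degrees, seed=1)
        G = nx.Graph(G)  # collapse multi-edges: perturbs slightly
        fit = netmod.degree_powerlaw(G)
        assert 1.5 <= fit.gamma <= 2.5

    def test_histogram_line_is_exact_via_synthetic_degrees(self):
        # bypass graph realization: feed the fitter a star-free graph whose
        # degree histogram lies exactly on freq = C * d^-2
        class FakeGraph:
            def degree(self):
                degs = []
                for d in (1, 2, 4, 8):
                    degs += [d] * (64 // d ** 2)
                return [(i, d) for i, d in enumerate(degs)]

        fit = netmod.degree_powerlaw(FakeGraph())
        assert fit.gamma == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_regular_graph_rejected(self):
        with pytest.raises(ValueError):
            degree_powerlaw(nx.complete_graph(5))

    def test_preferential_attachment_exponent_in_range(self):
        G = nx.barabasi_albert_graph(3000, 2, seed=5)
        fit = degree_powerlaw(G)
        assert 1.5 <= fit.gamma <= 3.5


class TestCensusAndHubs:
    def _signed_graph(self, pos, neg):
        G = nx.Graph()
        for i, e in enumerate(pos):
            G.add_edge(*e, rho=0.8, sign="+")
        for e in neg:
            G.add_edge(*e, rho=-0.8, sign="-")
        return G

    def test_signed_counts(self):
        G = self._signed_graph([("a", "b"), ("b", "c"), ("c", "d")],
                               [("a", "d")])
        df = edge_census({"T0": G})
        row = df.iloc[0]
        assert (row["positive_edges"], row["negative_edges"]) == (3, 1)

    def test_empty_graph_counts_zero(self):
        df = edge_census({"T0": nx.Graph()})
        assert df.iloc[0]["positive_edges"] == 0
        assert df.iloc[0]["negative_edges"] == 0

    def test_counts_match_bruteforce_scan(self, rng):
        G = nx.gnp_random_graph(20, 0.3, seed=9)
        for a, b in G.edges():
            rho = float(rng.uniform(-1, 1))
            G[a][b].update(rho=rho, sign="+" if rho > 0 else "-")
        df = edge_census({"g": G})
        pos = sum(1 for *_, d in G.edges(data=True) if d["sign"] == "+")
        assert df.iloc[0]["positive_edges"] == pos
        assert df.iloc[0]["negative_edges"] == G.number_of_edges() - pos

    def test_unknown_module_nodes_rejected(self):
        G = self._signed_graph([("a", "b")], [])
        with pytest.raises(ValueError, match="unknown"):
            edge_census({"T0": G}, module_map={"zzz": 1})

    def test_star_centre_is_top_hub(self):
        G = nx.star_graph(5)
        assert hub_genes(G, 1) == [0]
        assert len(hub_genes(G, 100)) == G.number_of_nodes()

    def test_hub_order_matches_degree_sort(self, rng):
        G = nx.gnp_random_graph(15, 0.4, seed=11)
        got = hub_genes(G, 15)
        expected = [v for v, _ in sorted(G.degree(),
                                         key=lambda vd: (-vd[1],
                                                         str(vd[0])))]
        assert got == expected

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hub_genes(nx.Graph())


class TestPlantedModuleRecovery:
    def test_mcode_recovers_planted_module(self):
        expr, ppi, truth = syndata.gen_ppi_expression(
            n_genes=80, planted_modules=[(10, 0.8)], n_cells=500, seed=13)
        G = correlation_graph(expr, ppi, rho_min=0.5)
        mods = mcode_modules(G)
        assert mods, "no module detected"
        planted = {g for g, m in truth.records["membership"].items()
                   if m == 0}
        best = max(mods, key=lambda m: len(m.nodes & planted))
        jacc = len(best.nodes & planted) / len(best.nodes | planted)
        assert jacc >= 0.8
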