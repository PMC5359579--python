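import networkx as nx
import numpy as np
import pandas as pd
import pytest

import phyloecol as pe
from oracles import fisher_bruteforce, spearman_bruteforce


def table_from(counts, columns=None):
    columns = columns or [f"o{j}" for j in range(len(counts[0]))]
    return pe.OtuTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(len(counts))], columns=columns))


class TestSpearman:
    def test_abundance_filter_is_strict(self):
        counts = np.zeros((5, 3), dtype=int)
        counts[:, 0] = [1, 1, 1, 1, 1]   # total 5 -> excluded
        counts[:, 1] = [2, 1, 1, 1, 1]   # total 6 -> retained
        counts[:, 2] = [3, 2, 1, 0, 4]   # total 10 -> retained
        corr = pe.spearman_matrix(table_from(counts.tolist()))
        assert corr.ids == ["o1", "o2"]

    def test_perfect_monotone(self):
        counts = [[1, 2], [2, 4], [3, 6], [4, 8]]
        corr = pe.spearman_matrix(table_from(counts), min_total=0,
                                  use_relative=False)
        assert corr.rho.iloc[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_midrank_oracle_with_ties(self, seed):
        rng = np.random.default_rng(500 + seed)
        counts = rng.integers(0, 5, size=(8, 3))  # many ties
        counts[0] += 1
        corr = pe.spearman_matrix(table_from(counts.tolist()), min_total=0,
                                  use_relative=False)
        cols = corr.ids
        data = pd.DataFrame(counts, columns=[f"o{j}" for j in range(3)])
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                rho, p = spearman_bruteforce(data[cols[i]], data[cols[j]])
                assert corr.rho.loc[cols[i], cols[j]] == pytest.approx(
                    rho, abs=1e-12)
                assert corr.p.loc[cols[i], cols[j]] == pytest.approx(
                    p, abs=1e-8)

    def test_too_few_sites_or_otus(self):
        with pytest.raises(ValueError, match="4 sites"):
            pe.spearman_matrix(table_from([[9, 9], [9, 9], [9, 9]]))
        with pytest.raises(ValueError, match="2 OTUs"):
            pe.spearman_matrix(table_from([[1, 9], [1, 9], [0, 9], [1, 9]]))


class TestBuildNetwork:
    def corr(self, rho_p):
        ids = sorted({i for pair in rho_p for i in pair[:2]})
        rho = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        p = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
        for i, j, r, pv in rho_p:
            rho.loc[i, j] = rho.loc[j, i] = r
            p.loc[i, j] = p.loc[j, i] = pv
        return pe.CorrMatrix(ids, rho, p)

    def test_threshold_logic(self):
        corr = self.corr([("a", "b", 0.61, 0.005),   # edge
                          ("a", "c", 0.90, 0.02),    # fails p
                          ("b", "c", -0.95, 1e-6)])  # negative: no edge
        G = pe.build_network(corr, keep_isolated=True)
        assert G.has_edge("a", "b")
        assert not G.has_edge("a", "c")
        assert not G.has_edge("b", "c")

    def test_signed_flag_admits_negative(self):
        corr = self.corr([("a", "b", -0.95, 1e-6)])
        G = pe.build_network(corr, signed=True, keep_isolated=True)
        assert G.has_edge("a", "b")

    def test_isolated_nodes_dropped_by_default(self):
        corr = self.corr([("a", "b", 0.7, 0.001), ("c", "d", 0.1, 0.9)])
        G = pe.build_network(corr)
        assert set(G.nodes) == {"a", "b"}


class TestTopology:
    def test_path_graph_enumeration(self):
        G = nx.path_graph(["A", "B", "C"])
        topo = pe.topology(G)
        assert topo.graph["diameter_largest"] == 2
        assert topo.graph["average_path_length_largest"] == pytest.approx(4 / 3)
        assert topo.nodes.loc["B", "betweenness"] == pytest.approx(1.0)
        assert topo.nodes.loc["B", "degree"] == 2
        assert topo.nodes.loc["B", "closeness"] == pytest.approx(1.0)
        assert topo.graph["n_shortest_paths"] == 3

    def test_complete_graph(self):
        G = nx.complete_graph(4)
        topo = pe.topology(G)
        assert topo.graph["diameter_largest"] == 1
        assert (topo.nodes["betweenness"] == 0).all()

    def test_disconnected_components_convention(self):
        G = nx.Graph([("a", "b"), ("c", "d")])
        topo = pe.topology(G)
        assert topo.graph["diameter_largest"] == 1
        assert topo.graph["diameter_weighted"] == pytest.approx(1.0)
        assert topo.graph["n_shortest_paths"] == 2  # cross-pairs excluded

    def test_empty_graph_error(self):
        with pytest.raises(ValueError):
            pe.topology(nx.Graph())


class TestLouvain:
    def test_two_triangles_q_half(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part, q = pe.louvain(G, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(part.values())) == 2
        assert part[0] == part[1] == part[2]
        assert part[3] == part[4] == part[5]

    def test_complete_graph_single_module(self):
        G = nx.complete_graph(6)
        part, q = pe.louvain(G, seed=1)
        assert len(set(part.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_q_matches_independent_modularity_formula(self, default_dataset):
        _, _, _, _, table = default_dataset
        corr = pe.spearman_matrix(table)
        G = pe.build_network(corr)
        part, q = pe.louvain(G, seed=2)
        assert q == pytest.approx(pe.modularity(G, part), abs=1e-12)
        communities = {}
        for v, c in part.items():
            communities.setdefault(c, set()).add(v)
        ref = nx.community.modularity(G, communities.values())
        assert q == pytest.approx(ref, abs=1e-12)

    def test_planted_cliques_recovered_across_seeds(self):
        G = nx.Graph()
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    G.add_edge(base + i, base + j)
        G.add_edge(0, 5)
        hits = 0
        for seed in range(40):
            part, _ = pe.louvain(G, seed=seed)
            left = {part[i] for i in range(5)}
            right = {part[i] for i in range(5, 10)}
            hits += len(left) == 1 and len(right) == 1 and left != right
        assert hits >= 38

    def test_edgeless_graph_error(self):
        G = nx.Graph()
        G.add_nodes_from("ab")
        with pytest.raises(ValueError):
            pe.louvain(G)


class TestFisher:
    def test_diagonal_table(self):
        # [[3,0],[0,3]]: two-sided p = 2 / C(6,3) = 0.1
        assert fisher_bruteforce(3, 0, 0, 3) == pytest.approx(0.1)
        from scipy.stats import fisher_exact
        assert fisher_exact([[3, 0], [0, 3]])[1] == pytest.approx(0.1)

    def test_independent_table(self):
        from scipy.stats import fisher_exact
        assert fisher_exact([[1, 1], [1, 1]])[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hypergeometric_enumeration(self, seed):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(600 + seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            a, b, c, d = a + 1, b + 1, c + 1, d + 1
        expect = fisher_bruteforce(a, b, c, d)
        assert fisher_exact([[a, b], [c, d]])[1] == pytest.approx(
            expect, abs=1e-9)

    def test_module_exclusive_to_habitat_small_p(self, default_dataset):
        _, _, _, metadata, table = default_dataset
        corr = pe.spearman_matrix(table)
        G = pe.build_network(corr, table=table)
        part, _ = pe.louvain(G, seed=3)
        res = pe.module_habitat_fisher(part, table, metadata)
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
        # the peat-exclusive lineage forms a module detected only in peat
        assert res["p"].min() < 0.001
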