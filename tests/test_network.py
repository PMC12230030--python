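import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from ccmicro import network, simulate
from ccmicro.io import AbundanceTable


def _table(values, prefix="t"):
    values = np.asarray(values, dtype=float)
    return AbundanceTable(
        taxon_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values)


class TestFilterTaxa:
    def test_mean_abundance_floor(self):
        # 5 taxa with known mean relative abundances; one sits at 0.05%
        base = np.array([0.30, 0.25, 0.30, 0.1495, 0.0005])
        values = np.tile(base[:, None], (1, 4)) * 1000
        kept = network.filter_taxa(_table(values), floor=0.001)
        assert kept.n_taxa == 4

    def test_absent_taxon_removed(self):
        values = np.array([[10.0, 10.0], [0.0, 0.0]])
        kept = network.filter_taxa(_table(values), floor=0.0)
        assert kept.taxon_ids == ["t0"]

    def test_present_everywhere_retained(self):
        values = np.vstack([np.full(4, 5.0), np.full(4, 995.0)])
        kept = network.filter_taxa(_table(values), floor=0.001)
        assert "t0" in kept.taxon_ids  # 0.5% > 0.1%

    def test_floor_bounds(self):
        with pytest.raises(ValueError):
            network.filter_taxa(_table(np.ones((2, 2))), floor=1.5)


class TestCorrelationMatrix:
    def test_proportional_and_antiproportional(self):
        a = np.array([1.0, 2.0, 5.0, 3.0, 8.0, 4.0])
        values = np.vstack([a, 2 * a, -a + 10.0])
        r, p = network.correlation_matrix(_table(values))
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert p[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.random((2, 10))
        r, p = network.correlation_matrix(_table(values))
        x, y = values
        # direct Pearson formula + t-distribution p-value
        r_direct = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        t = r_direct * np.sqrt(8 / (1 - r_direct ** 2))
        p_direct = 2 * stats.t.sf(abs(t), 8)
        assert r[0, 1] == pytest.approx(r_direct, abs=1e-12)
        assert p[0, 1] == pytest.approx(p_direct, abs=1e-12)
        # and agrees with scipy's reference implementation
        ref = stats.pearsonr(x, y)
        assert r[0, 1] == pytest.approx(ref.statistic, abs=1e-12)
        assert p[0, 1] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_variance_taxon_flagged(self):
        values = np.vstack([np.full(6, 3.0), np.arange(6.0)])
        r, _ = network.correlation_matrix(_table(values))
        assert np.isnan(r[0, 1])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            network.correlation_matrix(_table(np.ones((2, 3))))


class TestAdjustBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.04], [0.04]),
        ([0.005, 0.04], [0.01, 0.04]),
    ])
    def test_step_up_arithmetic(self, p, expected):
        np.testing.assert_allclose(network.adjust_bh(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            network.adjust_bh([0.5, 1.2])


class TestBuildNetwork:
    def _full_chain(self, values, r_min=0.7, alpha=0.05):
        table = _table(values)
        return network.cooccurrence_network(table, r_min=r_min, alpha=alpha,
                                            floor=0.0)

    def test_brute_force_edge_set(self):
        rng = np.random.default_rng(21)
        base = rng.random((6, 10))
        base[1] = base[0] * 1.5 + rng.normal(0, 0.01, 10)   # strong +
        base[3] = -base[2] + 2.0 + rng.normal(0, 0.01, 10)  # strong -
        net = self._full_chain(base)
        # independent brute force over all 15 pairs
        rel = base / base.sum(axis=0)
        raw = {}
        for i, j in itertools.combinations(range(6), 2):
            res = stats.pearsonr(rel[i], rel[j])
            raw[(i, j)] = (res.statistic, res.pvalue)
        pvals = [raw[k][1] for k in sorted(raw)]
        qvals = dict(zip(sorted(raw), stats.false_discovery_control(pvals)))
        expected = {(f"t{i}", f"t{j}") for (i, j) in raw
                    if abs(raw[(i, j)][0]) >= 0.7 and qvals[(i, j)] < 0.05}
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == {tuple(sorted(e)) for e in expected}
        assert net.n_edges == len(expected)

    def test_no_thresholds_gives_complete_graph(self):
        rng = np.random.default_rng(2)
        net = self._full_chain(rng.random((5, 8)), r_min=0.0, alpha=1.0)
        assert net.n_edges == 10

    def test_high_threshold_gives_no_edges(self):
        rng = np.random.default_rng(4)
        net = self._full_chain(rng.random((5, 30)), r_min=0.999)
        assert net.n_edges == 0
        assert net.n_nodes == 5  # isolated nodes retained

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        values = rng.random((8, 12))
        loose = self._full_chain(values, r_min=0.3, alpha=0.5)
        tight_r = self._full_chain(values, r_min=0.6, alpha=0.5)
        tight_a = self._full_chain(values, r_min=0.3, alpha=0.05)
        assert set(tight_r.graph.edges) <= set(loose.graph.edges)
        assert set(tight_a.graph.edges) <= set(loose.graph.edges)

    def test_order_invariance(self):
        rng = np.random.default_rng(31)
        values = rng.random((6, 10))
        table = _table(values)
        net = network.cooccurrence_network(table, r_min=0.3, alpha=0.5,
                                           floor=0.0)
        perm_t = rng.permutation(6)
        perm_s = rng.permutation(10)
        shuffled = AbundanceTable(
            taxon_ids=[table.taxon_ids[i] for i in perm_t],
            sample_ids=[table.sample_ids[j] for j in perm_s],
            values=values[np.ix_(perm_t, perm_s)])
        net2 = network.cooccurrence_network(shuffled, r_min=0.3, alpha=0.5,
                                            floor=0.0)
        assert ({tuple(sorted(e)) for e in net.graph.edges}
                == {tuple(sorted(e)) for e in net2.graph.edges})

    def test_independent_neutral_taxa_yield_few_edges(self):
        edges = 0
        for seed in range(5):
            meta = simulate.lognormal_metacommunity(30, seed=50 + seed, sd=1.0)
            params = simulate.NeutralParams(metacommunity=meta, N=5000, m=0.5)
            table = simulate.simulate_neutral_table(params, 14, seed=60 + seed)
            net = network.cooccurrence_network(table, floor=0.0)
            edges += net.n_edges
        assert edges <= 5


def _graph_to_net(g):
    for _, _, d in g.edges(data=True):
        d.setdefault("r", 1.0)
        d.setdefault("abs_r", 1.0)
        d.setdefault("sign", "+")
    edges = None
    import pandas as pd
    edges = pd.DataFrame([{"taxon_a": a, "taxon_b": b, "r": 1.0, "q": 0.0,
                           "sign": "+"} for a, b in g.edges])
    return network.CorrelationNetwork(graph=g, edges=edges)


class TestTopology:
    def test_complete_graph(self):
        topo = network.topology(_graph_to_net(nx.complete_graph(4)))
        assert topo.density == pytest.approx(1.0)
        assert topo.avg_degree == pytest.approx(3.0)
        assert topo.avg_clustering == pytest.approx(1.0)
        assert topo.avg_path_length == pytest.approx(1.0)

    def test_two_triangles_modularity(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        topo = network.topology(_graph_to_net(g), seed=0)
        assert topo.modularity == pytest.approx(0.5)
        assert topo.n_components == 2

    def test_path_graph(self):
        g = nx.path_graph(3)
        topo = network.topology(_graph_to_net(g))
        assert topo.avg_path_length == pytest.approx(4.0 / 3.0)
        assert topo.avg_clustering == pytest.approx(0.0)

    def test_sign_percentages_sum(self):
        g = nx.Graph()
        g.add_edge("a", "b", r=0.9, abs_r=0.9, sign="+")
        g.add_edge("b", "c", r=-0.8, abs_r=0.8, sign="-")
        g.add_edge("c", "d", r=0.75, abs_r=0.75, sign="+")
        import pandas as pd
        net = network.CorrelationNetwork(graph=g, edges=pd.DataFrame())
        topo = network.topology(net)
        assert topo.pct_positive_edges + topo.pct_negative_edges == pytest.approx(100.0)
        assert topo.pct_negative_edges == pytest.approx(100.0 / 3.0)

    def test_empty_graph_markers(self):
        topo = network.topology(_graph_to_net(nx.empty_graph(0)))
        assert topo.n_nodes == 0
        assert np.isnan(topo.modularity)
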