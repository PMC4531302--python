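"""Graph metrics against brute-force oracles; group comparisons."""
from itertools import combinations

import numpy as np
import pytest

from roifc.connectivity import ConnMatrix
from roifc.core import UndefinedResultWarning
from roifc.graphstats import (BinaryGraph, assortativity, binarize,
                              clustering_coefficient, compare_groups_edgewise,
                              compare_methods_paired, count_significant_edges,
                              global_efficiency, graph_metrics, group_graph,
                              louvain_modularity, modularity_q)


def graph_from_adj(adj):
    n = len(adj)
    return BinaryGraph(labels=[f"N.n{i}" for i in range(n)],
                       adjacency=np.asarray(adj, dtype=bool),
                       r_threshold=0.35)


def graph_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return graph_from_adj(adj)


# ------------------------------------------------------------- oracles

def oracle_clustering(adj):
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a][b])
        out.append(2.0 * links / (k * (k - 1)))
    return out


def oracle_efficiency(adj):
    n = len(adj)
    dist = [[np.inf] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0
        for j in range(n):
            if adj[i][j]:
                dist[i][j] = 1
    for k in range(n):            # Floyd-Warshall
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    total = sum(1.0 / dist[i][j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(dist[i][j]))
    return total / (n * (n - 1))


def oracle_assortativity(adj):
    n = len(adj)
    deg = [sum(adj[i]) for i in range(n)]
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if adj[i][j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def all_partitions(items):
    """Every partition of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    head, *rest = items
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {head}] + part[i + 1:]
        yield part + [{head}]


# ------------------------------------------------------------- binarize

class TestBinarize:
    def _cm(self, v):
        n = len(v)
        return ConnMatrix(labels=[f"N.n{i}" for i in range(n)],
                          values=np.asarray(v, float))

    def test_threshold_is_strict(self):
        cm = self._cm([[1, 0.35], [0.35, 1]])
        assert binarize(cm, 0.35).n_edges == 0
        cm2 = self._cm([[1, 0.3500001], [0.3500001, 1]])
        assert binarize(cm2, 0.35).n_edges == 1

    def test_negative_correlations_never_edges(self):
        cm = self._cm([[1, -0.9], [-0.9, 1]])
        assert binarize(cm).n_edges == 0

    def test_all_ones_gives_complete_graph(self):
        cm = self._cm(np.ones((4, 4)))
        assert binarize(cm).n_edges == 6

    def test_undefined_entries_become_no_edge_with_warning(self):
        v = np.array([[1, np.nan], [np.nan, 1]])
        with pytest.warns(UndefinedResultWarning):
            g = binarize(self._cm(v))
        assert g.n_edges == 0

    def test_group_graph_averages_then_thresholds(self):
        a = self._cm([[1, 0.5], [0.5, 1]])
        b = self._cm([[1, 0.1], [0.1, 1]])
        assert group_graph([a, b]).n_edges == 0        # mean 0.3
        c = self._cm([[1, 0.9], [0.9, 1]])
        assert group_graph([a, c]).n_edges == 1        # mean 0.7
        assert group_graph([a]).n_edges == binarize(a).n_edges

    def test_group_graph_empty_rejected(self):
        with pytest.raises(ValueError):
            group_graph([])


# ------------------------------------------------------------- metrics

class TestMetricsClosedForms:
    def test_triangle_clustering(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        per, mean = clustering_coefficient(g)
        assert all(v == 1.0 for v in per.values()) and mean == 1.0

    def test_path_clustering_zero(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        _, mean = clustering_coefficient(g)
        assert mean == 0.0

    def test_complete_graph_efficiency_one(self):
        g = graph_from_adj(~np.eye(5, dtype=bool))
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_disconnected_graph_efficiency_zero(self):
        g = graph_from_edges(4, [])
        assert global_efficiency(g) == 0.0

    def test_p3_efficiency_closed_form(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert global_efficiency(g) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_star_assortativity_minus_one(self):
        g = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        assert assortativity(g) == pytest.approx(-1.0)

    def test_cycle_assortativity_undefined(self):
        g = graph_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        with pytest.warns(UndefinedResultWarning):
            assert np.isnan(assortativity(g))


SEEDED_GRAPHS = [np.random.default_rng(s).random((6, 6)) for s in range(3)]


class TestMetricsAgainstBruteForce:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_graphs_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 8)
        adj = rng.random((n, n)) < 0.45
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        g = graph_from_adj(adj)
        per, mean = clustering_coefficient(g)
        assert np.allclose(list(per.values()), oracle_clustering(adj.tolist()))
        assert global_efficiency(g) == pytest.approx(
            oracle_efficiency(adj.tolist()), abs=1e-12)
        if g.n_edges:
            oracle = oracle_assortativity(adj.tolist())
            if np.isnan(oracle):
                with pytest.warns(UndefinedResultWarning):
                    assert np.isnan(assortativity(g))
            else:
                assert assortativity(g) == pytest.approx(oracle, abs=1e-12)


class TestLouvain:
    def test_two_cliques_with_bridge_matches_exhaustive_maximum(self):
        edges = ([(i, j) for i, j in combinations(range(4), 2)]
                 + [(i, j) for i, j in combinations(range(4, 8), 2)]
                 + [(3, 4)])
        g = graph_from_edges(8, edges)
        part, q = louvain_modularity(g, seed=0)
        best_q = max(modularity_q(g, [set(f"N.n{i}" for i in p) for p in part2])
                     for part2 in all_partitions(list(range(8))))
        assert q == pytest.approx(best_q, abs=1e-12)
        assert sorted(sorted(p) for p in part) == [
            [f"N.n{i}" for i in range(4)], [f"N.n{i}" for i in range(4, 8)]]

    def test_complete_graph_single_community_q_zero(self):
        g = graph_from_adj(~np.eye(4, dtype=bool))
        part, q = louvain_modularity(g, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)
        best_q = max(modularity_q(g, [set(f"N.n{i}" for i in p) for p in part2])
                     for part2 in all_partitions(list(range(4))))
        assert best_q == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        adj = rng.random((12, 12)) < 0.3
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        g = graph_from_adj(adj)
        assert louvain_modularity(g, seed=3) == louvain_modularity(g, seed=3)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            louvain_modularity(graph_from_edges(3, []))

    def test_graph_metrics_invariants(self):
        rng = np.random.default_rng(8)
        adj = rng.random((10, 10)) < 0.4
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        gm = graph_metrics(graph_from_adj(adj), seed=0)
        assert -0.5 <= gm.modularity_q <= 1.0
        assert 0.0 <= gm.global_efficiency <= 1.0
        covered = sorted(lab for p in gm.partition for lab in p)
        assert covered == sorted(f"N.n{i}" for i in range(10))


# ------------------------------------------------------------- t tests

class TestPairedComparison:
    def test_identical_samples_give_t0_p1(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert compare_methods_paired(a, a.copy()) == (0.0, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UndefinedResultWarning):
            t, p = compare_methods_paired(a, a + 2.0)
        assert np.isnan(t) and np.isnan(p)

    def test_matches_textbook_closed_form(self):
        a = np.array([5.1, 4.8, 6.0, 5.5, 4.9, 5.7, 6.1, 5.2, 4.7, 5.9])
        b = np.array([4.6, 4.9, 5.1, 5.0, 4.4, 5.5, 5.8, 4.9, 4.5, 5.2])
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats
        p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
        t, p = compare_methods_paired(a, b)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_methods_paired([1.0, 2.0], [1.0, 3.0])


def _random_cms(rng, n_subjects, labels, shift=0.0):
    out = []
    n = len(labels)
    for s in range(n_subjects):
        v = rng.normal(0.2 + shift, 0.1, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        out.append(ConnMatrix(labels=labels, values=v,
                              subject_id=f"s{s}"))
    return out


class TestEdgewiseComparison:
    def test_family_size_is_all_node_pairs(self, rng):
        labels = [f"N{i // 6}.n{i % 6}" for i in range(30)]
        ec = compare_groups_edgewise(_random_cms(rng, 3, labels),
                                     _random_cms(rng, 3, labels))
        assert ec.m == 435
        assert len(ec.table) == 435

    def test_corrected_implies_uncorrected(self, rng):
        labels = [f"A.n{i}" for i in range(8)]
        ec = compare_groups_edgewise(_random_cms(rng, 6, labels),
                                     _random_cms(rng, 6, labels, shift=0.3))
        t = ec.table
        assert (t.loc[t["sig_bonferroni"], "sig_uncorrected"]).all()

    def test_identical_groups_have_no_corrected_hits(self, rng):
        labels = [f"A.n{i}" for i in range(5)]
        cms = _random_cms(rng, 5, labels)
        ec = compare_groups_edgewise(cms, [ConnMatrix(labels=labels,
                                                      values=c.values.copy())
                                           for c in cms])
        assert not ec.table["sig_bonferroni"].any()
        assert np.allclose(ec.table["t"].abs(), 0.0)

    def test_undefined_entries_excluded_pairwise(self, rng):
        labels = [f"A.n{i}" for i in range(3)]
        g1 = _random_cms(rng, 4, labels)
        v = g1[0].values.copy()
        v[0, 1] = v[1, 0] = np.nan
        g1[0] = ConnMatrix(labels=labels, values=v)
        with pytest.warns(UndefinedResultWarning, match="excluded"):
            ec = compare_groups_edgewise(g1, _random_cms(rng, 4, labels))
        assert np.isfinite(ec.table["t"]).all()

    def test_count_significant_edges_directions(self, rng):
        labels = [f"A.n{i}" for i in range(4)] + [f"B.n{i}" for i in range(4)]
        g1 = _random_cms(rng, 8, labels, shift=0.4)
        g2 = _random_cms(rng, 8, labels)
        ec = compare_groups_edgewise(g1, g2)
        dec = count_significant_edges(ec, within_network=False,
                                      direction="decrease", corrected=False)
        inc = count_significant_edges(ec, within_network=False,
                                      direction="increase", corrected=False)
        both = count_significant_edges(ec, within_network=False,
                                       direction="any", corrected=False)
        assert dec + inc == both
        within = count_significant_edges(ec, within_network=True,
                                         direction="any", corrected=False)
        assert within <= both

    def test_small_groups_rejected(self, rng):
        labels = ["A.a", "A.b"]
        with pytest.raises(ValueError, match="2 subjects"):
            compare_groups_edgewise(_random_cms(rng, 1, labels),
                                    _random_cms(rng, 3, labels))
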