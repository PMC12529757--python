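"""Graph construction, maximin cutoff, widest-path extraction."""

import itertools

import networkx as nx
import numpy as np
import pytest

import stresspath as sp
from stresspath.pathways import (
    DisconnectedError,
    PathwayGraph,
    _widest_path,
)

from conftest import random_delta_matrix


def _graph_from_edges(edges, source, sink):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return PathwayGraph(graph=g, source=frozenset(source),
                        sink=frozenset(sink))


def _brute_force_cutoff(g: PathwayGraph):
    """Oracle: sweep every unique weight, test connectivity with networkx."""
    weights = sorted({d["weight"] for _, _, d in g.graph.edges(data=True)})
    best = None
    for w in weights:
        sub = nx.Graph(
            (u, v) for u, v, d in g.graph.edges(data=True)
            if d["weight"] >= w)
        sub.add_nodes_from(g.graph.nodes)
        if any(nx.has_path(sub, s, t)
               for s in g.source if s in sub
               for t in g.sink if t in sub):
            best = w
        else:
            break
    return best


def _random_pathway_graph(rng, n_max=30):
    n = int(rng.integers(5, n_max + 1))
    p = float(rng.uniform(0.15, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for u, v in g.edges:
        g.edges[u, v]["weight"] = float(rng.uniform(0.1, 10.0))
    nodes = list(g.nodes)
    rng.shuffle(nodes)
    k = max(1, n // 8)
    keyed = nx.relabel_nodes(g, {i: ("A", i + 1) for i in g.nodes})
    source = frozenset(("A", i + 1) for i in nodes[:k])
    sink = frozenset(("A", i + 1) for i in nodes[k:2 * k])
    return PathwayGraph(graph=keyed, source=source, sink=sink)


class TestBuildGraph:
    def test_floor_zero_dense_matrix_complete_graph(self):
        dF = random_delta_matrix(np.random.default_rng(0), n=6)
        g = sp.build_graph(dF, 0.0, [("A", 1)], [("A", 6)])
        assert g.graph.number_of_edges() == 6 * 5 // 2

    def test_floor_above_max_is_error(self):
        dF = random_delta_matrix(np.random.default_rng(1), n=5)
        with pytest.raises(ValueError, match="no edges"):
            sp.build_graph(dF, float(dF.values.max()) + 1.0,
                           [("A", 1)], [("A", 5)])

    def test_hand_counted_four_by_four(self):
        vals = np.zeros((4, 4))
        # two strong edges (5.0) and two weak (1.0)
        for (i, j), w in {(0, 1): 5.0, (1, 2): 1.0,
                          (2, 3): 5.0, (0, 3): 1.0}.items():
            vals[i, j] = vals[j, i] = w
        dF = sp.DeltaForceMatrix(
            index=[("A", i) for i in range(1, 5)], values=vals)
        g = sp.build_graph(dF, 2.0, [("A", 1)], [("A", 4)])
        assert g.graph.number_of_nodes() == 4
        assert g.graph.number_of_edges() == 2


class TestMaxConnectivityCutoff:
    def test_single_bridging_edge(self):
        g = _graph_from_edges([(("A", 1), ("B", 1), 4.2)],
                              [("A", 1)], [("B", 1)])
        assert sp.max_connectivity_cutoff(g) == pytest.approx(4.2)

    def test_two_parallel_chains_picks_wider(self):
        edges = [("s", "a", 8), ("a", "t", 3),       # bottleneck 3
                 ("s", "b", 7), ("b", "t", 9)]       # bottleneck 7
        g = _graph_from_edges(edges, ["s"], ["t"])
        assert sp.max_connectivity_cutoff(g) == pytest.approx(7)

    def test_disconnected_regions_error(self):
        g = _graph_from_edges(
            [(("A", 1), ("A", 2), 1.0), (("B", 1), ("B", 2), 1.0)],
            [("A", 1)], [("B", 2)])
        with pytest.raises(DisconnectedError,
                           match="no perturbation connectivity"):
            sp.max_connectivity_cutoff(g)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 60:
            g = _random_pathway_graph(rng)
            oracle = _brute_force_cutoff(g)
            if oracle is None:
                with pytest.raises(DisconnectedError):
                    sp.max_connectivity_cutoff(g)
            else:
                assert sp.max_connectivity_cutoff(g) == oracle
            checked += 1

    def test_monotone_under_edge_insertion_and_removal(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = _random_pathway_graph(rng, n_max=15)
            try:
                base = sp.max_connectivity_cutoff(g)
            except DisconnectedError:
                continue
            # adding a heavy source-sink edge can only raise the cutoff
            g2 = PathwayGraph(g.graph.copy(), g.source, g.sink)
            s, t = next(iter(g.source)), next(iter(g.sink))
            g2.graph.add_edge(s, t, weight=1e6)
            assert sp.max_connectivity_cutoff(g2) >= base
            # removing any single edge can only lower it
            u, v, _ = next(iter(g.graph.edges(data=True)))
            g3 = PathwayGraph(g.graph.copy(), g.source, g.sink)
            g3.graph.remove_edge(u, v)
            try:
                assert sp.max_connectivity_cutoff(g3) <= base
            except DisconnectedError:
                pass

    def test_scaling_weights_scales_cutoff(self):
        rng = np.random.default_rng(8)
        while True:
            g = _random_pathway_graph(rng, n_max=12)
            try:
                base = sp.max_connectivity_cutoff(g)
                break
            except DisconnectedError:
                continue
        lam = 3.7
        g2 = PathwayGraph(g.graph.copy(), g.source, g.sink)
        for u, v in g2.graph.edges:
            g2.graph.edges[u, v]["weight"] *= lam
        assert sp.max_connectivity_cutoff(g2) == pytest.approx(lam * base)
        p1 = sp.extract_pathways(g, base).paths
        p2 = sp.extract_pathways(g2, lam * base).paths
        assert p1 == p2


class TestExtractPathways:
    def test_single_chain_is_unique_path(self):
        edges = [(("A", i), ("A", i + 1), float(i)) for i in range(1, 5)]
        g = _graph_from_edges(edges, [("A", 1)], [("A", 5)])
        res = sp.extract_pathways(g, 1.0, max_paths=3)
        assert res.paths == [[("A", i) for i in range(1, 6)]]
        assert res.bottlenecks[0] == pytest.approx(1.0)

    def test_cutoff_above_limit_rejected(self):
        g = _graph_from_edges([(("A", 1), ("A", 2), 2.0)],
                              [("A", 1)], [("A", 2)])
        with pytest.raises(ValueError, match="exceeds"):
            sp.extract_pathways(g, 5.0)

    def test_first_bottleneck_equals_cutoff_on_random_graphs(self):
        rng = np.random.default_rng(9)
        done = 0
        while done < 25:
            g = _random_pathway_graph(rng, n_max=20)
            try:
                c = sp.max_connectivity_cutoff(g)
            except DisconnectedError:
                continue
            res = sp.extract_pathways(g, c, max_paths=1)
            assert res.bottlenecks[0] == pytest.approx(c)
            assert min(
                g.graph.edges[u, v]["weight"]
                for u, v in zip(res.paths[0], res.paths[0][1:])
            ) == pytest.approx(c)
            assert res.paths[0][0] in g.source
            assert res.paths[0][-1] in g.sink
            done += 1

    def test_widest_path_matches_enumeration_on_small_graphs(self):
        rng = np.random.default_rng(10)
        done = 0
        while done < 30:
            n = int(rng.integers(4, 9))
            g_nx = nx.gnp_random_graph(n, 0.5,
                                       seed=int(rng.integers(2**31)))
            for u, v in g_nx.edges:
                g_nx.edges[u, v]["weight"] = float(rng.uniform(1, 10))
            keyed = nx.relabel_nodes(g_nx,
                                     {i: ("A", i + 1) for i in g_nx.nodes})
            source, sink = frozenset([("A", 1)]), frozenset([("A", n)])
            if (("A", 1) not in keyed or ("A", n) not in keyed
                    or not nx.has_path(keyed, ("A", 1), ("A", n))):
                continue
            best = max(
                min(keyed.edges[u, v]["weight"]
                    for u, v in zip(path, path[1:]))
                for path in nx.all_simple_paths(keyed, ("A", 1), ("A", n))
            )
            path, bottleneck = _widest_path(keyed, source, sink)
            assert bottleneck == pytest.approx(best)
            done += 1

    def test_second_path_found_after_interior_removal(self):
        # two node-disjoint routes: extraction ranks them by bottleneck
        edges = [("s", "a", 9), ("a", "t", 8),
                 ("s", "b", 6), ("b", "t", 7)]
        g = _graph_from_edges(edges, ["s"], ["t"])
        res = sp.extract_pathways(g, 1.0, max_paths=3)
        assert res.paths[0] == ["s", "a", "t"]
        assert res.paths[1] == ["s", "b", "t"]
        assert res.bottlenecks == [pytest.approx(8.0), pytest.approx(6.0)]

    def test_tie_break_prefers_fewer_hops_then_lexicographic(self):
        edges = [("s", "m", 5), ("m", "t", 5),
                 ("s", "a", 5), ("a", "b", 5), ("b", "t", 5)]
        g = _graph_from_edges(edges, ["s"], ["t"])
        res = sp.extract_pathways(g, 5.0, max_paths=1)
        assert res.paths[0] == ["s", "m", "t"]
        # pure lexicographic tie at equal hops
        edges = [("s", "a", 5), ("a", "t", 5), ("s", "m", 5), ("m", "t", 5)]
        g = _graph_from_edges(edges, ["s"], ["t"])
        res = sp.extract_pathways(g, 5.0, max_paths=1)
        assert res.paths[0] == ["s", "a", "t"]


class TestRobustResidues:
    def _result(self, paths):
        return sp.PathwayResult(cutoff=1.0, subgraph=nx.Graph(),
                                paths=paths, bottlenecks=[1.0] * len(paths))

    def test_identical_results_full_node_set(self):
        paths = [[("A", 1), ("A", 2), ("B", 1)]]
        out = sp.robust_residues([self._result(paths)] * 3)
        assert out == {("A", 1), ("A", 2), ("B", 1)}

    def test_disjoint_results_empty(self):
        r1 = self._result([[("A", 1), ("A", 2)]])
        r2 = self._result([[("B", 1), ("B", 2)]])
        assert sp.robust_residues([r1, r2]) == frozenset()

    def test_fewer_than_two_results_rejected(self):
        with pytest.raises(ValueError):
            sp.robust_residues([self._result([])])

    def test_planted_quartet_contains_interface_bridge(self, planted_dimer):
        # four comparisons with different region choices (both directions
        # across the dimer, from the site and from deeper in chain A):
        # every maximin route must use the planted interface bridge, so
        # the intersection keeps the bridge residues.
        net, net_planted, spec = planted_dimer
        bridge = {("A", 32), ("B", 32)}
        region_pairs = [
            ([("A", 28), ("A", 29)], [("B", 31)]),
            ([("B", 31)], [("A", 28), ("A", 29)]),
            ([("A", 25)], [("B", 31)]),
            ([("B", 30)], [("A", 30)]),
        ]
        results = []
        for i, (src, snk) in enumerate(region_pairs):
            ta = sp.sample_ensemble(net, 2000, seed=50 + 2 * i)
            tb = sp.sample_ensemble(net_planted, 2000, seed=51 + 2 * i)
            fa, fb = sp.align_force_matrices(
                sp.mean_force_matrix(ta, net),
                sp.mean_force_matrix(tb, net_planted))
            dF = sp.force_difference(fa, fb)
            g = sp.build_graph(dF, 0.0, src, snk)
            c = sp.max_connectivity_cutoff(g)
            results.append(sp.extract_pathways(g, c, max_paths=2))
        robust = sp.robust_residues(results)
        assert bridge <= robust


class TestExports:
    def test_graphml_and_edge_tsv(self, tmp_path, apo_vs_planted):
        dF, _ = apo_vs_planted
        g = sp.build_graph(dF, 0.0, [("A", 28)], [("B", 31)])
        g.write_graphml(tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_edges() == g.graph.number_of_edges()
        cutoff = sp.max_connectivity_cutoff(g)
        g.write_edge_tsv(tmp_path / "edges.tsv", cutoff=cutoff)
        lines = (tmp_path / "edges.tsv").read_text().splitlines()
        assert lines[0] == "i\tj\tweight_pN\tsurviving_at_cutoff"
        assert len(lines) - 1 == g.graph.number_of_edges()
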