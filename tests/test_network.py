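"""Topology measures against exhaustive oracles; exponents; subnetworks."""

import itertools

import networkx as nx
import numpy as np
import pytest

from centralprot import network as net

# ------------------------------------------------------------------ oracles


def oracle_betweenness(G):
    """Raw pair-count betweenness via explicit shortest-path enumeration."""
    nodes = list(G.nodes)
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def oracle_clustering(G):
    out = {}
    for v in G.nodes:
        nbrs = list(G.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if G.has_edge(a, b)
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def oracle_kcore(G):
    """Largest k such that the node survives iterative degree-k pruning."""
    out = {n: 0 for n in G.nodes}
    for k in range(1, G.number_of_nodes() + 1):
        H = G.copy()
        while True:
            drop = [n for n in H.nodes if H.degree[n] < k]
            if not drop:
                break
            H.remove_nodes_from(drop)
        for n in H.nodes:
            out[n] = k
        if H.number_of_nodes() == 0:
            break
    return out


def oracle_eigenvector(G):
    """Unit-norm principal eigenvector of the largest component's adjacency."""
    out = {n: 0.0 for n in G.nodes}
    comp = max(nx.connected_components(G), key=len)
    if len(comp) == 1:
        out[next(iter(comp))] = 1.0
        return out
    nodes = sorted(comp)
    A = nx.to_numpy_array(G.subgraph(nodes), nodelist=nodes)
    w, v = np.linalg.eigh(A)
    vec = np.abs(v[:, np.argmax(w)])
    vec /= np.linalg.norm(vec)
    for n, x in zip(nodes, vec):
        out[n] = x
    return out


def assert_matches_oracles(G):
    prof = net.topology_measures(G)
    deg = dict(G.degree)
    bc = oracle_betweenness(G)
    cl = oracle_clustering(G)
    kc = oracle_kcore(G)
    ev = oracle_eigenvector(G)
    for n in G.nodes:
        assert prof.loc[n, "degree"] == deg[n]
        assert prof.loc[n, "betweenness"] == pytest.approx(bc[n], abs=1e-9)
        assert prof.loc[n, "clustering"] == pytest.approx(cl[n], abs=1e-9)
        assert prof.loc[n, "kcore"] == kc[n]
        assert prof.loc[n, "eigenvector"] == pytest.approx(ev[n], abs=1e-6)
        assert prof.loc[n, "kcore"] <= deg[n]


# -------------------------------------------------------------------- tests


class TestTopologyMeasures:
    def test_triangle_symmetry(self):
        prof = net.topology_measures(nx.cycle_graph(3))
        assert (prof["degree"] == 2).all()
        assert (prof["clustering"] == 1.0).all()
        assert (prof["kcore"] == 2).all()
        assert (prof["betweenness"] == 0.0).all()

    def test_star_betweenness(self):
        G = nx.star_graph(4)  # center 0, four leaves
        prof = net.topology_measures(G)
        assert prof.loc[0, "betweenness"] == 6.0  # all leaf pairs
        assert (prof.loc[1:, "betweenness"] == 0.0).all()
        assert (prof.loc[1:, "clustering"] == 0.0).all()

    def test_small_graphs_match_oracles(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            p = float(rng.uniform(0.15, 0.9))
            G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            assert_matches_oracles(G)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            net.topology_measures(nx.Graph())


class TestShortestPathDistribution:
    def test_path_graph_endpoints(self):
        G = nx.path_graph(["A", "B", "C"])
        hist, unreachable = net.shortest_path_distribution(G, {"A"}, {"C"})
        assert hist == {2: 1} and unreachable == 0

    def test_triangle_all_pairs(self):
        G = nx.cycle_graph(3)
        hist, _ = net.shortest_path_distribution(G, set(G), set(G))
        assert hist == {1: 3}

    def test_matches_bfs_oracle_on_random_graph(self):
        G = nx.gnp_random_graph(50, 0.06, seed=3)
        nodes = list(G)
        set_a, set_b = set(nodes[:30]), set(nodes[20:])
        hist, unreachable = net.shortest_path_distribution(G, set_a, set_b)
        expect: dict = {}
        n_unreach = 0
        seen = set()
        for a in set_a:
            for b in set_b:
                if a == b or frozenset((a, b)) in seen:
                    continue
                seen.add(frozenset((a, b)))
                try:
                    d = nx.shortest_path_length(G, a, b)
                    expect[d] = expect.get(d, 0) + 1
                except nx.NetworkXNoPath:
                    n_unreach += 1
        assert hist == dict(sorted(expect.items()))
        assert unreachable == n_unreach

    def test_unreachable_counted_separately(self):
        G = nx.Graph([("A", "B")])
        G.add_node("C")
        hist, unreachable = net.shortest_path_distribution(G, {"A"}, {"B", "C"})
        assert hist == {1: 1} and unreachable == 1


class TestSubnetwork:
    def _graph(self):
        G = nx.gnp_random_graph(20, 0.2, seed=1)
        terms = {n: frozenset({f"T{n % 3}"}) for n in G}
        labels = {n: {"central": n < 10, "n_detected": 7 if n < 10 else 3} for n in G}
        return net.AnnotatedGraph(graph=G, node_terms=terms, node_labels=labels)

    def test_full_node_set_is_identity(self):
        g = self._graph()
        sub = net.extract_subnetwork(g, set(g.graph.nodes))
        assert set(sub.graph.edges) == set(g.graph.edges)
        assert sub.node_terms == g.node_terms

    def test_single_node_has_no_edges(self):
        sub = net.extract_subnetwork(self._graph(), {0})
        assert sub.graph.number_of_edges() == 0

    def test_induced_edges_equal_filtered_edge_list(self):
        g = self._graph()
        keep = set(range(0, 20, 2))
        sub = net.extract_subnetwork(g, keep)
        expected = {
            frozenset(e) for e in g.graph.edges if e[0] in keep and e[1] in keep
        }
        assert {frozenset(e) for e in sub.graph.edges} == expected
        again = net.extract_subnetwork(sub, keep)
        assert set(again.graph.edges) == set(sub.graph.edges)

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            net.extract_subnetwork(self._graph(), {999})


class TestPowerlawExponent:
    @staticmethod
    def _degrees(exponent, scale=64):
        degs = []
        for d in (1, 2, 4, 8):
            count = int(round(scale * d**exponent))
            degs.extend([d] * count)
        return degs

    def test_exact_inverse_square_table(self):
        assert net.powerlaw_exponent(self._degrees(-2)) == pytest.approx(-2.0, abs=1e-9)

    def test_constructed_minus_one_point_one(self):
        degs = []
        for d in range(1, 11):
            degs.extend([d] * int(round(10000 * d**-1.1)))
        assert net.powerlaw_exponent(degs) == pytest.approx(-1.1, abs=0.02)

    def test_doubling_frequencies_leaves_slope(self):
        degs = self._degrees(-2)
        assert net.powerlaw_exponent(degs) == pytest.approx(
            net.powerlaw_exponent(degs * 2), abs=1e-12
        )

    def test_too_few_distinct_degrees(self):
        with pytest.raises(ValueError):
            net.powerlaw_exponent([2, 2, 3, 3])


def test_planted_central_set_is_better_connected(annotated_graph):
    """Early preferential-attachment nodes (the planted central set) have
    a higher mean degree than the background."""
    graph, truth = annotated_graph
    central = truth.central_nodes
    deg = dict(graph.graph.degree)
    mean_c = np.mean([deg[n] for n in central])
    mean_o = np.mean([deg[n] for n in set(deg) - central])
    assert mean_c > mean_o
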