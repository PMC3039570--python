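"""Ancestor pruning, flux counting, annotated-network nulls, NScores."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sp_stats

from centralprot import goflux as gf
from centralprot import synthetic as syn
from centralprot.network import AnnotatedGraph


def brute_prune(term_set, slim):
    """Transitive-closure oracle: drop terms reachable from another term."""
    def reach(t, acc):
        for p in slim.parents[t]:
            if p not in acc:
                acc.add(p)
                reach(p, acc)
        return acc

    keep = set()
    for t in term_set:
        ancestors_of_others = set()
        for u in term_set:
            if u != t:
                reach(u, ancestors_of_others)
        if t not in ancestors_of_others:
            keep.add(t)
    return keep


class TestPruneAncestors:
    def test_singleton_unchanged(self, slim):
        assert gf.prune_ancestors({"glycolysis"}, slim) == {"glycolysis"}

    def test_direct_parent_removed(self, slim):
        assert gf.prune_ancestors({"glycolysis", "metabolism"}, slim) == {"glycolysis"}
        assert gf.prune_ancestors({"glycolysis", "root"}, slim) == {"glycolysis"}

    def test_sibling_terms_kept(self, slim):
        s = {"glycolysis", "tca", "transport"}
        assert gf.prune_ancestors(s, slim) == s

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(5)
        terms = [f"t{i}" for i in range(12)]
        parents = {
            t: set(rng.choice(terms[:i], size=min(i, int(rng.integers(0, 3))), replace=False))
            for i, t in enumerate(terms)
        }
        slim = gf.GOSlim(parents)
        for _ in range(30):
            k = int(rng.integers(1, 6))
            s = set(rng.choice(terms, size=k, replace=False))
            assert gf.prune_ancestors(s, slim) == brute_prune(s, slim)

    def test_unknown_term_rejected(self, slim):
        with pytest.raises(KeyError):
            gf.prune_ancestors({"nope"}, slim)

    def test_cyclic_ontology_rejected(self):
        with pytest.raises(ValueError):
            gf.GOSlim({"a": {"b"}, "b": {"a"}})


def _edge_graph(terms_u, terms_v):
    G = nx.Graph([("P1", "P2")])
    return AnnotatedGraph(
        graph=G,
        node_terms={"P1": frozenset(terms_u), "P2": frozenset(terms_v)},
    )


class TestFluxCounts:
    def test_worked_example_two_by_three(self):
        counts, report = gf.flux_counts(_edge_graph({"A", "B"}, {"C", "D", "E"}))
        assert counts == {
            ("A", "C"): 1, ("A", "D"): 1, ("A", "E"): 1,
            ("B", "C"): 1, ("B", "D"): 1, ("B", "E"): 1,
        }
        assert report["edges_skipped_unannotated"] == 0

    def test_same_term_pair_counts_once_per_edge(self):
        counts, _ = gf.flux_counts(_edge_graph({"A"}, {"A"}))
        assert counts == {("A", "A"): 1}
        counts, _ = gf.flux_counts(_edge_graph({"A", "B"}, {"A", "B"}))
        assert counts == {("A", "A"): 1, ("A", "B"): 1, ("B", "B"): 1}

    def test_additive_over_edges(self):
        G = nx.Graph([("P1", "P2"), ("P3", "P4")])
        g = AnnotatedGraph(
            graph=G,
            node_terms={
                "P1": frozenset({"A"}), "P2": frozenset({"B"}),
                "P3": frozenset({"A"}), "P4": frozenset({"B"}),
            },
        )
        counts, _ = gf.flux_counts(g)
        assert counts == {("A", "B"): 2}

    def test_unannotated_endpoint_skipped_and_reported(self):
        G = nx.Graph([("P1", "P2"), ("P2", "P3")])
        g = AnnotatedGraph(
            graph=G,
            node_terms={"P1": frozenset({"A"}), "P2": frozenset({"B"})},
        )
        counts, report = gf.flux_counts(g)
        assert counts == {("A", "B"): 1}
        assert report["edges_skipped_unannotated"] == 1

    def test_isolated_annotated_nodes_do_not_change_counts(self):
        g = _edge_graph({"A"}, {"B"})
        base, _ = gf.flux_counts(g)
        g.graph.add_nodes_from(["X", "Y"])
        g.node_terms["X"] = frozenset({"A"})
        g.node_terms["Y"] = frozenset({"B"})
        again, _ = gf.flux_counts(g)
        assert again == base

    def test_pruned_input_is_fixed_point(self, slim):
        g = _edge_graph({"glycolysis", "metabolism"}, {"transport"})
        pruned = AnnotatedGraph(
            graph=g.graph,
            node_terms={
                n: gf.prune_ancestors(t, slim) for n, t in g.node_terms.items()
            },
        )
        c1, _ = gf.flux_counts(pruned)
        twice = AnnotatedGraph(
            graph=pruned.graph,
            node_terms={
                n: gf.prune_ancestors(t, slim) for n, t in pruned.node_terms.items()
            },
        )
        c2, _ = gf.flux_counts(twice)
        assert c1 == c2 == {("glycolysis", "transport"): 1}


class TestRandomizeAnnotated:
    def test_degree_sequence_and_term_frequencies_preserved(self, annotated_graph):
        graph, _ = annotated_graph
        orig_deg = sorted(d for _, d in graph.graph.degree)
        orig_terms = Counter(
            t for s in graph.node_terms.values() for t in s
        )
        orig_sizes = sorted(len(s) for s in graph.node_terms.values())
        for rep in gf.randomize_annotated(graph, n_networks=3, seed=1):
            assert sorted(d for _, d in rep.graph.degree) == orig_deg
            # per-node degrees unchanged, not just the sequence
            assert dict(rep.graph.degree) == dict(graph.graph.degree)
            terms = Counter(t for s in rep.node_terms.values() for t in s)
            assert terms == orig_terms
            assert sorted(len(s) for s in rep.node_terms.values()) == orig_sizes
            assert rep.node_labels == graph.node_labels

    def test_degree_term_size_decoupling(self, annotated_graph):
        graph, _ = annotated_graph
        nodes = list(graph.graph.nodes)
        deg = np.array([graph.graph.degree[n] for n in nodes])
        rhos = []
        for rep in gf.randomize_annotated(graph, n_networks=60, seed=7):
            sizes = np.array([len(rep.terms(n)) for n in nodes])
            rhos.append(sp_stats.spearmanr(deg, sizes).statistic)
        rhos = np.array(rhos)
        se = rhos.std(ddof=1) / np.sqrt(len(rhos))
        assert abs(rhos.mean()) < 3 * max(se, 1e-3)

    def test_determinism_under_seed(self, annotated_graph):
        graph, _ = annotated_graph
        a = next(iter(gf.randomize_annotated(graph, 1, seed=3)))
        b = next(iter(gf.randomize_annotated(graph, 1, seed=3)))
        assert set(a.graph.edges) == set(b.graph.edges)
        assert a.node_terms == b.node_terms


class TestNScores:
    @staticmethod
    def _ensemble(pair, values):
        return [Counter({pair: v}) for v in values]

    def test_nscore_formula(self):
        pair = ("A", "B")
        rng = np.random.default_rng(0)
        vals = rng.normal(50, 5, size=20).round()
        ens = self._ensemble(pair, vals)
        train = np.array(vals[:18])
        mean, sd = train.mean(), train.std(ddof=1)
        res = gf.nscore_fluxes(Counter({pair: mean}), ens)
        assert res.nscore[pair] == pytest.approx(0.0, abs=1e-9)
        res2 = gf.nscore_fluxes(Counter({pair: mean + 2 * sd}), ens)
        assert res2.nscore[pair] == pytest.approx(2.0, abs=1e-9)

    def test_zero_variance_pair_excluded(self):
        pair = ("A", "B")
        ens = self._ensemble(pair, [5.0] * 20)
        other = ("C", "D")
        for i, c in enumerate(ens):
            c[other] = i % 5
        res = gf.nscore_fluxes(Counter({pair: 7}), ens)
        assert pair in res.excluded_pairs
        assert pair not in res.nscore

    def test_small_ensembles_rejected(self):
        with pytest.raises(ValueError):
            gf.nscore_fluxes(Counter(), self._ensemble(("A", "B"), range(5)))

    def test_planted_pair_recovered_at_multiplier_three(self):
        cfg = syn.SyntheticConfig(
            seed=21, n_proteins=250, n_nodes=250, flux_multiplier=3.0
        )
        graph, truth = syn.generate_annotated_interactome(cfg)
        obs, _ = gf.flux_counts(graph)
        res = gf.nscore_fluxes(
            obs, gf.randomize_annotated(graph, 30, seed=2), alpha=0.01
        )
        assert truth.planted_flux_pair in res.significant_pairs
        others = res.significant_pairs - {truth.planted_flux_pair}
        n_eval = len(res.nscore) - 1
        assert len(others) <= 0.01 * n_eval + 3 * np.sqrt(n_eval * 0.01 * 0.99)


class TestFluxRegimes:
    def test_partition_is_disjoint_and_contained(self, annotated_graph):
        graph, truth = annotated_graph
        regimes = gf.partition_regime_edges(graph, truth.central_nodes)
        all_edges = {frozenset(e) for e in graph.graph.edges}
        seen = set()
        for edges in regimes.values():
            fs = {frozenset(e) for e in edges}
            assert fs <= all_edges
            assert not (fs & seen)
            seen |= fs

    def test_central_everything_empties_other_regimes(self, annotated_graph):
        graph, _ = annotated_graph
        regimes = gf.partition_regime_edges(graph, set(graph.graph.nodes))
        assert regimes["boundary"] == [] and regimes["outside"] == []
        with pytest.warns(UserWarning):
            results = gf.flux_regimes(
                graph, central=set(graph.graph.nodes), n_networks=15, seed=0
            )
        assert results["boundary"] is None and results["outside"] is None
        assert results["within"] is not None

    def test_pair_universe_arithmetic(self):
        assert gf.pair_universe_size(50) == 1275
        assert gf.expected_significant(1275, 0.01) == pytest.approx(12.75)
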