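"""GO biological-process "flux" scoring over PPI networks.

A flux between two biological-process (BP) terms counts how often the
pair co-occurs across the two endpoints of protein-protein interaction
edges: for an edge between P1 annotated {A, B} and P2 annotated
{C, D, E} the pairs AC, AD, AE, BC, BD, BE each receive one count, and
counts are summed over all edges.  To avoid re-discovering the GO
hierarchy, each protein's term set is first pruned of terms that are
ancestors of another of its terms.

Raw fluxes depend on term frequencies and node connectivity, so they
are standardized against an ensemble of randomized annotated networks
in which node degrees and term frequencies are preserved individually
but decoupled (degree-preserving edge rewiring plus permutation of
whole term sets across nodes):

    NScore(i, j) = (flux(i, j) - mean_random(i, j)) / sd_random(i, j)

The first 90% of the ensemble provides the null moments; NScores of the
held-out 10% provide the empirical null distribution from which the
significance cutoff (default 1% level) is taken.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .network import AnnotatedGraph

__all__ = [
    "GOSlim",
    "FluxResult",
    "prune_ancestors",
    "flux_counts",
    "randomize_annotated",
    "nscore_fluxes",
    "flux_regimes",
    "pair_universe_size",
    "expected_significant",
]

Pair = tuple[str, str]


class GOSlim:
    """A slim BP vocabulary with is-a parent links (acyclic)."""

    def __init__(
        self,
        parents: dict[str, set[str]],
        term_names: dict[str, str] | None = None,
    ) -> None:
        self.parents = {t: set(p) for t, p in parents.items()}
        for ps in parents.values():
            for p in ps:
                self.parents.setdefault(p, set())
        self.term_names = dict(term_names or {})
        dag = nx.DiGraph(
            (t, p) for t, ps in self.parents.items() for p in ps
        )
        dag.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("is-a parent graph has a cycle")
        self._dag = dag
        self._ancestors: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """All transitive is-a ancestors of ``term`` (excluding itself)."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        if term not in self._ancestors:
            self._ancestors[term] = frozenset(nx.descendants(self._dag, term))
        return self._ancestors[term]

    @classmethod
    def from_parent_table(cls, table: pd.DataFrame) -> "GOSlim":
        """Build from a two-column table (term, parent); empty parent = root."""
        parents: dict[str, set[str]] = {}
        for term, parent in zip(table.iloc[:, 0], table.iloc[:, 1]):
            parents.setdefault(str(term), set())
            if isinstance(parent, str) and parent:
                parents[str(term)].add(parent)
        return cls(parents)

    @classmethod
    def from_obo(cls, path) -> "GOSlim":
        """Load an OBO ontology (is-a edges only) via obonet."""
        import obonet

        g = obonet.read_obo(path)
        parents: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for t, data in g.nodes(data=True):
            parents[t] = set(g.successors(t))
            if "name" in data:
                names[t] = data["name"]
        return cls(parents, names)


def prune_ancestors(term_set, slim: GOSlim) -> frozenset[str]:
    """Remove every term that is an ancestor of another term in the set.

    The result is an antichain of the is-a DAG: only the most specific
    annotations of the protein remain.
    """
    terms = set(term_set)
    shared_ancestors: set[str] = set()
    for t in terms:
        shared_ancestors |= slim.ancestors(t)
    return frozenset(terms - shared_ancestors)


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def flux_counts(graph: AnnotatedGraph) -> tuple[Counter, dict]:
    """Raw BP-pair co-occurrence counts summed over all edges.

    For each edge, every unordered pair from the cross product of the
    endpoints' term sets is incremented by one; a same-term pair (A, A)
    counts once per edge.  Edges with an unannotated endpoint contribute
    nothing and are tallied in the report.
    """
    counts: Counter = Counter()
    skipped = 0
    for u, v in graph.graph.edges:
        tu, tv = graph.terms(u), graph.terms(v)
        if not tu or not tv:
            skipped += 1
            continue
        counts.update({_pair(a, b) for a in tu for b in tv})
    return counts, {"edges_skipped_unannotated": skipped}


def randomize_annotated(
    graph: AnnotatedGraph,
    n_networks: int = 100,
    seed: int | np.random.Generator = 0,
    swap_factor: int = 10,
):
    """Yield randomized annotated networks preserving degrees and term frequencies.

    Each replicate applies (i) degree-preserving double-edge-swap
    rewiring (``swap_factor`` x |edges| accepted swaps), and (ii) a
    uniform permutation of whole node->term-set assignments across
    nodes, which preserves every term's total frequency and the multiset
    of set sizes while decoupling annotation from topology.  Membership
    labels stay on their nodes, whose degrees are unchanged by the
    rewiring.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    nodes = list(graph.graph.nodes)
    term_sets = [graph.terms(n) for n in nodes]
    n_edges = graph.graph.number_of_edges()
    for _ in range(n_networks):
        G = graph.graph.copy()
        if n_edges >= 2:
            nswap = swap_factor * n_edges
            try:
                nx.double_edge_swap(
                    G,
                    nswap=nswap,
                    max_tries=100 * nswap,
                    seed=int(rng.integers(2**31 - 1)),
                )
            except nx.NetworkXException as exc:
                raise RuntimeError(
                    "graph too constrained for degree-preserving rewiring"
                ) from exc
        perm = rng.permutation(len(nodes))
        new_terms = {
            nodes[i]: term_sets[perm[i]]
            for i in range(len(nodes))
            if term_sets[perm[i]]
        }
        yield AnnotatedGraph(
            graph=G,
            node_terms=new_terms,
            node_labels={n: dict(l) for n, l in graph.node_labels.items()},
        )


@dataclass
class FluxResult:
    """Flux counts, null moments, NScores and significance calls."""

    flux: dict[Pair, float]
    mean_random: dict[Pair, float]
    sd_random: dict[Pair, float]
    nscore: dict[Pair, float]
    significance_cutoff: float
    significant_pairs: set[Pair]
    excluded_pairs: set[Pair]  # sd_random == 0
    alpha: float
    n_networks: int

    @property
    def evaluated_pairs(self) -> set[Pair]:
        return set(self.nscore)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair in sorted(set(self.flux) | set(self.mean_random)):
            rows.append(
                {
                    "term_i": pair[0],
                    "term_j": pair[1],
                    "flux": self.flux.get(pair, 0),
                    "mean_random": self.mean_random.get(pair, np.nan),
                    "sd_random": self.sd_random.get(pair, np.nan),
                    "nscore": self.nscore.get(pair, np.nan),
                    "significant": pair in self.significant_pairs,
                }
            )
        return pd.DataFrame(rows)


def nscore_fluxes(
    observed: Counter,
    ensemble,
    alpha: float = 0.01,
    train_frac: float = 0.9,
    cutoff_method: str = "empirical",
) -> FluxResult:
    """Standardize observed fluxes against a randomized ensemble.

    ``ensemble`` is a sequence of flux Counters (or annotated graphs,
    which are counted on the fly).  The first ``train_frac`` of the
    ensemble gives per-pair null means and standard deviations; NScores
    of the held-out remainder, pooled over pairs, give the empirical
    ``1 - alpha`` significance cutoff (``cutoff_method="gaussian"`` fits
    a normal to the held-out scores instead).  Pairs with zero null
    standard deviation are excluded and reported.
    """
    fluxes: list[Counter] = []
    for item in ensemble:
        if isinstance(item, AnnotatedGraph):
            fluxes.append(flux_counts(item)[0])
        else:
            fluxes.append(item)
    n = len(fluxes)
    if n < 12:
        raise ValueError(f"ensemble must have >= 12 networks, got {n}")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 2), n - 1)
    train, held = fluxes[:n_train], fluxes[n_train:]

    universe = set(observed)
    for f in fluxes:
        universe.update(f)
    universe = sorted(universe)

    mat = np.array(
        [[f.get(p, 0) for p in universe] for f in train], dtype=float
    )
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)

    mean_random = dict(zip(universe, mean))
    sd_random = dict(zip(universe, sd))
    defined = sd > 0
    excluded = {p for p, ok in zip(universe, defined) if not ok}

    obs = np.array([observed.get(p, 0) for p in universe], dtype=float)
    nscore = {
        p: float((o - m) / s)
        for p, o, m, s, ok in zip(universe, obs, mean, sd, defined)
        if ok
    }

    held_mat = np.array(
        [[f.get(p, 0) for p in universe] for f in held], dtype=float
    )
    null_scores = ((held_mat - mean) / np.where(defined, sd, np.nan))[
        :, defined
    ].ravel()
    null_scores = null_scores[np.isfinite(null_scores)]
    if null_scores.size == 0:
        raise ValueError("no defined null NScores in held-out networks")
    if cutoff_method == "empirical":
        cutoff = float(np.quantile(null_scores, 1.0 - alpha))
    elif cutoff_method == "gaussian":
        mu, sigma = float(np.mean(null_scores)), float(np.std(null_scores))
        cutoff = float(sp_stats.norm.ppf(1.0 - alpha, loc=mu, scale=sigma))
    else:
        raise ValueError(f"unknown cutoff_method {cutoff_method!r}")

    significant = {p for p, s in nscore.items() if s > cutoff}
    return FluxResult(
        flux={p: float(observed.get(p, 0)) for p in universe},
        mean_random=mean_random,
        sd_random=sd_random,
        nscore=nscore,
        significance_cutoff=cutoff,
        significant_pairs=significant,
        excluded_pairs=excluded,
        alpha=alpha,
        n_networks=n,
    )


def _regime_graph(graph: AnnotatedGraph, edges) -> AnnotatedGraph:
    G = nx.Graph()
    G.add_edges_from(edges)
    keep = set(G.nodes)
    return AnnotatedGraph(
        graph=G,
        node_terms={n: t for n, t in graph.node_terms.items() if n in keep},
        node_labels={n: dict(l) for n, l in graph.node_labels.items() if n in keep},
    )


def partition_regime_edges(
    graph: AnnotatedGraph,
    central: set,
    max_lines_boundary: int = 5,
) -> dict[str, list]:
    """Split edges into the three flux regimes.

    ``within``: both endpoints central; ``boundary``: exactly one
    endpoint central and the other detected in at most
    ``max_lines_boundary`` cell lines; ``outside``: neither endpoint
    central.  The three lists are pairwise disjoint; edges from a
    central node to a non-central node detected in more than
    ``max_lines_boundary`` lines belong to no regime.
    """
    within, boundary, outside = [], [], []
    for u, v in graph.graph.edges:
        cu, cv = u in central, v in central
        if cu and cv:
            within.append((u, v))
        elif cu or cv:
            other = v if cu else u
            nd = graph.n_detected(other)
            if nd is not None and nd <= max_lines_boundary:
                boundary.append((u, v))
        else:
            outside.append((u, v))
    return {"within": within, "boundary": boundary, "outside": outside}


def flux_regimes(
    graph: AnnotatedGraph,
    central: set | None = None,
    n_networks: int = 100,
    seed: int = 0,
    alpha: float = 0.01,
    max_lines_boundary: int = 5,
    swap_factor: int = 10,
) -> dict[str, FluxResult | None]:
    """Run the flux analysis in the three network regimes.

    Each regime (within / boundary / outside the central set, see
    :func:`partition_regime_edges`) gets its own randomized ensemble.
    Empty regimes yield ``None`` with a warning.
    """
    if central is None:
        central = graph.central_nodes
    regimes = partition_regime_edges(graph, central, max_lines_boundary)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(regimes))
    results: dict[str, FluxResult | None] = {}
    for (name, edges), child in zip(regimes.items(), children):
        if not edges:
            warnings.warn(f"regime {name!r} has no edges")
            results[name] = None
            continue
        sub = _regime_graph(graph, edges)
        obs, _ = flux_counts(sub)
        ensemble = randomize_annotated(
            sub,
            n_networks=n_networks,
            seed=np.random.default_rng(child),
            swap_factor=swap_factor,
        )
        results[name] = nscore_fluxes(obs, ensemble, alpha=alpha)
    return results


def pair_universe_size(n_terms: int) -> int:
    """Number of unordered BP pairs including same-term pairs."""
    return n_terms * (n_terms + 1) // 2


def expected_significant(n_pairs: int, alpha: float = 0.01) -> float:
    """Expected significant pairs under the null: alpha x n_pairs."""
    return alpha * n_pairs
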