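"""PPI-network topology profiling.

Five node-level connectivity measures (betweenness, eigenvector
centrality, degree, clustering coefficient, k-core score), shortest-path
distance distributions between protein sets, induced-subgraph
extraction (the "central interactome"), and power-law exponent
estimation from a degree histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedGraph",
    "topology_measures",
    "shortest_path_distribution",
    "extract_subnetwork",
    "powerlaw_exponent",
]


@dataclass
class AnnotatedGraph:
    """Undirected simple PPI graph with per-node BP terms and labels.

    ``node_terms`` maps a node to its (pruned) set of GO biological
    process terms; ``node_labels`` carries membership information such
    as ``central`` (in the central proteome) and ``n_detected`` (number
    of cell lines the protein was detected in).
    """

    graph: nx.Graph
    node_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    node_labels: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.graph, (nx.MultiGraph, nx.DiGraph)):
            raise ValueError("graph must be a simple undirected nx.Graph")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"graph has self-loops: {loops[:3]}")
        for n in self.node_terms:
            if n not in self.graph:
                raise ValueError(f"annotated id {n!r} is not a node")

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def terms(self, node) -> frozenset[str]:
        return self.node_terms.get(node, frozenset())

    @property
    def central_nodes(self) -> set:
        return {
            n for n, lab in self.node_labels.items() if lab.get("central", False)
        }

    def n_detected(self, node) -> int | None:
        return self.node_labels.get(node, {}).get("n_detected")


def topology_measures(
    graph: AnnotatedGraph | nx.Graph,
    normalized_betweenness: bool = False,
) -> pd.DataFrame:
    """All five connectivity measures for every node.

    Betweenness is reported as raw shortest-path counts (with even
    splitting among equal-length paths) by default; pass
    ``normalized_betweenness=True`` for the ratio form.  Eigenvector
    centrality is computed on the largest connected component (with unit
    2-norm scaling) and set to 0 elsewhere, avoiding the degenerate
    multi-component eigenproblem.
    """
    G = graph.graph if isinstance(graph, AnnotatedGraph) else graph
    if G.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = list(G.nodes)
    deg = dict(G.degree)
    btw = nx.betweenness_centrality(G, normalized=normalized_betweenness)
    clust = nx.clustering(G)
    core = nx.core_number(G) if G.number_of_edges() else {n: 0 for n in nodes}

    eig = {n: 0.0 for n in nodes}
    components = sorted(nx.connected_components(G), key=len, reverse=True)
    largest = components[0]
    if len(largest) == 1:
        eig[next(iter(largest))] = 1.0
    elif len(largest) <= 1000:
        # dense principal eigenvector; robust for tiny components where
        # sparse eigensolvers cannot run
        sub_nodes = sorted(largest)
        A = nx.to_numpy_array(G.subgraph(sub_nodes), nodelist=sub_nodes)
        w, v = np.linalg.eigh(A)
        vec = np.abs(v[:, np.argmax(w)])
        vec /= np.linalg.norm(vec)
        for n, x in zip(sub_nodes, vec):
            eig[n] = float(x)
    else:
        sub = G.subgraph(largest)
        vals = nx.eigenvector_centrality_numpy(sub)
        norm = np.sqrt(sum(v * v for v in vals.values()))
        for n, v in vals.items():
            eig[n] = abs(v) / norm

    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "eigenvector": [eig[n] for n in nodes],
            "clustering": [clust[n] for n in nodes],
            "kcore": [core[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def shortest_path_distribution(
    graph: AnnotatedGraph | nx.Graph,
    set_a: set,
    set_b: set,
) -> tuple[dict[int, int], int]:
    """Histogram of shortest-path lengths over unordered cross pairs.

    Counts every unordered pair (a, b) with a in ``set_a``, b in
    ``set_b`` and a != b exactly once.  Returns ``(histogram,
    n_unreachable)`` where unreachable pairs are tallied separately.
    """
    G = graph.graph if isinstance(graph, AnnotatedGraph) else graph
    if not set_a or not set_b:
        raise ValueError("both sets must be nonempty")
    for s in (set_a, set_b):
        unknown = s - set(G.nodes)
        if unknown:
            raise KeyError(f"ids not in graph: {sorted(unknown)[:3]}")
    hist: dict[int, int] = {}
    unreachable = 0
    seen: set[frozenset] = set()
    for a in set_a:
        dist = nx.single_source_shortest_path_length(G, a)
        for b in set_b:
            if a == b:
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            if b in dist:
                d = dist[b]
                hist[d] = hist.get(d, 0) + 1
            else:
                unreachable += 1
    return dict(sorted(hist.items())), unreachable


def extract_subnetwork(graph: AnnotatedGraph, node_set: set) -> AnnotatedGraph:
    """Induced subgraph on ``node_set`` with annotations preserved."""
    unknown = set(node_set) - set(graph.graph.nodes)
    if unknown:
        raise KeyError(f"ids not in graph: {sorted(unknown)[:5]}")
    sub = graph.graph.subgraph(node_set).copy()
    return AnnotatedGraph(
        graph=sub,
        node_terms={n: t for n, t in graph.node_terms.items() if n in node_set},
        node_labels={n: dict(l) for n, l in graph.node_labels.items() if n in node_set},
    )


def powerlaw_exponent(degree_sequence) -> float:
    """OLS slope of log10(frequency) vs log10(degree).

    Zero degrees and empty frequency bins are omitted.  Negative for
    heavy-tailed (scale-free) degree distributions.
    """
    degrees = np.asarray(list(degree_sequence), dtype=float)
    degrees = degrees[degrees > 0]
    vals, counts = np.unique(degrees, return_counts=True)
    if len(vals) < 3:
        raise ValueError(
            f"need >= 3 distinct positive degrees, got {len(vals)}"
        )
    slope, _ = np.polyfit(np.log10(vals), np.log10(counts), 1)
    return float(slope)
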