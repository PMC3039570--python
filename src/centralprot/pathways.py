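"""Relative positions of proteins along pathway graphs.

A node's relative position in a pathway is derived from directed
shortest-path distances: with ``d_s`` the distance from the closest
source (in-degree 0) and ``d_e`` the distance to the closest end node
(out-degree 0), the position is ``d_s / (d_s + d_e)`` so that sources
sit at 0 and end points at 1.  Cyclic pathways are condensed to their
strongly connected components first; every member of a component
inherits the component's position, which guarantees that sources and
ends exist.  A protein occurring at several nodes of a pathway gets the
average of its node positions; occurrences in several pathways are
averaged again (unweighted, two-level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "PathwayGraph",
    "node_relative_positions",
    "protein_positions",
    "positional_profile",
    "REPORT_BINS",
]

#: Figure-style reporting bins: source, center and end of pathways.
REPORT_BINS = {
    "source": (0.0, 0.2),
    "center": (0.4, 0.6),
    "end": (0.8, 1.0),
}


@dataclass
class PathwayGraph:
    """Directed pathway graph with node -> protein assignments.

    One node may carry several proteins (a complex); one protein may
    occur at several nodes.
    """

    pathway_id: str
    graph: nx.DiGraph
    assignments: dict = field(default_factory=dict)  # node -> set of proteins

    def __post_init__(self) -> None:
        for node in self.assignments:
            if node not in self.graph:
                raise ValueError(
                    f"assignment references unknown node {node!r} "
                    f"in pathway {self.pathway_id}"
                )


def node_relative_positions(
    pathway: PathwayGraph,
    all_paths_average: bool = False,
) -> dict:
    """Relative position in [0, 1] for every positionable node.

    By default uses the shortest path to the *closest* source and end.
    With ``all_paths_average=True``, ``d_s`` and ``d_e`` are instead the
    mean shortest-path length over *all* reachable sources/ends — an
    alternative metric that tracks the default closely.

    Nodes isolated from all sources and all ends are excluded with a
    warning.
    """
    G = pathway.graph
    cond = nx.condensation(G)  # DAG of strongly connected components
    sources = [c for c in cond.nodes if cond.in_degree(c) == 0]
    ends = [c for c in cond.nodes if cond.out_degree(c) == 0]

    if all_paths_average:
        fwd = {s: nx.single_source_shortest_path_length(cond, s) for s in sources}
        rev_g = cond.reverse(copy=False)
        bwd = {e: nx.single_source_shortest_path_length(rev_g, e) for e in ends}
        d_s, d_e = {}, {}
        for c in cond.nodes:
            ds_vals = [d[c] for d in fwd.values() if c in d]
            de_vals = [d[c] for d in bwd.values() if c in d]
            if ds_vals:
                d_s[c] = float(np.mean(ds_vals))
            if de_vals:
                d_e[c] = float(np.mean(de_vals))
    else:
        d_s = nx.multi_source_dijkstra_path_length(cond, sources, weight=None)
        d_e = nx.multi_source_dijkstra_path_length(
            cond.reverse(copy=False), ends, weight=None
        )

    positions: dict = {}
    skipped = []
    comp_pos: dict = {}
    for c in cond.nodes:
        if c not in d_s and c not in d_e:
            skipped.append(c)
            continue
        ds = d_s.get(c)
        de = d_e.get(c)
        if ds is None:
            comp_pos[c] = 1.0  # reaches ends only: treat as terminal
        elif de is None:
            comp_pos[c] = 0.0  # reachable from sources only
        elif ds == 0 and de == 0:
            comp_pos[c] = 0.5  # isolated single-node component
        else:
            comp_pos[c] = ds / (ds + de)
    if skipped:
        warnings.warn(
            f"pathway {pathway.pathway_id}: {len(skipped)} component(s) "
            "isolated from all sources and ends were excluded"
        )
    for node, comp in cond.graph["mapping"].items():
        if comp in comp_pos:
            positions[node] = comp_pos[comp]
    return positions


def protein_positions(
    pathways: list[PathwayGraph],
    all_paths_average: bool = False,
) -> dict:
    """Two-level averaged relative position per protein.

    Within each pathway the positions of all nodes carrying the protein
    are averaged; the per-pathway means are then averaged across
    pathways.  Proteins assigned to no positionable node are absent
    from the result.
    """
    per_protein: dict[str, list[float]] = {}
    for pw in pathways:
        node_pos = node_relative_positions(pw, all_paths_average=all_paths_average)
        in_this: dict[str, list[float]] = {}
        for node, proteins in pw.assignments.items():
            if node not in node_pos:
                continue
            for p in proteins:
                in_this.setdefault(p, []).append(node_pos[node])
        for p, vals in in_this.items():
            per_protein.setdefault(p, []).append(float(np.mean(vals)))
    return {p: float(np.mean(v)) for p, v in per_protein.items()}


def positional_profile(
    positions: dict,
    protein_sets: dict[str, set],
    n_bins: int = 5,
) -> dict:
    """Histograms of positions per protein set plus report-bin members.

    Returns per set a dict with ``histogram`` (counts over ``n_bins``
    equal-width bins on [0, 1]), ``bin_edges`` and ``bins`` — the
    membership lists of the source (0–0.2), center (0.4–0.6) and end
    (0.8–1) report bins.
    """
    if not protein_sets:
        raise ValueError("protein_sets must be nonempty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out: dict = {}
    for name, members in protein_sets.items():
        vals = np.array([positions[p] for p in members if p in positions])
        hist, _ = np.histogram(vals, bins=edges)
        bins = {}
        for bname, (lo, hi) in REPORT_BINS.items():
            if lo == 0.0:
                sel = {
                    p for p in members
                    if p in positions and lo <= positions[p] <= hi
                }
            else:
                sel = {
                    p for p in members
                    if p in positions and lo < positions[p] <= hi
                }
            bins[bname] = sel
        out[name] = {"histogram": hist, "bin_edges": edges, "bins": bins}
    return out
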