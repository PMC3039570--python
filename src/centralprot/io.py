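"""Readers and writers for the pipeline's file formats.

All formats are plain text: FASTA for sequence collections, TSV for PSM
tables, protein groups, abundance values, annotations and pathways,
GraphML/edge-list TSV for networks, GMT for protein-set partitions and
JSON for ground truth and reports.  Every writer is deterministic, so
identical in-memory objects produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .inference import PSM_COLUMNS, ProteinGroup
from .network import AnnotatedGraph
from .pathways import PathwayGraph

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_psm_table",
    "read_psm_table",
    "write_groups",
    "read_groups",
    "write_graph",
    "read_graph",
    "write_edge_list",
    "read_edge_list",
    "write_annotations",
    "read_annotations",
    "write_pathways",
    "read_pathways",
    "write_gmt",
    "write_json",
    "read_json",
]


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in sorted(sequences.items())
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _ids_to_str(value) -> str:
    if isinstance(value, str):
        return value
    return ";".join(sorted(value))


def write_psm_table(psms: pd.DataFrame, path) -> None:
    out = psms.copy()
    out["protein_ids"] = out["protein_ids"].map(_ids_to_str)
    out.to_csv(path, sep="\t", index=False, columns=PSM_COLUMNS)


def read_psm_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "peptide": str})
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def write_groups(groups: list[ProteinGroup], path) -> None:
    rows = []
    for i, g in enumerate(sorted(groups, key=lambda g: g.sort_key)):
        rows.append(
            {
                "group_id": f"G{i:05d}",
                "members": ";".join(sorted(g.member_ids)),
                "gene": ";".join(sorted(g.gene_ids)),
                "n_peptides": len(g.peptides),
                "n_specific": len(g.specific_peptides),
                "peptides": ";".join(sorted(g.peptides)),
                "specific_peptides": ";".join(sorted(g.specific_peptides)),
                "coverage": g.coverage,
                "is_decoy": g.is_decoy,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_groups(path) -> list[ProteinGroup]:
    df = pd.read_csv(path, sep="\t")
    groups = []
    for row in df.itertuples(index=False):
        groups.append(
            ProteinGroup(
                member_ids=frozenset(row.members.split(";")),
                peptides=frozenset(
                    row.peptides.split(";") if isinstance(row.peptides, str) else []
                ),
                specific_peptides=frozenset(
                    row.specific_peptides.split(";")
                    if isinstance(row.specific_peptides, str)
                    else []
                ),
                gene_ids=frozenset(
                    row.gene.split(";") if isinstance(row.gene, str) else []
                ),
                coverage=float(row.coverage),
                is_decoy=bool(row.is_decoy),
            )
        )
    return groups


def write_graph(graph: AnnotatedGraph, path) -> None:
    """GraphML with terms as a ';'-joined node attribute."""
    G = nx.Graph()
    G.add_nodes_from(sorted(graph.graph.nodes))
    G.add_edges_from(sorted(tuple(sorted(e)) for e in graph.graph.edges))
    for n in G.nodes:
        G.nodes[n]["terms"] = ";".join(sorted(graph.terms(n)))
        lab = graph.node_labels.get(n, {})
        G.nodes[n]["central"] = bool(lab.get("central", False))
        if "n_detected" in lab:
            G.nodes[n]["n_detected"] = int(lab["n_detected"])
    nx.write_graphml(G, path)


def read_graph(path) -> AnnotatedGraph:
    G = nx.read_graphml(str(path))
    terms = {}
    labels = {}
    for n, data in G.nodes(data=True):
        t = data.pop("terms", "")
        if t:
            terms[n] = frozenset(t.split(";"))
        lab = {}
        if "central" in data:
            lab["central"] = bool(data.pop("central"))
        if "n_detected" in data:
            lab["n_detected"] = int(data.pop("n_detected"))
        if lab:
            labels[n] = lab
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    H.add_edges_from(G.edges)
    return AnnotatedGraph(graph=H, node_terms=terms, node_labels=labels)


def write_edge_list(graph: AnnotatedGraph | nx.Graph, path) -> None:
    G = graph.graph if isinstance(graph, AnnotatedGraph) else graph
    edges = sorted(tuple(sorted(map(str, e))) for e in G.edges)
    pd.DataFrame(edges, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    G = nx.Graph()
    G.add_edges_from(df.itertuples(index=False, name=None))
    return G


def write_annotations(node_terms: dict, path) -> None:
    rows = [
        {"protein": n, "term": t}
        for n in sorted(node_terms)
        for t in sorted(node_terms[n])
    ]
    pd.DataFrame(rows, columns=["protein", "term"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path) -> dict[str, frozenset]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set] = {}
    for protein, term in df.itertuples(index=False, name=None):
        out.setdefault(protein, set()).add(term)
    return {p: frozenset(t) for p, t in out.items()}


def write_pathways(pathways: list[PathwayGraph], edges_path, assign_path) -> None:
    edge_rows, assign_rows = [], []
    for pw in pathways:
        for u, v in sorted(pw.graph.edges):
            edge_rows.append({"pathway_id": pw.pathway_id, "src_node": u, "dst_node": v})
        for node in sorted(pw.assignments):
            for p in sorted(pw.assignments[node]):
                assign_rows.append(
                    {"pathway_id": pw.pathway_id, "node": node, "protein": p}
                )
    pd.DataFrame(edge_rows, columns=["pathway_id", "src_node", "dst_node"]).to_csv(
        edges_path, sep="\t", index=False
    )
    pd.DataFrame(assign_rows, columns=["pathway_id", "node", "protein"]).to_csv(
        assign_path, sep="\t", index=False
    )


def read_pathways(edges_path, assign_path) -> list[PathwayGraph]:
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    assigns = pd.read_csv(assign_path, sep="\t", dtype=str)
    out = []
    for pid in sorted(edges["pathway_id"].unique()):
        G = nx.DiGraph()
        sub = edges[edges["pathway_id"] == pid]
        G.add_edges_from(zip(sub["src_node"], sub["dst_node"]))
        asub = assigns[assigns["pathway_id"] == pid]
        assignments: dict[str, set] = {}
        for node, prot in zip(asub["node"], asub["protein"]):
            G.add_node(node)
            assignments.setdefault(node, set()).add(prot)
        out.append(PathwayGraph(pathway_id=pid, graph=G, assignments=assignments))
    return out


def write_gmt(sets: dict[str, set], path, description: str = "centralprot") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_JSONEncoder) + "\n"
    )


def read_json(path):
    return json.loads(Path(path).read_text())
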