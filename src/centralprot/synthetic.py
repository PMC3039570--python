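"""Synthetic inputs with known ground truth for every pipeline stage.

Generates a random proteome (tryptic-friendly sequences), per-cell-line
PSM tables for two search engines with Gaussian target/decoy score
distributions and a planted commonly-expressed protein subset,
scale-free annotated interactomes with an optionally enriched BP-term
pair, source-to-sink pathway DAGs, and feature tables with planted
exon-count/ortholog shifts.  All generation is deterministic under the
configuration seed (independent sub-streams are spawned per artifact),
so one seed fixes every output byte-exactly.

The defaults describe the emulated study: 7 cell lines, a ~30% common
subset of a 1,000-protein search space, two engines with an
ion-score-like and a z-score-like scale, a preferential-attachment
interactome (scale-free degree distribution), and a +3.7 planted
exon-count shift for the common set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .abundance import tryptic_peptides
from .goflux import flux_counts
from .inference import PSM_COLUMNS
from .network import AnnotatedGraph
from .pathways import PathwayGraph

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_proteome",
    "generate_psm_tables",
    "generate_annotated_interactome",
    "generate_pathways",
    "generate_feature_table",
]

# amino acids without K/R (cleavage sites) for peptide interiors
_INTERIOR_AA = np.array(list("ACDEFGHILMNQSTVWY"))
_INTERIOR_NO_G = np.array(list("ACDEFHILMNQSTVWY"))


@dataclass
class SyntheticConfig:
    """Parameters of every synthetic artifact; one seed drives them all."""

    seed: int = 0
    # proteome / PSMs
    n_proteins: int = 1000
    n_cell_lines: int = 7
    frac_common: float = 0.3
    peptides_per_protein: tuple[int, int] = (12, 25)
    share_rate: float = 0.05  # fraction of proteins borrowing a peptide
    true_psms_per_protein: int = 4
    false_match_rate: float = 0.1
    conflict_rate: float = 0.02
    target_score_params: dict = field(
        default_factory=lambda: {"A": (30.0, 7.0), "B": (6.5, 1.2)}
    )
    decoy_score_params: dict = field(
        default_factory=lambda: {"A": (10.0, 5.0), "B": (2.5, 1.0)}
    )
    # interactome
    n_nodes: int = 1000
    attachment_m: int = 3
    n_bp_terms: int = 30
    terms_per_node: tuple[int, int] = (1, 4)
    planted_flux_pair: tuple[str, str] | None = None
    flux_multiplier: float = 1.0
    # pathways
    pathway_sizes: list[int] = field(default_factory=lambda: [8, 12, 20])
    extra_edge_prob: float = 0.25
    # feature table
    planted_exon_shift: float = 3.7
    planted_ortholog_shift: float = 5.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_common <= 1.0:
            raise ValueError("frac_common must be in [0, 1]")
        for name in (
            "n_proteins",
            "n_cell_lines",
            "n_nodes",
            "attachment_m",
            "n_bp_terms",
            "true_psms_per_protein",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # independent deterministic sub-streams per artifact
    def rng(self, artifact: str) -> np.random.Generator:
        labels = ["proteome", "psms", "interactome", "pathways", "features"]
        ss = np.random.SeedSequence(self.seed).spawn(len(labels))
        return np.random.default_rng(ss[labels.index(artifact)])

    @property
    def bp_terms(self) -> list[str]:
        return [f"BP{i:03d}" for i in range(self.n_bp_terms)]


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage."""

    common_set: set[str] = field(default_factory=set)
    expressed: dict[str, set[str]] = field(default_factory=dict)
    # per-PSM truth: cell_line, engine, spectrum_id, is_false_match, is_decoy_db
    decoy_labels: pd.DataFrame | None = None
    planted_flux_pair: tuple[str, str] | None = None
    flux_multiplier: float = 1.0
    central_nodes: set[str] = field(default_factory=set)
    planted_shift: float = 0.0


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def generate_proteome(config: SyntheticConfig) -> dict[str, str]:
    """Random protein sequences built from tryptic segments.

    Every protein is a concatenation of segments ending in K/R with
    non-K/R interiors (and no leading proline), so tryptic digestion
    recovers the segments exactly; each protein carries one anchor
    segment of 10 residues whose mass is guaranteed to fall in the
    default instrument mass range.
    """
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1 (empty collection)")
    rng = config.rng("proteome")
    lo, hi = config.peptides_per_protein
    proteome: dict[str, str] = {}
    for i in range(config.n_proteins):
        n_seg = int(rng.integers(lo, hi + 1))
        segments = []
        for j in range(n_seg):
            if j == 0:  # anchor peptide: 9 interior (no G) + K/R, mass in range
                interior = rng.choice(_INTERIOR_NO_G, size=9)
            else:
                length = int(rng.integers(6, 21))
                interior = rng.choice(_INTERIOR_AA, size=length - 1)
            if interior[0] == "P":
                interior[0] = "A"
            term = "K" if rng.random() < 0.5 else "R"
            segments.append("".join(interior) + term)
        proteome[_protein_id(i)] = "".join(segments)

    # shared-peptide structure: a fraction of proteins borrow a segment
    ids = list(proteome)
    n_share = int(round(config.share_rate * config.n_proteins))
    if n_share and config.n_proteins > 1:
        borrowers = rng.choice(config.n_proteins, size=n_share, replace=False)
        for b in borrowers:
            donor = int(rng.integers(config.n_proteins - 1))
            if donor >= b:
                donor += 1
            donor_peps = sorted(tryptic_peptides(proteome[ids[donor]], 0, 6))
            if not donor_peps:
                continue
            pep = donor_peps[int(rng.integers(len(donor_peps)))]
            if not pep.endswith(("K", "R")):
                pep += "K"
            proteome[ids[b]] = proteome[ids[b]] + pep
    return proteome


def decoy_sequences(proteome: dict[str, str]) -> dict[str, str]:
    """Reverse-sequence decoy analogue of the proteome."""
    return {f"DECOY_{pid}": seq[::-1] for pid, seq in proteome.items()}


def generate_psm_tables(
    proteome: dict[str, str], config: SyntheticConfig
) -> tuple[dict[tuple[str, str], pd.DataFrame], GroundTruth]:
    """Per-cell-line, per-engine PSM tables with planted truth.

    True matches draw scores from ``target_score_params``; false matches
    draw from ``decoy_score_params`` and hit either a reversed-sequence
    decoy protein (flagged ``is_decoy``) or a random target protein,
    with equal probability — the standard target/decoy symmetry
    assumption.  Proteins of the planted common set receive PSMs in
    every cell line; a ``conflict_rate`` fraction of true spectra get a
    different peptide from engine B (discarded on merge).
    """
    if not proteome:
        raise ValueError("proteome must be nonempty")
    rng = config.rng("psms")
    ids = sorted(proteome)
    n = len(ids)
    n_common = int(round(config.frac_common * n))
    if config.frac_common > 0 and n_common < 1:
        warnings.warn("frac_common * n_proteins < 1: common set is empty")
    common = (
        {str(p) for p in rng.choice(ids, size=n_common, replace=False)}
        if n_common
        else set()
    )

    # digest once; build peptide -> proteins index for protein_ids fields
    digests = {pid: sorted(tryptic_peptides(proteome[pid], 0, 6)) for pid in ids}
    pep_index: dict[str, set[str]] = {}
    for pid, peps in digests.items():
        for pep in peps:
            pep_index.setdefault(pep, set()).add(pid)

    cell_lines = [f"CL{i + 1}" for i in range(config.n_cell_lines)]
    expressed: dict[str, set[str]] = {cl: set(common) for cl in cell_lines}
    for pid in ids:
        if pid in common:
            continue
        k = int(rng.integers(1, config.n_cell_lines))  # 1 .. n_lines - 1
        for cl in rng.choice(cell_lines, size=k, replace=False):
            expressed[str(cl)].add(pid)

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    truth_rows = []
    for cl in cell_lines:
        rows_a, rows_b = [], []
        sid = 0
        for pid in sorted(expressed[cl]):
            peps = digests[pid]
            # distinct peptides per protein: several distinct tryptic
            # peptides per identified protein, as in real runs
            n_draw = min(config.true_psms_per_protein, len(peps))
            chosen = rng.choice(len(peps), size=n_draw, replace=False)
            for ci in chosen:
                pep = peps[int(ci)]
                spectrum = f"{cl}:S{sid:06d}"
                sid += 1
                score_a = rng.normal(*config.target_score_params["A"])
                score_b = rng.normal(*config.target_score_params["B"])
                pep_b = pep
                conflict = rng.random() < config.conflict_rate
                if conflict:
                    other = ids[int(rng.integers(n))]
                    alts = [q for q in digests[other] if q != pep]
                    if alts:
                        pep_b = alts[int(rng.integers(len(alts)))]
                rows_a.append(
                    (spectrum, cl, "A", pep, score_a, np.nan,
                     ";".join(sorted(pep_index[pep])), False)
                )
                rows_b.append(
                    (spectrum, cl, "B", pep_b, score_b,
                     float(sp_stats.norm.sf(score_b)),
                     ";".join(sorted(pep_index.get(pep_b, {pid}))), False)
                )
                truth_rows.append((cl, spectrum, False, False))
        n_true = sid
        n_false = int(round(config.false_match_rate * n_true))
        for _ in range(n_false):
            spectrum = f"{cl}:S{sid:06d}"
            sid += 1
            src = ids[int(rng.integers(n))]
            pep = digests[src][int(rng.integers(len(digests[src])))]
            engine = "A" if rng.random() < 0.5 else "B"
            is_decoy = bool(rng.random() < 0.5)
            if is_decoy:
                pep_out = pep[::-1]
                prot_ids = f"DECOY_{src}"
            else:
                pep_out = pep
                prot_ids = ";".join(sorted(pep_index[pep]))
            score = rng.normal(*config.decoy_score_params[engine])
            pval = (
                float(sp_stats.norm.sf(score)) if engine == "B" else np.nan
            )
            row = (spectrum, cl, engine, pep_out, score, pval, prot_ids, is_decoy)
            (rows_a if engine == "A" else rows_b).append(row)
            truth_rows.append((cl, spectrum, True, is_decoy))
        tables[(cl, "A")] = pd.DataFrame(rows_a, columns=PSM_COLUMNS)
        tables[(cl, "B")] = pd.DataFrame(rows_b, columns=PSM_COLUMNS)

    truth = GroundTruth(
        common_set=common,
        expressed=expressed,
        decoy_labels=pd.DataFrame(
            truth_rows,
            columns=["cell_line", "spectrum_id", "is_false_match", "is_decoy_db"],
        ),
    )
    return tables, truth


def generate_annotated_interactome(
    config: SyntheticConfig,
) -> tuple[AnnotatedGraph, GroundTruth]:
    """Scale-free annotated interactome with an optionally planted flux pair.

    The graph grows by preferential attachment (heavy-tailed degrees);
    the planted central set occupies the earliest — hence best-connected
    — nodes.  Nodes carry 1–4 BP terms from a Zipf-like frequency
    vector.  If a flux pair with multiplier > 1 is requested, extra
    edges between carriers of the two terms are added until the pair's
    flux reaches multiplier x its baseline count.
    """
    if config.n_nodes < config.n_bp_terms or config.n_bp_terms < 2:
        raise ValueError("need n_nodes >= n_bp_terms >= 2")
    rng = config.rng("interactome")
    G0 = nx.barabasi_albert_graph(
        config.n_nodes, config.attachment_m, seed=int(rng.integers(2**31 - 1))
    )
    ids = [_protein_id(i) for i in range(config.n_nodes)]
    G = nx.relabel_nodes(G0, dict(enumerate(ids)))

    n_central = int(round(config.frac_common * config.n_nodes))
    central = set(ids[:n_central])
    labels = {}
    for pid in ids:
        if pid in central:
            labels[pid] = {"central": True, "n_detected": config.n_cell_lines}
        else:
            labels[pid] = {
                "central": False,
                "n_detected": int(rng.integers(1, config.n_cell_lines)),
            }

    terms = config.bp_terms
    freq = 1.0 / np.arange(1, len(terms) + 1)
    freq /= freq.sum()
    lo, hi = config.terms_per_node
    node_terms = {}
    for pid in ids:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False, p=freq)
        node_terms[pid] = frozenset(terms[i] for i in chosen)

    graph = AnnotatedGraph(graph=G, node_terms=node_terms, node_labels=labels)

    pair = config.planted_flux_pair
    if pair is None:
        # moderately frequent terms so the enriched signal is non-degenerate
        pair = (terms[min(2, len(terms) - 2)], terms[min(4, len(terms) - 1)])
    pair = tuple(sorted(pair))
    if config.flux_multiplier > 1.0:
        counts, _ = flux_counts(graph)
        baseline = counts.get(pair, 0)
        target = int(round(config.flux_multiplier * max(baseline, 1)))
        carriers_i = [p for p in ids if pair[0] in node_terms[p]]
        carriers_j = [p for p in ids if pair[1] in node_terms[p]]
        candidates = [
            (u, v)
            for u in carriers_i
            for v in carriers_j
            if u != v and not G.has_edge(u, v)
        ]
        rng.shuffle(candidates)
        current = baseline
        while current < target:
            if not candidates:
                raise ValueError(
                    "planted flux edges exceed simple-graph capacity"
                )
            u, v = candidates.pop()
            if G.has_edge(u, v):
                continue
            G.add_edge(u, v)
            extra, _ = flux_counts(
                AnnotatedGraph(
                    graph=nx.Graph([(u, v)]),
                    node_terms={u: node_terms[u], v: node_terms[v]},
                )
            )
            current += extra.get(pair, 0)

    truth = GroundTruth(
        planted_flux_pair=pair,
        flux_multiplier=config.flux_multiplier,
        central_nodes=central,
    )
    return graph, truth


def generate_pathways(
    config: SyntheticConfig, protein_ids: list[str] | None = None
) -> list[PathwayGraph]:
    """Connected source-to-sink pathway DAGs with protein assignments.

    Each pathway of size ``s`` is built on a topological order: every
    node links back to a random earlier node (guaranteeing
    connectivity, at least one source and one end) and extra forward
    edges are added with probability ``extra_edge_prob``.  Node->protein
    assignments are drawn from a shared pool so proteins repeat across
    pathways.
    """
    rng = config.rng("pathways")
    if protein_ids is None:
        protein_ids = [_protein_id(i) for i in range(max(config.n_proteins, 1))]
    pool = list(
        rng.choice(
            protein_ids,
            size=min(len(protein_ids), max(10, 2 * max(config.pathway_sizes, default=2))),
            replace=False,
        )
    )
    pathways = []
    for k, size in enumerate(config.pathway_sizes):
        if size < 2:
            raise ValueError(f"pathway size must be >= 2, got {size}")
        G = nx.DiGraph()
        G.add_nodes_from(range(size))
        for j in range(1, size):
            G.add_edge(int(rng.integers(j)), j)
        for i in range(size):
            for j in range(i + 1, size):
                if not G.has_edge(i, j) and rng.random() < config.extra_edge_prob:
                    G.add_edge(i, j)
        assignments = {}
        for node in range(size):
            n_prot = 1 + int(rng.random() < 0.2)  # occasional complex node
            assignments[node] = {
                pool[int(rng.integers(len(pool)))] for _ in range(n_prot)
            }
        nid = {i: f"pw{k}:n{i}" for i in range(size)}
        pathways.append(
            PathwayGraph(
                pathway_id=f"pw{k}",
                graph=nx.relabel_nodes(G, nid),
                assignments={nid[i]: prots for i, prots in assignments.items()},
            )
        )
    return pathways


def generate_feature_table(
    proteome: dict[str, str],
    config: SyntheticConfig,
    target_set: set[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-protein features with planted shifts for the target set.

    Exon counts follow a length-dependent Poisson baseline; proteins of
    the target set (default: the first ``frac_common`` fraction) receive
    an extra Poisson(``planted_exon_shift``) exon count and
    Poisson(``planted_ortholog_shift``) ortholog species, so the planted
    mean shifts equal the configured values over and above any
    length-matched background.
    """
    rng = config.rng("features")
    ids = sorted(proteome)
    if target_set is None:
        target_set = set(ids[: int(round(config.frac_common * len(ids)))])
    lengths = np.array([len(proteome[p]) for p in ids])
    base_exons = 1 + rng.poisson(2.0 + lengths / 150.0)
    base_orth = rng.poisson(12.0, size=len(ids))
    in_target = np.array([p in target_set for p in ids])
    exons = base_exons + np.where(
        in_target, rng.poisson(config.planted_exon_shift, size=len(ids)), 0
    )
    orth = base_orth + np.where(
        in_target, rng.poisson(config.planted_ortholog_shift, size=len(ids)), 0
    )
    table = pd.DataFrame(
        {
            "protein": ids,
            "sequence_length": lengths,
            "exon_count": exons,
            "ortholog_species": orth,
        }
    )
    truth = GroundTruth(
        common_set=set(target_set), planted_shift=config.planted_exon_shift
    )
    return table, truth
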