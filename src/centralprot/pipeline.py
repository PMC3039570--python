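"""End-to-end orchestration of the analysis stages.

Stages run in dependency order: ``synth`` (generate all inputs) →
``infer`` (two-engine protein inference with FDR calibration) →
``abundance`` (emPAI, central proteome, abundance classes) →
``topology`` (network measures, power-law exponents, distance
distributions) → ``pathpos`` (relative pathway positions) → ``goflux``
(BP-flux regimes against randomized networks) → ``compare``
(length-matched shifts, set association, distribution comparison).
A stage re-executes only when an output is missing or an input is newer;
all randomness flows through per-stage seeds derived from the run seed,
so re-running an unchanged configuration reproduces every output
byte-exactly.  A machine-readable report (per-stage status, parameter
echo, file checksums and headline numbers) is written even on failure.
"""

from __future__ import annotations

import hashlib
import time
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import goflux as gf
from . import inference as inf
from . import io as cio
from . import network as net
from . import pathways as pw
from . import stats as cstats
from . import synthetic as syn

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ["synth", "infer", "abundance", "topology", "pathpos", "goflux", "compare"]

DEFAULT_FDR_GRID = [
    {"A_primary_score": 14.0, "A_additional_score": 8.0, "A_sph_score": 40.0,
     "B_primary_z": 3.5, "B_additional_z": 2.5, "B_sph_z": 5.0},
    {"A_primary_score": 16.0, "A_additional_score": 9.0, "A_sph_score": 45.0,
     "B_primary_z": 4.0, "B_additional_z": 3.0, "B_sph_z": 5.5},
    {},  # the default working point (18/10/50, 4.5/3.5/6)
    {"A_primary_score": 20.0, "A_additional_score": 11.0, "A_sph_score": 55.0,
     "B_primary_z": 5.0, "B_additional_z": 4.0, "B_sph_z": 6.5},
    {"A_primary_score": 22.0, "A_additional_score": 12.0, "A_sph_score": 60.0,
     "B_primary_z": 5.5, "B_additional_z": 4.5, "B_sph_z": 7.0},
]


@dataclass
class RunConfig:
    """One configuration file drives every stage."""

    out_dir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    fdr_grid: list[dict] = field(default_factory=lambda: [dict(d) for d in DEFAULT_FDR_GRID])
    group_fdr_max: float = 0.0025
    quantile: float = 0.25
    required_lines: int | None = None  # None = all cell lines
    n_random: int = 30
    alpha: float = 0.01
    force: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        allowed = set(cls.__dataclass_fields__)
        bad = set(data) - allowed
        if bad:
            raise ValueError(f"invalid config keys: {sorted(bad)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def synth_config(self) -> syn.SyntheticConfig:
        params = dict(self.synthetic)
        params.setdefault("seed", self.seed)
        return syn.SyntheticConfig(**params)

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, STAGES.index(stage)]).generate_state(1)[0]
            % (2**31 - 1)
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    def __init__(self, config: RunConfig, name: str):
        self.config = config
        self.name = name
        self.dir = config.out_dir / name
        self.info: dict = {"status": "pending", "outputs": {}, "headline": {}}

    def path(self, *parts) -> Path:
        return self.dir.joinpath(*parts)


def _fresh(outputs: list[Path], inputs: list[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    out_oldest = min(p.stat().st_mtime for p in outputs)
    in_newest = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    return in_newest <= out_oldest


def _paths(cfg: RunConfig) -> dict:
    """Canonical file layout of one run."""
    scfg = cfg.synth_config()
    lines = [f"CL{i + 1}" for i in range(scfg.n_cell_lines)]
    o = cfg.out_dir
    p = {
        "cell_lines": lines,
        "fasta": o / "synth" / "proteome.fasta",
        "gene_map": o / "synth" / "gene_map.tsv",
        "interactome": o / "synth" / "interactome.graphml",
        "pathway_edges": o / "synth" / "pathway_edges.tsv",
        "pathway_assign": o / "synth" / "pathway_assignments.tsv",
        "features": o / "synth" / "features.tsv",
        "drug_targets": o / "synth" / "drug_targets.tsv",
        "ground_truth": o / "synth" / "ground_truth.json",
        "calibration": o / "infer" / "calibration.json",
        "abundance": o / "abundance" / "abundance.tsv",
        "central": o / "abundance" / "central.txt",
        "classes": o / "abundance" / "classes.gmt",
        "topology": o / "topology" / "topology.tsv",
        "net_summary": o / "topology" / "network_summary.json",
        "positions": o / "pathpos" / "positions.tsv",
        "profile": o / "pathpos" / "profile.json",
        "goflux_summary": o / "goflux" / "goflux_summary.json",
        "compare": o / "compare" / "compare.json",
    }
    p["psms"] = {
        (cl, eng): o / "synth" / f"psms_{cl}_{eng}.tsv"
        for cl in lines
        for eng in ("A", "B")
    }
    p["groups"] = {cl: o / "infer" / f"groups_{cl}.tsv" for cl in lines}
    p["flux"] = {
        reg: o / "goflux" / f"flux_{reg}.tsv"
        for reg in ("within", "boundary", "outside")
    }
    return p


# ---------------------------------------------------------------- stages


def _stage_synth(cfg: RunConfig, p: dict) -> dict:
    scfg = cfg.synth_config()
    proteome = syn.generate_proteome(scfg)
    sequences = dict(proteome)
    sequences.update(syn.decoy_sequences(proteome))
    cio.write_fasta(sequences, p["fasta"])

    gene_map = pd.DataFrame(
        {"protein": sorted(sequences), "gene": [f"G_{pid}" for pid in sorted(sequences)]}
    )
    gene_map.to_csv(p["gene_map"], sep="\t", index=False)

    tables, truth = syn.generate_psm_tables(proteome, scfg)
    for key, table in tables.items():
        cio.write_psm_table(table, p["psms"][key])

    graph, net_truth = syn.generate_annotated_interactome(scfg)
    cio.write_graph(graph, p["interactome"])

    pathways = syn.generate_pathways(scfg, protein_ids=sorted(proteome))
    cio.write_pathways(pathways, p["pathway_edges"], p["pathway_assign"])

    features, feat_truth = syn.generate_feature_table(
        proteome, scfg, target_set=truth.common_set
    )
    features.to_csv(p["features"], sep="\t", index=False)

    # drug-target-like labels enriched in the planted common set
    rng = np.random.default_rng(cfg.stage_seed("synth"))
    ids = sorted(proteome)
    prob = np.array([0.15 if pid in truth.common_set else 0.04 for pid in ids])
    targets = [pid for pid, r in zip(ids, rng.random(len(ids))) if r < prob[ids.index(pid)]]
    pd.DataFrame({"protein": targets}).to_csv(p["drug_targets"], sep="\t", index=False)

    cio.write_json(
        {
            "common_set": truth.common_set,
            "expressed": {cl: s for cl, s in truth.expressed.items()},
            "planted_flux_pair": net_truth.planted_flux_pair,
            "flux_multiplier": net_truth.flux_multiplier,
            "central_nodes": net_truth.central_nodes,
            "planted_exon_shift": feat_truth.planted_shift,
            "decoy_labels": truth.decoy_labels,
        },
        p["ground_truth"],
    )
    return {
        "n_proteins": len(proteome),
        "n_cell_lines": scfg.n_cell_lines,
        "n_common_planted": len(truth.common_set),
        "n_psm_rows": int(sum(len(t) for t in tables.values())),
        "n_nodes": graph.graph.number_of_nodes(),
        "n_edges": graph.graph.number_of_edges(),
    }


def _stage_infer(cfg: RunConfig, p: dict) -> dict:
    sequences = cio.read_fasta(p["fasta"])
    gene_map = dict(
        pd.read_csv(p["gene_map"], sep="\t").itertuples(index=False, name=None)
    )
    pairs = [
        (cio.read_psm_table(p["psms"][(cl, "A")]), cio.read_psm_table(p["psms"][(cl, "B")]))
        for cl in p["cell_lines"]
    ]
    grid = [inf.Thresholds(**d) for d in cfg.fdr_grid]
    calib = inf.calibrate_group_fdr(
        pairs, sequences, grid, gene_map=gene_map, group_fdr_max=cfg.group_fdr_max
    )
    n_groups = {}
    for cl, (psms_a, psms_b) in zip(p["cell_lines"], pairs):
        groups = inf.run_inference_chain(
            psms_a, psms_b, sequences, calib.thresholds, gene_map=gene_map
        )
        cio.write_groups(groups, p["groups"][cl])
        n_groups[cl] = len(groups)
    cio.write_json(
        {
            "thresholds": {
                k: getattr(calib.thresholds, k)
                for k in inf.Thresholds.__dataclass_fields__
            },
            "achieved_fdr": calib.achieved_fdr,
            "passed": calib.passed,
            "groups_per_cell_line": n_groups,
        },
        p["calibration"],
    )
    return {"achieved_fdr": calib.achieved_fdr, "fdr_passed": calib.passed,
            "groups_per_cell_line": n_groups}


def _stage_abundance(cfg: RunConfig, p: dict) -> dict:
    sequences = cio.read_fasta(p["fasta"])
    lo, hi = ab.DEFAULT_MASS_RANGE
    rows = []
    observable: dict[str, int] = {}
    for cl in p["cell_lines"]:
        for g in cio.read_groups(p["groups"][cl]):
            if g.is_decoy:
                continue
            for pid in sorted(g.member_ids):
                seq = sequences[pid]
                # detection comes from identification; an accepted protein
                # with no in-range peptide still counts, with emPAI 0
                n_obs = sum(
                    1
                    for pep in g.peptides
                    if pep in seq and lo <= ab.peptide_mass(pep) <= hi
                )
                if pid not in observable:
                    observable[pid] = ab.count_observable_peptides(seq, lo, hi)
                rows.append({"protein": pid, "cell_line": cl, "n_observed": n_obs})
    observed = pd.DataFrame(rows, columns=["protein", "cell_line", "n_observed"])
    matrix = ab.build_abundance_matrix(observed, observable)
    long = observed.copy()
    long["n_observable"] = long["protein"].map(observable)
    long["empai"] = [
        ab.empai(int(n), int(o))
        for n, o in zip(long["n_observed"], long["n_observable"])
    ]
    long.to_csv(p["abundance"], sep="\t", index=False)

    central = ab.central_proteome(matrix, required=cfg.required_lines)
    p["central"].write_text("".join(f"{pid}\n" for pid in sorted(central)))
    part = ab.abundance_classes(matrix, central, quantile=cfg.quantile)
    cio.write_gmt(
        {
            "central": part.central,
            "top_cl": part.top_cl,
            "low_cprot": part.low_cprot,
            "top_cprot": part.top_cprot,
        },
        p["classes"],
    )
    return {
        "central_size": len(central),
        "top_cl": len(part.top_cl),
        "low_cprot": len(part.low_cprot),
        "top_cprot": len(part.top_cprot),
    }


def _labelled_graph(p: dict) -> net.AnnotatedGraph:
    """Interactome with membership labels from the computed abundance sets."""
    graph = cio.read_graph(p["interactome"])
    central = set(p["central"].read_text().split())
    nd = pd.read_csv(p["abundance"], sep="\t").groupby("protein")["cell_line"].nunique()
    labels = {}
    for n in graph.graph.nodes:
        labels[n] = {
            "central": n in central,
            "n_detected": int(nd.get(n, 0)),
        }
    return net.AnnotatedGraph(
        graph=graph.graph, node_terms=graph.node_terms, node_labels=labels
    )


def _stage_topology(cfg: RunConfig, p: dict) -> dict:
    graph = _labelled_graph(p)
    profile = net.topology_measures(graph)
    profile["central"] = [graph.node_labels[n]["central"] for n in profile.index]
    profile.to_csv(p["topology"], sep="\t")
    central = graph.central_nodes
    all_nodes = set(graph.graph.nodes)
    exponent_whole = net.powerlaw_exponent([d for _, d in graph.graph.degree])
    summary = {"powerlaw_exponent_whole": exponent_whole}
    if central:
        sub = net.extract_subnetwork(graph, central)
        degs = [d for _, d in sub.graph.degree]
        try:
            summary["powerlaw_exponent_central"] = net.powerlaw_exponent(degs)
        except ValueError:
            summary["powerlaw_exponent_central"] = None
        hist_cc, unr_cc = net.shortest_path_distribution(graph, central, central)
        hist_all, unr_all = net.shortest_path_distribution(graph, all_nodes, all_nodes)
        summary["mean_distance_central"] = float(
            np.average(list(hist_cc), weights=list(hist_cc.values()))
        )
        summary["mean_distance_all"] = float(
            np.average(list(hist_all), weights=list(hist_all.values()))
        )
        summary["distance_hist_central"] = {str(k): v for k, v in hist_cc.items()}
        summary["distance_hist_all"] = {str(k): v for k, v in hist_all.items()}
        summary["mean_degree_central"] = float(
            np.mean([graph.graph.degree[n] for n in central])
        )
        summary["mean_degree_other"] = float(
            np.mean([graph.graph.degree[n] for n in all_nodes - central])
        ) if all_nodes - central else None
    cio.write_json(summary, p["net_summary"])
    return {k: summary.get(k) for k in
            ("powerlaw_exponent_whole", "powerlaw_exponent_central",
             "mean_distance_central", "mean_distance_all")}


def _stage_pathpos(cfg: RunConfig, p: dict) -> dict:
    pathways = cio.read_pathways(p["pathway_edges"], p["pathway_assign"])
    positions = pw.protein_positions(pathways)
    pd.DataFrame(
        sorted(positions.items()), columns=["protein", "position"]
    ).to_csv(p["positions"], sep="\t", index=False)
    central = set(p["central"].read_text().split())
    targets = set(pd.read_csv(p["drug_targets"], sep="\t")["protein"])
    sets = {
        "all": set(positions),
        "central": central & set(positions),
        "drug_targets": targets & set(positions),
    }
    sets = {k: v for k, v in sets.items() if v}
    profile = pw.positional_profile(positions, sets)
    cio.write_json(
        {
            name: {
                "histogram": prof["histogram"],
                "bins": {b: sorted(m) for b, m in prof["bins"].items()},
            }
            for name, prof in profile.items()
        },
        p["profile"],
    )
    return {"n_positioned": len(positions)}


def _stage_goflux(cfg: RunConfig, p: dict) -> dict:
    graph = _labelled_graph(p)
    results = gf.flux_regimes(
        graph,
        n_networks=cfg.n_random,
        seed=cfg.stage_seed("goflux"),
        alpha=cfg.alpha,
    )
    summary = {}
    for reg, res in results.items():
        if res is None:
            summary[reg] = None
            pd.DataFrame().to_csv(p["flux"][reg], sep="\t", index=False)
            continue
        res.to_frame().to_csv(p["flux"][reg], sep="\t", index=False)
        summary[reg] = {
            "n_significant": len(res.significant_pairs),
            "n_evaluated": len(res.nscore),
            "expected_under_null": gf.expected_significant(len(res.nscore), cfg.alpha),
            "cutoff": res.significance_cutoff,
        }
    cio.write_json(summary, p["goflux_summary"])
    return {
        reg: (s["n_significant"] if s else None) for reg, s in summary.items()
    }


def _stage_compare(cfg: RunConfig, p: dict) -> dict:
    features = pd.read_csv(p["features"], sep="\t")
    central = set(p["central"].read_text().split())
    targets = set(pd.read_csv(p["drug_targets"], sep="\t")["protein"])
    seed = cfg.stage_seed("compare")
    target_tab = features[features["protein"].isin(central)]
    out: dict = {}
    if len(target_tab):
        for feat in ("exon_count", "ortholog_species"):
            res = cstats.length_matched_bootstrap(
                target_tab, features, feat, n_draws=200, seed=seed
            )
            out[f"{feat}_shift"] = {
                "shift": res.shift,
                "interval": list(res.interval),
            }
    topo = pd.read_csv(p["topology"], sep="\t", index_col=0)
    in_c = topo["central"].astype(bool)
    if in_c.any() and (~in_c).any():
        sub = min(200, int(in_c.sum()), int((~in_c).sum()))
        res = cstats.bootstrap_chi2(
            topo.loc[in_c, "degree"],
            topo.loc[~in_c, "degree"],
            subsample=sub,
            seed=seed,
        )
        out["degree_comparison"] = {
            "statistic": res.statistic,
            "p_value": res.p_value,
            "mean_shift": res.mean_shift,
        }
    universe = set(features["protein"])
    assoc = cstats.set_association(
        central & universe, targets & universe, universe, seed=seed,
        subsample=min(500, len(universe)),
    )
    out["drug_target_association"] = {
        "statistic": assoc.statistic,
        "p_value": assoc.p_value,
        "overlap_excess": assoc.mean_shift,
    }
    cio.write_json(out, p["compare"])
    return {
        "exon_shift": out.get("exon_count_shift", {}).get("shift"),
        "drug_target_p": out["drug_target_association"]["p_value"],
    }


def _stage_io(cfg: RunConfig, p: dict, name: str) -> tuple[list[Path], list[Path]]:
    """(inputs, outputs) of each stage for freshness checks."""
    psms = list(p["psms"].values())
    groups = list(p["groups"].values())
    flux = list(p["flux"].values())
    table = {
        "synth": ([], [p["fasta"], p["gene_map"], p["interactome"],
                       p["pathway_edges"], p["pathway_assign"], p["features"],
                       p["drug_targets"], p["ground_truth"], *psms]),
        "infer": ([p["fasta"], p["gene_map"], *psms], [p["calibration"], *groups]),
        "abundance": ([p["fasta"], *groups],
                      [p["abundance"], p["central"], p["classes"]]),
        "topology": ([p["interactome"], p["central"], p["abundance"]],
                     [p["topology"], p["net_summary"]]),
        "pathpos": ([p["pathway_edges"], p["pathway_assign"], p["central"],
                     p["drug_targets"]], [p["positions"], p["profile"]]),
        "goflux": ([p["interactome"], p["central"], p["abundance"]],
                   [p["goflux_summary"], *flux]),
        "compare": ([p["features"], p["central"], p["topology"],
                     p["drug_targets"]], [p["compare"]]),
    }
    return table[name]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "infer": _stage_infer,
    "abundance": _stage_abundance,
    "topology": _stage_topology,
    "pathpos": _stage_pathpos,
    "goflux": _stage_goflux,
    "compare": _stage_compare,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run report.

    Downstream stages are halted on the first failure; the report is
    written to ``<out_dir>/report.json`` in every case.
    """
    p = _paths(config)
    report: dict = {
        "seed": config.seed,
        "parameters": {
            "group_fdr_max": config.group_fdr_max,
            "quantile": config.quantile,
            "n_random": config.n_random,
            "alpha": config.alpha,
            "synthetic": config.synthetic,
        },
        "stages": {},
    }
    failed = False
    for name in STAGES:
        if name not in config.stages:
            continue
        inputs, outputs = _stage_io(config, p, name)
        entry: dict = {"status": "pending"}
        report["stages"][name] = entry
        if failed:
            entry["status"] = "halted"
            continue
        if not config.force and _fresh(outputs, inputs):
            entry["status"] = "up-to-date"
        else:
            for out in outputs:
                out.parent.mkdir(parents=True, exist_ok=True)
            t0 = time.time()
            try:
                entry["headline"] = _STAGE_FUNCS[name](config, p)
                entry["status"] = "completed"
            except Exception as exc:  # report-and-halt semantics
                entry["status"] = "failed"
                entry["error"] = f"{type(exc).__name__}: {exc}"
                failed = True
            entry["wall_seconds"] = round(time.time() - t0, 3)
        entry["outputs"] = {
            str(out.relative_to(config.out_dir)): _sha256(out)
            for out in outputs
            if out.exists()
        }
    config.out_dir.mkdir(parents=True, exist_ok=True)
    cio.write_json(report, config.out_dir / "report.json")
    return report
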