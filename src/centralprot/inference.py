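"""Two-engine protein inference with decoy-calibrated group FDR.

PSM tables from two search engines (A on an ion-score-like scale, B on
a z-score scale with P-values) are merged per spectrum — spectra the two
engines assign to different peptides are discarded.  Per engine, a
protein is accepted with at least two distinct peptides above the
primary score threshold (all further peptides above the lower
"additional" threshold are then exported), or as a single peptide hit
(SPH) above a much higher threshold provided sequence coverage reaches
a minimum.  Accepted proteins are grouped by shared peptides
(identical-set merging plus strict-subset absorption), groups without
any specific peptide are discarded, and groups that mix several genes
(i.e. are not made of splice variants exclusively) can be filtered out.
Score thresholds are calibrated on a grid so that the protein-group
false discovery rate, estimated from reverse-database (decoy) matches
as decoy groups / target groups, stays below a bound (default 0.25%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "ProteinGroup",
    "CalibrationResult",
    "merge_engine_results",
    "apply_identification_rules",
    "group_proteins",
    "splice_variant_filter",
    "run_inference_chain",
    "calibrate_group_fdr",
    "realized_false_discovery",
]

PSM_COLUMNS = [
    "spectrum_id",
    "cell_line",
    "engine",
    "peptide",
    "score",
    "pvalue",
    "protein_ids",
    "is_decoy",
]


@dataclass(frozen=True)
class Thresholds:
    """Score thresholds of the two engines and the group-FDR bound.

    Defaults are the calibrated working point: engine A (ion score) —
    two peptides at >= 18, additional peptides exported at >= 10, SPH at
    >= 50; engine B (z-score) — two peptides at z >= 4.5 with P <= 0.001,
    additional at z >= 3.5, SPH at z >= 6; SPHs additionally need 2.5%
    sequence coverage.
    """

    A_primary_score: float = 18.0
    A_additional_score: float = 10.0
    A_sph_score: float = 50.0
    B_primary_z: float = 4.5
    B_primary_pmax: float = 0.001
    B_additional_z: float = 3.5
    B_sph_z: float = 6.0
    sph_min_coverage: float = 0.025
    group_fdr_max: float = 0.0025

    def __post_init__(self) -> None:
        if not (
            self.A_additional_score
            <= self.A_primary_score
            <= self.A_sph_score
        ):
            raise ValueError("engine A thresholds must satisfy additional <= primary <= SPH")
        if not (self.B_additional_z <= self.B_primary_z <= self.B_sph_z):
            raise ValueError("engine B thresholds must satisfy additional <= primary <= SPH")
        for name in ("sph_min_coverage", "group_fdr_max", "B_primary_pmax"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def stringency_key(self) -> tuple:
        """Sort key: lower = less stringent."""
        return (
            self.A_primary_score,
            self.B_primary_z,
            self.A_sph_score,
            self.B_sph_z,
            self.A_additional_score,
            self.B_additional_z,
        )


@dataclass(frozen=True)
class ProteinGroup:
    """Set of protein accessions indistinguishable by accepted peptides."""

    member_ids: frozenset
    peptides: frozenset
    specific_peptides: frozenset = frozenset()
    gene_ids: frozenset = frozenset()
    coverage: float = field(default=float("nan"), compare=False)
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("member_ids must be nonempty")
        if not self.specific_peptides <= self.peptides:
            raise ValueError("specific_peptides must be a subset of peptides")

    @property
    def sort_key(self) -> tuple:
        return tuple(sorted(self.member_ids))


def _as_idset(value) -> frozenset:
    if isinstance(value, str):
        ids = frozenset(x for x in value.split(";") if x)
    else:
        ids = frozenset(value)
    if not ids:
        raise ValueError("protein_ids must be nonempty")
    return ids


def validate_psm_table(psms: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate one engine's PSM table."""
    missing = set(PSM_COLUMNS) - set(psms.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    out = psms.copy()
    dup = out["spectrum_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicated spectrum_id within one engine table: "
            f"{out.loc[dup, 'spectrum_id'].iloc[0]!r}"
        )
    if (out["peptide"].str.len() < 6).any():
        raise ValueError("peptides must be at least 6 residues long")
    if not np.isfinite(out["score"]).all():
        raise ValueError("scores must be finite")
    out["protein_ids"] = out["protein_ids"].map(_as_idset)
    return out


def merge_engine_results(
    psms_a: pd.DataFrame, psms_b: pd.DataFrame
) -> pd.DataFrame:
    """Merge the two engines' PSMs of one cell line by spectrum.

    Spectra assigned to different peptides by the two engines are
    removed entirely; agreeing duplicates collapse to one record that
    retains both engines' scores (``score_A``, ``score_B``,
    ``pvalue_B``); spectra seen by a single engine are kept.
    """
    a = validate_psm_table(psms_a) if len(psms_a) else psms_a
    b = validate_psm_table(psms_b) if len(psms_b) else psms_b
    lines = set()
    for t in (a, b):
        if len(t):
            lines.update(t["cell_line"].unique())
    if len(lines) > 1:
        raise ValueError(f"tables mix cell lines: {sorted(lines)}")

    records: dict[str, dict] = {}
    for table, engine in ((a, "A"), (b, "B")):
        for row in table.itertuples(index=False) if len(table) else []:
            sid = row.spectrum_id
            rec = records.setdefault(
                sid,
                {
                    "spectrum_id": sid,
                    "cell_line": row.cell_line,
                    "peptide": row.peptide,
                    "protein_ids": row.protein_ids,
                    "is_decoy": bool(row.is_decoy),
                    "score_A": np.nan,
                    "score_B": np.nan,
                    "pvalue_B": np.nan,
                    "_conflict": False,
                },
            )
            if rec["peptide"] != row.peptide:
                rec["_conflict"] = True
                continue
            rec["protein_ids"] = rec["protein_ids"] | row.protein_ids
            rec["is_decoy"] = rec["is_decoy"] or bool(row.is_decoy)
            if engine == "A":
                rec["score_A"] = row.score
            else:
                rec["score_B"] = row.score
                rec["pvalue_B"] = row.pvalue
    merged = [r for r in records.values() if not r.pop("_conflict")]
    cols = [
        "spectrum_id",
        "cell_line",
        "peptide",
        "protein_ids",
        "is_decoy",
        "score_A",
        "score_B",
        "pvalue_B",
    ]
    return pd.DataFrame(merged, columns=cols)


def _peptide_coverage(sequence: str, peptides) -> float:
    """Fraction of residues covered by any occurrence of any peptide."""
    covered = np.zeros(len(sequence), dtype=bool)
    for pep in peptides:
        start = sequence.find(pep)
        while start >= 0:
            covered[start : start + len(pep)] = True
            start = sequence.find(pep, start + 1)
    return float(covered.mean()) if len(sequence) else 0.0


def apply_identification_rules(
    merged: pd.DataFrame,
    sequences,
    thresholds: Thresholds = Thresholds(),
) -> dict:
    """Accept proteins per engine and return union evidence.

    Returns protein id -> ``{"peptides": frozenset, "is_decoy": bool}``.
    Acceptance per engine: >= 2 distinct peptides above the primary
    threshold (exporting all peptides above the additional threshold),
    or exactly one peptide above the SPH threshold with sequence
    coverage >= ``sph_min_coverage``.  The engines are evaluated
    separately on the merged spectra and their acceptances are unioned.
    """
    t = thresholds
    # protein -> peptide -> best score per engine
    best: dict[str, dict[str, dict]] = {"A": {}, "B": {}}
    decoy_flag: dict[str, bool] = {}
    for row in merged.itertuples(index=False):
        for pid in row.protein_ids:
            decoy_flag[pid] = decoy_flag.get(pid, False) or bool(row.is_decoy)
            if np.isfinite(row.score_A):
                d = best["A"].setdefault(pid, {})
                d[row.peptide] = max(d.get(row.peptide, -np.inf), row.score_A)
            if np.isfinite(row.score_B):
                d = best["B"].setdefault(pid, {})
                prev = d.get(row.peptide)
                cand = (row.score_B, row.pvalue_B)
                if prev is None or cand[0] > prev[0]:
                    d[row.peptide] = cand

    def passes(engine: str, val, level: str) -> bool:
        if engine == "A":
            score = val
            return score >= {
                "primary": t.A_primary_score,
                "additional": t.A_additional_score,
                "sph": t.A_sph_score,
            }[level]
        z, p = val
        if level == "primary":
            return z >= t.B_primary_z and (
                not np.isfinite(p) or p <= t.B_primary_pmax
            )
        if level == "additional":
            return z >= t.B_additional_z
        return z >= t.B_sph_z

    evidence: dict[str, dict] = {}
    for engine in ("A", "B"):
        for pid, peps in best[engine].items():
            primary = {p for p, v in peps.items() if passes(engine, v, "primary")}
            exported: set[str] = set()
            if len(primary) >= 2:
                exported = {
                    p for p, v in peps.items() if passes(engine, v, "additional")
                }
            else:
                sph = {p for p, v in peps.items() if passes(engine, v, "sph")}
                if len(sph) == 1:
                    if pid not in sequences:
                        raise KeyError(
                            f"sequence required for SPH coverage of {pid!r} "
                            "but absent from the sequence collection"
                        )
                    if (
                        _peptide_coverage(sequences[pid], sph)
                        >= t.sph_min_coverage
                    ):
                        exported = sph
            if exported:
                rec = evidence.setdefault(
                    pid, {"peptides": set(), "is_decoy": decoy_flag[pid]}
                )
                rec["peptides"].update(exported)
    return {
        pid: {"peptides": frozenset(rec["peptides"]), "is_decoy": rec["is_decoy"]}
        for pid, rec in evidence.items()
    }


def group_proteins(evidence: dict, sequences=None) -> list[ProteinGroup]:
    """Group accepted proteins by shared peptides.

    Proteins with identical peptide sets form one group; a protein whose
    peptide set is a strict subset of another's is absorbed into that
    group (ties broken deterministically by member ids).  Groups whose
    peptide set contains no peptide unique to the group are discarded;
    ``specific_peptides`` are then recomputed against the surviving
    groups.  Coverage (fraction of the longest member sequence covered)
    is filled in when ``sequences`` is given.
    """
    if not evidence:
        raise ValueError("evidence must be nonempty")
    by_set: dict[frozenset, list[str]] = {}
    for pid in sorted(evidence):
        by_set.setdefault(evidence[pid]["peptides"], []).append(pid)

    pepsets = sorted(by_set, key=lambda s: (-len(s), sorted(s)))
    # inverted peptide index: a set can only be a strict subset of a set
    # sharing its rarest peptide
    index: dict[str, list[frozenset]] = {}
    for s in pepsets:
        for pep in s:
            index.setdefault(pep, []).append(s)

    def strict_supersets(s: frozenset) -> list[frozenset]:
        pep = min(s, key=lambda p: len(index[p]))
        return [other for other in index[pep] if s < other]

    maximal = [s for s in pepsets if not strict_supersets(s)]
    maximal_set = set(maximal)
    groups: dict[frozenset, set[str]] = {s: set(by_set[s]) for s in maximal}
    for s in pepsets:
        if s in groups:
            continue
        supersets = sorted(
            (m for m in strict_supersets(s) if m in maximal_set),
            key=lambda m: sorted(groups[m]),
        )
        groups[supersets[0]].update(by_set[s])

    # specificity across all groups
    pep_owner: dict[str, int] = {}
    for s in groups:
        for pep in s:
            pep_owner[pep] = pep_owner.get(pep, 0) + 1
    surviving = {
        s: members
        for s, members in groups.items()
        if any(pep_owner[pep] == 1 for pep in s)
    }
    # recompute specificity among survivors
    pep_owner2: dict[str, int] = {}
    for s in surviving:
        for pep in s:
            pep_owner2[pep] = pep_owner2.get(pep, 0) + 1

    out = []
    for s, members in surviving.items():
        specific = frozenset(p for p in s if pep_owner2[p] == 1)
        coverage = float("nan")
        if sequences is not None:
            seqs = [sequences[m] for m in members if m in sequences]
            if seqs:
                rep = max(seqs, key=len)
                coverage = _peptide_coverage(rep, s)
        out.append(
            ProteinGroup(
                member_ids=frozenset(members),
                peptides=s,
                specific_peptides=specific,
                coverage=coverage,
                is_decoy=any(evidence[m]["is_decoy"] for m in members),
            )
        )
    return sorted(out, key=lambda g: g.sort_key)


def splice_variant_filter(
    groups: list[ProteinGroup], gene_map: dict
) -> list[ProteinGroup]:
    """Retain groups whose members all share a single gene identifier."""
    kept = []
    for g in groups:
        genes = set()
        for pid in g.member_ids:
            if pid not in gene_map:
                raise KeyError(f"no gene mapping for accession {pid!r}")
            genes.add(gene_map[pid])
        if len(genes) == 1:
            kept.append(replace(g, gene_ids=frozenset(genes)))
    return kept


def run_inference_chain(
    psms_a: pd.DataFrame,
    psms_b: pd.DataFrame,
    sequences,
    thresholds: Thresholds = Thresholds(),
    gene_map: dict | None = None,
) -> list[ProteinGroup]:
    """Merge, threshold, group and (optionally) splice-filter one cell line."""
    merged = merge_engine_results(psms_a, psms_b)
    evidence = apply_identification_rules(merged, sequences, thresholds)
    if not evidence:
        return []
    groups = group_proteins(evidence, sequences)
    if gene_map is not None:
        groups = splice_variant_filter(groups, gene_map)
    return groups


@dataclass
class CalibrationResult:
    thresholds: Thresholds
    achieved_fdr: float
    passed: bool
    per_candidate: pd.DataFrame


def estimate_group_fdr(
    groups: list[ProteinGroup], estimator: str = "decoys_over_targets"
) -> float:
    """Decoy-based group FDR estimate over a list of surviving groups."""
    n_decoy = sum(g.is_decoy for g in groups)
    n_target = len(groups) - n_decoy
    if n_target == 0:
        return 1.0 if n_decoy else float("nan")
    if estimator == "decoys_over_targets":
        return n_decoy / n_target
    if estimator == "two_decoys_over_all":
        return 2 * n_decoy / (n_target + n_decoy)
    raise ValueError(f"unknown estimator {estimator!r}")


def calibrate_group_fdr(
    psm_tables,
    sequences,
    thresholds_grid,
    gene_map: dict | None = None,
    group_fdr_max: float = 0.0025,
    estimator: str = "decoys_over_targets",
) -> CalibrationResult:
    """Pick the least stringent thresholds meeting the group-FDR bound.

    ``psm_tables`` is a sequence of ``(psms_A, psms_B)`` pairs, one per
    cell line.  For each candidate the full merge/threshold/grouping
    chain is run per cell line; decoy and target group counts are summed
    and the FDR estimated (default: decoys / targets, the single
    reverse-database convention).  Among candidates with FDR <=
    ``group_fdr_max`` the least stringent is returned; if none
    qualifies, the best achievable is returned with ``passed=False``.
    """
    if not thresholds_grid:
        raise ValueError("thresholds_grid must be nonempty")
    rows = []
    for cand in thresholds_grid:
        n_decoy = n_target = 0
        for psms_a, psms_b in psm_tables:
            merged = merge_engine_results(psms_a, psms_b)
            evidence = apply_identification_rules(merged, sequences, cand)
            if not evidence:
                continue
            groups = group_proteins(evidence, sequences)
            if gene_map is not None:
                groups = splice_variant_filter(groups, gene_map)
            n_decoy += sum(g.is_decoy for g in groups)
            n_target += sum(not g.is_decoy for g in groups)
        if n_target == 0:
            fdr = 1.0 if n_decoy else float("nan")
        elif estimator == "decoys_over_targets":
            fdr = n_decoy / n_target
        else:
            fdr = 2 * n_decoy / (n_target + n_decoy)
        rows.append(
            {
                "thresholds": cand,
                "n_decoy_groups": n_decoy,
                "n_target_groups": n_target,
                "fdr": fdr,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[
        table["fdr"].notna() & (table["fdr"] <= group_fdr_max)
    ]
    if len(ok):
        idx = min(
            ok.index, key=lambda i: table.loc[i, "thresholds"].stringency_key()
        )
        return CalibrationResult(
            thresholds=table.loc[idx, "thresholds"],
            achieved_fdr=float(table.loc[idx, "fdr"]),
            passed=True,
            per_candidate=table,
        )
    finite = table[table["fdr"].notna()]
    idx = (
        finite["fdr"].idxmin() if len(finite) else table.index[0]
    )
    return CalibrationResult(
        thresholds=table.loc[idx, "thresholds"],
        achieved_fdr=float(table.loc[idx, "fdr"]),
        passed=False,
        per_candidate=table,
    )


def realized_false_discovery(
    groups: list[ProteinGroup], true_proteins: set
) -> tuple[int, int]:
    """(false, total) among surviving target groups, given planted truth.

    A target (non-decoy) group is a false identification when none of
    its members is a truly present protein.
    """
    targets = [g for g in groups if not g.is_decoy]
    false = sum(1 for g in targets if not (g.member_ids & true_proteins))
    return false, len(targets)
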