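"""emPAI protein abundance, the central proteome, and abundance classes.

Abundance is estimated with emPAI, an exponentially modified spectral
count: ``emPAI = 10^(n_observed / n_observable) - 1``, where
``n_observable`` counts the tryptic peptides of the protein whose
monoisotopic mass falls inside the instrument mass range.  Per-protein
abundance across cell lines is summarized by the median over the cell
lines in which the protein was detected (absence is missing data, not
zero).  The central proteome is the intersection of the per-cell-line
identification sets; abundance classes partition proteins into the top
quartile of non-ubiquitous proteins (Top.CL) and the bottom/top quartile
of the central proteome (Low.C.Prot / Top.C.Prot).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass
from pyteomics import parser as _pt_parser

__all__ = [
    "AbundanceMatrix",
    "SetPartition",
    "DEFAULT_MASS_RANGE",
    "tryptic_peptides",
    "count_observable_peptides",
    "empai",
    "build_abundance_matrix",
    "central_proteome",
    "abundance_classes",
]

#: Instrument mass range (monoisotopic Da) covering ~99% of detected peptides.
DEFAULT_MASS_RANGE = (698.0, 2370.0)

# cleave C-terminal to K/R unless followed by proline
TRYPSIN_RULE = r"[KR](?!P)"

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def tryptic_peptides(
    sequence: str,
    missed_cleavages: int = 1,
    min_length: int = 6,
) -> set[str]:
    """Distinct tryptic peptides of ``sequence``.

    Cleaves after K/R except before P, allows up to ``missed_cleavages``
    missed sites and drops peptides shorter than ``min_length`` residues.
    """
    if not sequence:
        return set()
    return _pt_parser.cleave(
        sequence,
        TRYPSIN_RULE,
        missed_cleavages=missed_cleavages,
        min_length=min_length,
    )


def count_observable_peptides(
    sequence: str,
    mass_min: float = DEFAULT_MASS_RANGE[0],
    mass_max: float = DEFAULT_MASS_RANGE[1],
    missed_cleavages: int = 1,
    min_length: int = 6,
) -> int:
    """Number of distinct tryptic peptides observable in the mass range.

    A peptide is observable when its monoisotopic neutral mass [M] lies
    in ``[mass_min, mass_max]``.

    Raises
    ------
    ValueError
        If the sequence contains a nonstandard residue (position reported)
        or ``mass_min >= mass_max``.
    """
    if mass_min >= mass_max:
        raise ValueError(f"mass_min ({mass_min}) must be < mass_max ({mass_max})")
    for pos, aa in enumerate(sequence):
        if aa not in _STANDARD_AA:
            raise ValueError(f"nonstandard residue {aa!r} at position {pos}")
    count = 0
    for pep in tryptic_peptides(sequence, missed_cleavages, min_length):
        m = _pt_mass.fast_mass(pep)  # monoisotopic [M]
        if mass_min <= m <= mass_max:
            count += 1
    return count


def peptide_mass(peptide: str) -> float:
    """Monoisotopic neutral mass [M] of a peptide."""
    return float(_pt_mass.fast_mass(peptide))


def empai(n_observed: int, n_observable: int) -> float:
    """emPAI = 10^(n_observed/n_observable) - 1.

    Raises
    ------
    ValueError
        If ``n_observable`` is 0 (abundance undefined) or counts negative.
    """
    if n_observable < 1:
        raise ValueError("emPAI undefined: n_observable must be >= 1")
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    return 10.0 ** (n_observed / n_observable) - 1.0


@dataclass
class AbundanceMatrix:
    """Protein x cell-line emPAI values with detection summaries.

    ``empai`` holds NaN where a protein was not detected in a cell line;
    ``median_empai`` is taken over detected cell lines only.
    """

    empai: pd.DataFrame  # index: protein, columns: cell line, NaN = absent

    @property
    def proteins(self) -> list[str]:
        return list(self.empai.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.empai.columns)

    @property
    def n_detected(self) -> pd.Series:
        return self.empai.notna().sum(axis=1)

    @property
    def median_empai(self) -> pd.Series:
        return self.empai.median(axis=1, skipna=True)


@dataclass
class SetPartition:
    """Central proteome and the three abundance classes."""

    central: set[str]
    top_cl: set[str]
    low_cprot: set[str]
    top_cprot: set[str]
    quantile: float = 0.25

    def validate(self) -> None:
        assert self.low_cprot <= self.central
        assert self.top_cprot <= self.central
        assert not (self.top_cl & self.central)
        assert not (self.low_cprot & self.top_cprot)


def build_abundance_matrix(
    observed: pd.DataFrame,
    observable: dict[str, int],
) -> AbundanceMatrix:
    """Assemble the emPAI matrix from per-cell-line observed peptide counts.

    Parameters
    ----------
    observed:
        Long table with columns ``protein``, ``cell_line``, ``n_observed``;
        one row per detection.
    observable:
        Protein id -> number of observable tryptic peptides (>= 1).
    """
    required = {"protein", "cell_line", "n_observed"}
    missing = required - set(observed.columns)
    if missing:
        raise ValueError(f"observed table missing columns: {sorted(missing)}")
    vals = observed.copy()
    vals["empai"] = [
        empai(int(n), int(observable[p]))
        for p, n in zip(vals["protein"], vals["n_observed"])
    ]
    wide = vals.pivot_table(
        index="protein", columns="cell_line", values="empai", aggfunc="max"
    )
    wide.index.name = "protein"
    return AbundanceMatrix(empai=wide.sort_index())


def central_proteome(matrix: AbundanceMatrix, required: int | None = None) -> set[str]:
    """Proteins detected in at least ``required`` cell lines.

    ``required=None`` (default) demands detection in every cell line,
    i.e. the strict intersection.
    """
    n_lines = len(matrix.cell_lines)
    if required is None:
        required = n_lines
    if not 1 <= required <= n_lines:
        raise ValueError(f"required must be in [1, {n_lines}], got {required}")
    nd = matrix.n_detected
    return set(nd.index[nd >= required])


def _quantile_class(medians: pd.Series, k: int, top: bool) -> set[str]:
    """Top or bottom ``k`` proteins by value, excluding boundary ties.

    If the value at the class boundary is shared with proteins outside
    the nominal class, all tied proteins are excluded, so the class may
    hold fewer than ``k`` members.
    """
    if k <= 0 or medians.empty:
        return set()
    s = medians.sort_values(ascending=not top, kind="mergesort")
    boundary = s.iloc[k - 1]
    if len(s) > k and s.iloc[k] == boundary:
        chosen = s.iloc[:k]
        return set(chosen.index[chosen != boundary])
    return set(s.index[:k])


def abundance_classes(
    matrix: AbundanceMatrix,
    central: set[str],
    quantile: float = 0.25,
    max_lines_for_top_cl: int | None = None,
) -> SetPartition:
    """Build Top.CL, Low.C.Prot and Top.C.Prot from median emPAI.

    Top.CL is the top ``quantile`` of median emPAI among proteins not
    detected in more than ``max_lines_for_top_cl`` cell lines (default:
    n_cell_lines - 2, i.e. 5 of 7).  Low/Top.C.Prot are the bottom/top
    ``quantile`` within the central set.  Values tied at a class
    boundary are excluded from the class.
    """
    if not 0 < quantile <= 0.5:
        raise ValueError(f"quantile must be in (0, 0.5], got {quantile}")
    if max_lines_for_top_cl is None:
        max_lines_for_top_cl = len(matrix.cell_lines) - 2
    med = matrix.median_empai
    nd = matrix.n_detected

    non_ubiq = med[nd <= max_lines_for_top_cl]
    k_cl = int(np.floor(quantile * len(non_ubiq)))
    top_cl = _quantile_class(non_ubiq, k_cl, top=True)

    if not central:
        warnings.warn("empty central set: abundance classes are empty")
        return SetPartition(set(), top_cl, set(), set(), quantile)

    central_med = med[med.index.isin(central)]
    k_c = int(np.floor(quantile * len(central_med)))
    low = _quantile_class(central_med, k_c, top=False)
    high = _quantile_class(central_med, k_c, top=True)
    part = SetPartition(set(central), top_cl, low, high, quantile)
    part.validate()
    return part
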