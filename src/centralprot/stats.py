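"""Cross-cutting statistical machinery.

The workhorse is a bootstrapped chi-square comparison of two value
distributions: with large observation counts a plain chi-square
goodness-of-fit test flags negligible differences, so instead the data
are re-sampled (default 1000 times, 500 points per set with
replacement), binned into equal-probability bins defined on the pooled
subsample, and the median of the per-resample two-sample chi-square
statistics is referred to the chi-square distribution (bins - 1 degrees
of freedom).  The module also provides a length-matched bootstrap for
estimating feature shifts (e.g. exon counts) against a reference
proteome, ortholog-species counting, a 2x2 set-association variant of
the bootstrapped test, and GO term-coverage ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "ComparisonResult",
    "ShiftResult",
    "bootstrap_chi2",
    "length_matched_bootstrap",
    "count_ortholog_species",
    "set_association",
    "term_coverage",
]


@dataclass
class ComparisonResult:
    """Median bootstrapped chi-square statistic and its P-value."""

    statistic: float
    p_value: float
    n_resamples: int
    subsample_size: int
    n_bins: int
    mean_shift: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0, 1]")


@dataclass
class ShiftResult:
    """Length-matched bootstrap shift estimate with percentile interval."""

    shift: float
    interval: tuple[float, float]
    n_draws: int

    def covers_zero(self) -> bool:
        return self.interval[0] <= 0.0 <= self.interval[1]


def _bin_counts(samples: np.ndarray, edges: np.ndarray, bins: int) -> np.ndarray:
    """Per-row histogram counts for row-specific inner bin edges."""
    idx = (samples[:, :, None] > edges[:, None, :]).sum(axis=2)
    counts = np.zeros((samples.shape[0], bins))
    rows = np.repeat(np.arange(samples.shape[0]), samples.shape[1])
    np.add.at(counts, (rows, idx.ravel()), 1.0)
    return counts


def bootstrap_chi2(
    sample_a,
    sample_b,
    n_resamples: int = 1000,
    subsample: int = 500,
    bins: int = 10,
    seed: int | np.random.Generator = 0,
    binning: str = "quantile",
) -> ComparisonResult:
    """Bootstrapped chi-square comparison of two value distributions.

    Each resample draws ``subsample`` points with replacement from each
    sample, bins both into ``bins`` equal-probability bins defined on
    the pooled subsample (``binning="width"`` for equal-width bins), and
    computes the two-sample chi-square statistic.  The median statistic
    is referred to chi-square with ``bins - 1`` degrees of freedom.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    pooled_all = np.concatenate([a, b])
    if np.ptp(pooled_all) == 0:
        raise ValueError("degenerate (constant) pooled sample")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    A = rng.choice(a, size=(n_resamples, subsample), replace=True)
    B = rng.choice(b, size=(n_resamples, subsample), replace=True)
    pooled = np.concatenate([A, B], axis=1)
    if binning == "quantile":
        probs = np.arange(1, bins) / bins
        edges = np.quantile(pooled, probs, axis=1).T  # (R, bins-1)
    elif binning == "width":
        lo = pooled.min(axis=1, keepdims=True)
        hi = pooled.max(axis=1, keepdims=True)
        frac = (np.arange(1, bins) / bins)[None, :]
        edges = lo + (hi - lo) * frac
    else:
        raise ValueError(f"unknown binning {binning!r}")
    oa = _bin_counts(A, edges, bins)
    ob = _bin_counts(B, edges, bins)
    tot = oa + ob
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(tot > 0, (oa - ob) ** 2 / np.where(tot > 0, tot, 1), 0.0)
    stats_ = contrib.sum(axis=1)
    median = float(np.median(stats_))
    p = float(sp_stats.chi2.sf(median, df=bins - 1))
    return ComparisonResult(
        statistic=median,
        p_value=p,
        n_resamples=n_resamples,
        subsample_size=subsample,
        n_bins=bins,
        mean_shift=float(a.mean() - b.mean()),
    )


def length_matched_bootstrap(
    target: pd.DataFrame,
    reference: pd.DataFrame,
    feature: str,
    n_draws: int = 200,
    seed: int | np.random.Generator = 0,
    n_strata: int = 10,
) -> ShiftResult:
    """Feature shift of ``target`` vs a length-matched reference bootstrap.

    Both tables need ``sequence_length`` and ``feature`` columns.  The
    target's sequence-length distribution is stratified into
    ``n_strata`` quantile strata; each draw samples, per stratum, as
    many reference values (with replacement) as the target holds there,
    reproducing the target's length distribution in the reference.
    Returns observed mean(feature | target) minus the bootstrap mean,
    with a 95% percentile interval.  Reference-empty strata are dropped
    from both sides with a warning.
    """
    for tab, name in ((target, "target"), (reference, "reference")):
        for col in ("sequence_length", feature):
            if col not in tab.columns:
                raise ValueError(f"{name} table lacks column {col!r}")
    if len(target) == 0 or len(reference) == 0:
        raise ValueError("tables must be nonempty")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tlen = target["sequence_length"].to_numpy(dtype=float)
    rlen = reference["sequence_length"].to_numpy(dtype=float)
    tfeat = target[feature].to_numpy(dtype=float)
    rfeat = reference[feature].to_numpy(dtype=float)

    edges = np.quantile(tlen, np.linspace(0, 1, n_strata + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        edges = np.array([tlen.min() - 1, tlen.max() + 1])
    t_bin = np.clip(np.searchsorted(edges, tlen, side="right") - 1, 0, len(edges) - 2)
    r_bin = np.clip(np.searchsorted(edges, rlen, side="right") - 1, 0, len(edges) - 2)

    strata = []
    kept_target = np.zeros(len(tlen), dtype=bool)
    for s in range(len(edges) - 1):
        t_mask = t_bin == s
        if not t_mask.any():
            continue
        r_vals = rfeat[r_bin == s]
        if r_vals.size == 0:
            warnings.warn(f"length stratum {s} empty in reference; dropped")
            continue
        strata.append((int(t_mask.sum()), r_vals))
        kept_target |= t_mask
    if not strata:
        raise ValueError("no usable length strata")
    obs_mean = float(tfeat[kept_target].mean())
    n_total = sum(n for n, _ in strata)
    boot_means = np.zeros(n_draws)
    for s_n, r_vals in strata:
        draws = rng.choice(r_vals, size=(n_draws, s_n), replace=True)
        boot_means += draws.sum(axis=1) / n_total
    shift_draws = obs_mean - boot_means
    lo, hi = np.percentile(shift_draws, [2.5, 97.5])
    return ShiftResult(
        shift=float(np.mean(shift_draws)),
        interval=(float(lo), float(hi)),
        n_draws=n_draws,
    )


def count_ortholog_species(ortholog_table: pd.DataFrame, protein: str) -> int:
    """Distinct species with at least one ortholog row for ``protein``."""
    for col in ("protein", "species"):
        if col not in ortholog_table.columns:
            raise ValueError(f"ortholog table lacks column {col!r}")
    rows = ortholog_table[ortholog_table["protein"] == protein]
    return int(rows["species"].nunique())


def set_association(
    set_a: set,
    set_b: set,
    universe: set,
    seed: int | np.random.Generator = 0,
    n_resamples: int = 1000,
    subsample: int = 500,
) -> ComparisonResult:
    """Bootstrapped chi-square association of two sets over a universe.

    Membership indicators over the universe form a 2x2 contingency
    table per resample (the bins collapse to the four cells); the
    median independence chi-square statistic is referred to chi-square
    with one degree of freedom.
    """
    universe = sorted(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    if not (set(set_a) <= set(universe) and set(set_b) <= set(universe)):
        raise ValueError("sets must be subsets of the universe")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    xa = np.array([u in set_a for u in universe])
    xb = np.array([u in set_b for u in universe])
    idx = rng.integers(len(universe), size=(n_resamples, subsample))
    A = xa[idx]
    B = xb[idx]
    n11 = (A & B).sum(axis=1).astype(float)
    n10 = (A & ~B).sum(axis=1).astype(float)
    n01 = (~A & B).sum(axis=1).astype(float)
    n00 = (~A & ~B).sum(axis=1).astype(float)
    n = float(subsample)
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    denom = r1 * r0 * c1 * c0
    with np.errstate(invalid="ignore", divide="ignore"):
        stats_ = np.where(
            denom > 0, n * (n11 * n00 - n10 * n01) ** 2 / np.where(denom > 0, denom, 1), 0.0
        )
    median = float(np.median(stats_))
    p = float(sp_stats.chi2.sf(median, df=1))
    overlap = len(set(set_a) & set(set_b))
    expected = len(set_a) * len(set_b) / len(universe)
    return ComparisonResult(
        statistic=median,
        p_value=p,
        n_resamples=n_resamples,
        subsample_size=subsample,
        n_bins=4,
        mean_shift=float(overlap - expected),
    )


def term_coverage(
    protein_set: set,
    term: str,
    annotations: pd.DataFrame,
    slim=None,
) -> float:
    """Fraction of the term's annotated proteins found in ``protein_set``.

    ``annotations`` is a long (protein, term) table.  With a ``slim``
    ontology, proteins annotated to descendants of ``term`` count too.
    """
    for col in ("protein", "term"):
        if col not in annotations.columns:
            raise ValueError(f"annotations table lacks column {col!r}")
    considered = {term}
    if slim is not None:
        considered |= {t for t in slim.terms if term in slim.ancestors(t)}
    annotated = set(
        annotations.loc[annotations["term"].isin(considered), "protein"]
    )
    if not annotated:
        raise ValueError(f"term {term!r} has no annotations in the universe")
    return len(annotated & set(protein_set)) / len(annotated)
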