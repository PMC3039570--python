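# Methods

This note documents the models and procedures implemented in
`centralprot`, the assumptions behind them, the defaults that matter,
and the choices made where the design was genuinely open.

## Problem setting

A panel of cell lines is profiled by shotgun proteomics; each cell line
yields peptide-spectrum matches (PSMs) from two database search
engines.  The pipeline identifies proteins per cell line under a strict
protein-group false-discovery-rate (FDR) bound, defines the *central
proteome* as the proteins identified in every cell line, estimates
abundances, and characterizes the central set against a protein-protein
interaction (PPI) network, pathway graphs, GO biological-process (BP)
annotations and gene-level features.

## Two-engine protein inference

**Merge.** PSM tables of the two engines are joined by spectrum.  A
spectrum assigned to *different* peptide sequences by the two engines is
removed entirely; agreeing assignments collapse into one record keeping
both scores.  The merge is therefore contraction-only: it never adds a
peptide to any protein.

**Acceptance rules (per engine, then union).**  A protein is accepted
when at least two distinct peptides exceed the engine's primary
threshold; all of its peptides above the lower "additional" threshold
are then exported.  Alternatively a single peptide hit (SPH) is
accepted above a much higher threshold, provided the peptide covers at
least 2.5% of the protein sequence.  Default thresholds: engine A (ion
score scale) 18 / 10 / 50; engine B (z-score scale) z ≥ 4.5 with
P ≤ 0.001 / z ≥ 3.5 / z ≥ 6.  Engines are evaluated separately on the
merged spectra and their acceptances are unioned, so one spectrum
contributes once to peptide counts.

**Grouping.**  Proteins with identical accepted-peptide sets form one
group; a protein whose set is a strict subset of another's is absorbed
into that group (Occam-style parsimony; when several maximal supersets
exist the tie is broken deterministically by sorted member ids).
Groups containing no peptide unique to them (no *specific* peptide) are
discarded; specificity is then recomputed among the survivors for
reporting.  Group coverage uses the longest member sequence as the
representative — deterministic and conservative.  An optional
splice-variant filter retains only groups whose members map to a single
gene.  Note that the splice filter interacts with absorption: a
shared-peptide protein absorbed into a group from a different gene
discards the whole group, which is the main source of planted-protein
loss (a few percent) in the synthetic pipeline, mirroring the small
discard rate such rules produce on real data.

**FDR calibration.**  Decoys are reversed-sequence matches carrying a
flag.  The group FDR is estimated as (decoy groups)/(target groups) —
the single reverse-database convention; the symmetric 2D/(T+D)
estimator is available as a switch.  Calibration runs the full
merge/threshold/grouping chain for each candidate threshold set on a
grid and returns the *least stringent* candidate whose estimated FDR
stays at or below the bound (default 0.25%); if none qualifies the best
achievable is returned with a failure flag.

## emPAI abundance and abundance classes

emPAI = 10^(N_observed/N_observable) − 1, where N_observable counts the
distinct tryptic peptides of the protein whose monoisotopic mass lies
in the instrument range (default 698–2370 Da).  Digest convention for
observability: cleavage after K/R except before proline, at most one
missed cleavage, minimum length 6 residues — matching the search
settings; all of these are parameters.  Detection is an identification
property: an accepted protein with no in-range peptide is still
detected, with emPAI 0.

Per-protein abundance over cell lines is the median emPAI across the
cell lines in which the protein was detected; absence is missing data,
not zero (otherwise proteins absent from some lines would collapse to
zero medians).  Classes, with quantile q = 0.25:

* **Top.CL** — top quantile of median emPAI among proteins detected in
  at most n_lines − 2 cell lines (5 of 7);
* **Low.C.Prot / Top.C.Prot** — bottom/top quantile within the central
  proteome.

Values tied exactly at a class boundary are excluded from the class, so
a nominal 25% class can hold slightly fewer members.

## Network topology

Five node measures: degree; betweenness (raw shortest-path counts with
even splitting among equal-length paths; the normalized ratio is a
flag, since distributional comparisons are invariant to the common
constant); clustering coefficient; k-core score (largest k such that
the node survives iterative degree-k pruning); eigenvector centrality,
computed on the largest connected component with unit 2-norm scaling
(other components get 0) to avoid the degenerate multi-component
eigenproblem — dense eigendecomposition below 1,000 nodes, sparse
above.  Shortest-path distance distributions are computed over
unordered cross-set pairs, with unreachable pairs tallied separately.
The power-law exponent is the OLS slope of log10 frequency versus
log10 degree over non-empty bins — a reporting convention matching
exponents read off distribution plots, not a maximum-likelihood tail
estimate (available separately if needed; at least three distinct
degrees are required).

## Pathway positions

Pathways are directed graphs; cyclic inputs are condensed to strongly
connected components first, so sources (in-degree 0) and ends
(out-degree 0) always exist, and every member of a component inherits
the component's position.  With d_s the shortest-path distance from the
closest source and d_e the distance to the closest end,

    position = d_s / (d_s + d_e)  ∈ [0, 1],

anchored at 0 for sources and 1 for ends.  An isolated single-node
component sits at 0.5.  A protein occurring at several nodes of a
pathway gets the unweighted mean of its node positions; occurrences in
several pathways are averaged again (two-level, unweighted).  Complex
nodes assign the node position to every member protein.  An
alternative metric — mean shortest-path length over *all* reachable
sources/ends instead of the closest — is available behind a flag and
tracks the default within 0.1 mean absolute difference on the synthetic
pathway graphs; reversing all edges maps every position p to 1 − p,
which serves as the internal consistency check of the formula.

## GO BP fluxes

For an edge between proteins annotated {A, B} and {C, D, E}, each of
the six unordered cross pairs receives one count; counts are summed
over edges.  Same-term pairs (A, A) count once per edge; pairs are
unordered (both switchable).  Before counting, each protein's term set
is pruned of terms that are ancestors (is-a transitive closure) of
another of its terms, leaving the most specific annotations and
avoiding re-discovery of the GO hierarchy.

The null model preserves node degrees and term frequencies individually
but decouples them: degree-preserving double-edge-swap rewiring (10 ×
|edges| accepted swaps) plus a uniform permutation of whole node→term-set
assignments across nodes.  Permuting whole sets preserves each term's
total frequency *and* the within-protein term correlation — the
stricter null, compared with resampling terms independently.
Membership labels stay on their nodes, whose degrees the rewiring does
not change.

With the first 90% of an ensemble of n randomized networks providing
per-pair means and standard deviations,

    NScore(i, j) = (flux(i, j) − mean_random(i, j)) / sd_random(i, j).

NScores of the held-out 10%, pooled over pairs, give the empirical
(1 − α) cutoff (α = 1% by default; a Gaussian fit to the held-out
scores is the alternative, the null being bell-shaped).  Pairs with
zero null standard deviation are excluded and reported.  Under a pure
null the expected number of significant pairs is α × (number of
evaluated pairs); for a 50-term vocabulary (1,275 unordered pairs
including same-term pairs) at the 1% level this is 12.75.

The analysis runs in three regimes with separate ensembles: edges
within the central set, edges between a central protein and a protein
detected in at most 5 cell lines, and edges outside the central set.
The three edge sets are pairwise disjoint; central-to-frequently-
detected-non-central edges belong to no regime.

## Bootstrapped chi-square comparison

To compare two value distributions without the oversensitivity of a
plain chi-square test at large n, the data are resampled (default 1,000
times, 500 points per set with replacement), binned into 10
equal-probability bins defined on the pooled subsample (equal-width
binning is a flag), and the two-sample chi-square statistic computed
per resample; the *median* statistic is referred to the chi-square
distribution with bins − 1 degrees of freedom (the df choice; the
reference distribution is part of the procedure's definition).

Calibration analysis: each resampled statistic decomposes into
multinomial resampling noise (expectation ≈ bins − 1) plus an
EDF-difference term that scales as (subsample / parent-sample-size) ×
χ²_{bins−1}.  Taking the median suppresses the spread of the first
term, so null p-values are *not* uniform; the rejection rate at
α = 0.05 is close to nominal when the parent samples are about twice
the subsample (≈1,000 points for the default subsample of 500), and the
procedure becomes rapidly conservative for larger parents — which is
precisely its purpose: damping trivially significant differences in
large samples.  The calibration test is run at parent size 1,000.  For
set association, membership indicators over a universe form a 2×2
table per resample (df = 1).

The length-matched bootstrap estimates a feature shift (e.g. exon
count) of a target set over a reference: the target's sequence-length
distribution is stratified into quantile strata (default deciles), each
draw samples matching counts per stratum from the reference with
replacement, and the shift is the observed target mean minus the
bootstrap mean, with a 95% percentile interval.  When the target is a
subset of the reference, the recovered shift is diluted by the target's
own weight in the reference (a planted shift s on a fraction f of the
reference recovers ≈ s·(1 − f)).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* the pipeline consumes, with
known ground truth: a proteome of tryptic-friendly random sequences
(every protein carries a 10-residue anchor peptide guaranteed to fall
in the default mass range); per-cell-line PSM tables for two engines
with Gaussian score distributions (targets: A ~ N(30, 7), B ~ N(6.5,
1.2); false matches: A ~ N(10, 5), B ~ N(2.5, 1.0)), a planted common
subset (default 30% of 1,000 proteins) expressed in all 7 cell lines,
four distinct true peptides per expressed protein per engine, a 10%
false-match rate split evenly between reversed-sequence decoys and
random target proteins (the standard target/decoy symmetry assumption),
and a 2% engine-disagreement rate; a preferential-attachment
interactome (heavy-tailed degrees, the planted central set on the
earliest and hence best-connected nodes) annotated with 1–4 BP terms
from a Zipf-like frequency vector, optionally with an enriched term
pair; connected source-to-sink pathway DAGs; and feature tables with
planted exon-count (+3.7) and ortholog (+5.9) shifts.

Not modeled: fragment spectra, retention times, mass-measurement error,
sequence homology beyond deliberate peptide sharing, correlated
annotations, or realistic pathway topologies.  Passing tests therefore
demonstrate the correctness and calibration of the *procedures* under
their stated assumptions, not performance on real mass-spectrometry
data.

## Problem sizes

Default synthetic scale: 1,000 proteins, 7 cell lines, ~38,000 PSM
rows, a 1,000-node / ~3,000-edge interactome, 30-network null
ensembles for the pipeline demo.  The FDR-control check runs 20 seeds
at the 1,000-protein scale; the null-calibration Monte-Carlo uses
300-node networks with 40-network ensembles; topology oracles are
verified exhaustively on 1,000 random graphs of at most 8 nodes.  The
full pipeline demo completes in well under a minute on one CPU at the
default scale.

## Known limitations

* Grouping absorbs a strict-subset protein into a single deterministic
  maximal superset; proteins that are subsets of several incomparable
  groups are not duplicated or flagged as ambiguous.
* The group-FDR estimate is a point estimate; no confidence statement
  accompanies the calibrated thresholds.
* The power-law exponent is a descriptive log-log regression slope, not
  a tail-index estimate.
* The bootstrapped chi-square P-value is interpretable as a fixed-level
  test only in the calibrated regime described above.
* Randomized ensembles must contain at least 12 networks so the 90/10
  split leaves both parts non-degenerate.
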