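# centralprot

Tools for constructing and characterizing a **central proteome** — the
set of proteins commonly identified across a panel of cell lines in
shotgun-proteomics experiments — and for profiling that set against
protein-interaction networks, pathways and Gene Ontology biological
processes.

The package is aimed at computational proteomics and systems-biology
practitioners who need a tested, reproducible implementation of this
analysis chain, together with synthetic-data generators that make every
stage verifiable against planted ground truth.

## What it computes

* **Two-engine protein inference.** PSM tables from two search engines
  are merged per spectrum (disagreeing spectra discarded), proteins are
  accepted with ≥ 2 distinct peptides above a primary score threshold
  or as high-scoring single-peptide hits with ≥ 2.5% sequence coverage,
  grouped by shared peptides (identical sets merged, strict subsets
  absorbed, groups without specific peptides discarded), and score
  thresholds are calibrated on a grid so the decoy-estimated
  protein-group FDR, `FDR = D/T`, stays below a bound (default 0.25%).
* **emPAI abundance and classes.** `emPAI = 10^(N_obs/N_obsbl) − 1`
  with `N_obsbl` the tryptic peptides in the instrument mass range
  (698–2370 Da); per-protein abundance is the median over detected cell
  lines; the central proteome is the intersection of the per-cell-line
  identification sets, and quartile classes (Top.CL, Low.C.Prot,
  Top.C.Prot) split proteins by median emPAI.
* **Interactome topology.** Betweenness, eigenvector centrality,
  degree, clustering coefficient and k-core score per node;
  shortest-path distance distributions between protein sets; induced
  "central interactome" subnetworks; power-law exponents from log-log
  degree histograms.
* **Pathway positions.** Relative position
  `d_s / (d_s + d_e)` of each node between pathway sources (0) and end
  points (1), averaged per protein within and across pathways, with
  positional profiles for protein sets (source 0–0.2 / center 0.4–0.6 /
  end 0.8–1 bins).
* **GO BP fluxes.** Co-occurrence counts of biological-process term
  pairs across PPI edges (ancestor-pruned annotations), standardized
  against ensembles of degree- and frequency-preserving randomized
  annotated networks:
  `NScore(i,j) = (flux(i,j) − mean_random(i,j)) / sd_random(i,j)`,
  with an empirical 1% significance cutoff from held-out null networks,
  in three regimes (within / at the boundary of / outside the central
  set).
* **Comparative statistics.** Bootstrapped chi-square distribution
  comparison (median of resampled statistics), length-matched bootstrap
  for exon-count/ortholog shifts, ortholog-species counting, 2×2 set
  association, GO term coverage.
* **Synthetic data.** Deterministic generators for every input —
  proteomes, two-engine PSM tables with planted common sets and decoys,
  scale-free annotated interactomes with planted flux pairs, pathway
  DAGs, feature tables with planted shifts — so all of the above is
  testable without external data.

## Worked example

Run the full pipeline on synthetic data at the default scale
(1,000 proteins, 7 cell lines, 1,000-node interactome):

```bash
centralprot run --out-dir demo --seed 0
```

which prints per-stage headlines:

```
synth: completed {'n_proteins': 1000, 'n_cell_lines': 7, 'n_common_planted': 300, 'n_psm_rows': 38506, 'n_nodes': 1000, 'n_edges': 2991}
infer: completed {'achieved_fdr': 0.0013172338090010978, 'fdr_passed': True, 'groups_per_cell_line': {'CL1': 643, 'CL2': 664, 'CL3': 647, 'CL4': 652, 'CL5': 638, 'CL6': 653, 'CL7': 664}}
abundance: completed {'central_size': 287, 'top_cl': 121, 'low_cprot': 68, 'top_cprot': 68}
topology: completed {'powerlaw_exponent_whole': -1.805225564843268, 'powerlaw_exponent_central': -1.8599110207132517, 'mean_distance_central': 3.4637070246826345, 'mean_distance_all': 3.470890890890891}
pathpos: completed {'n_positioned': 31}
goflux: completed {'within': 5, 'boundary': 1, 'outside': 1}
compare: completed {'exon_shift': 2.5535714285714293, 'drug_target_p': 6.34334654699961e-07}
```

Reading the numbers: 300 of the 1,000 proteins were planted as
commonly expressed; the calibrated thresholds achieve a decoy-estimated
group FDR of 0.13% (below the 0.25% bound) and identify ~650 protein
groups per cell line; the strict 7-line intersection recovers 287
central proteins (the planted set minus a few multi-gene shared-peptide
groups removed by the splice-variant rule), split into quartile classes
of 68; the degree distribution is scale-free (log-log slope ≈ −1.8);
5 BP-term pairs exchange significantly more flux than the randomized
null within the central interactome; and the central set shows an
exon-count shift of ≈ +2.6 over a length-matched background (the
planted +3.7 diluted by the common set's own 30% weight in the
reference) together with a strong drug-target association
(P ≈ 6e-7).

Every stage is also runnable standalone (`centralprot synth|infer|
abundance|topology|pathpos|goflux|compare`) against the same output
directory, and `centralprot run --config run.yaml` drives everything
from one YAML file.  Outputs are plain text (FASTA/TSV/GraphML/GMT/
JSON); re-running an unchanged configuration reproduces every file
byte-for-byte, and a `report.json` records per-stage parameters,
checksums and headline numbers.

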