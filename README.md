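# xenospot

Analysis toolkit for **xenograft ("barnyard") spatial transcriptomics** —
tissue sections containing a human cell graft embedded in host (pig)
myocardium, sequenced against a hybrid two-species reference — together
with the **cell-dose composition vs arrhythmia-burden** cohort statistics
that motivate such experiments in cardiac cell therapy.

It is aimed at analysts working with Visium-style spot data from
human-into-animal cardiomyocyte transplantation studies, where the
questions are: which spots are graft vs host, where is the graft–host
interface, what cell types make up the graft, which genes differ between
treatment conditions, and which cell-dose subpopulations predict
engraftment arrhythmia.

## What it computes

Given gene × spot counts with species-tagged features (`GRCh38_…` human,
`Sscrofa11-1_…` pig) and spot pixel coordinates:

1. **Species classification.** Per spot, a human score *h* (reads on
   human genes) and pig score *p* (reads on pig genes); a spot is human
   iff *h* > τ_h and *p* < τ_p (defaults 30 and 700, strict), with ≥ 80
   detected human genes required of human candidates and genes kept only
   if detected in ≥ 10 spots. τ_p can be chosen from the data as the
   valley between the two modes of the *p* density on the log scale.
   A PCA/silhouette report quantifies how cleanly the labels separate.
2. **Interface mapping.** A pig spot is *interfaced* (human-like) if it
   is among the *k* = 20 nearest neighbours of a human spot and closer
   than 1,500 px — the neighbourhood where graft–host signalling can act.
3. **Deconvolution.** Each human spot's counts are decomposed over
   reference cell-type profiles π (K × G, rows on the simplex) by
   maximising Σ_g y_g log(Σ_k w_k π_kg) over the weight simplex with EM;
   the predominant type is argmax_k w_k. A reference-free k-means
   clustering of the same spots gives an independent consistency check
   (adjusted Rand index after optimal coarse-graining).
4. **Pseudobulk DE.** Each condition's spots are pooled at random into
   three equal pseudo-replicates; per gene, a negative-binomial GLM with
   library-size offsets and a likelihood-ratio test compares conditions;
   dispersions are method-of-moments estimates shrunk 50/50 to the
   median; Benjamini–Hochberg controls FDR at 0.05.
5. **Cohort statistics.** Pearson/Spearman correlations (pairwise
   deletion, subjects reported) between arrhythmia burden (h/day) and
   flow-cytometry subpopulation percentages, and mean ± s.e.m. group
   summaries, over a packaged 16-subject per-subject table.

A synthetic-data generator produces hexagonal spot grids with a disk-shaped
graft, logistic graft-boundary mixing, negative-binomial counts,
configurable cross-species bleed-through, known per-spot cell-type weights
and planted fold changes — so every stage is scored against ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (`scratch/workspace/` is created by the first script):

```sh
python analysis/01_simulate_datasets.py     # standard + RA-like pair
python analysis/02_classify_species.py
python analysis/03_map_interface.py
python analysis/04_deconvolve.py
python analysis/05_pseudobulk_de.py
python analysis/06_cohort_correlations.py
```

which prints, among other things:

```
standard: 56/900 human spots, suggested tau_p 363.2, PCA silhouette 0.99
standard: 56 human / 73 interfaced / 771 pure pig spots
70 of 300 human genes at FDR < 0.05
top hits (log2FC, RA relative to standard):
HGENE0004  1.9030   0.0  0.0000
...
pscm_cd200pos: r = +0.81 (n = 4, p = 0.1932)
combined_cd200pos: r = +0.89 (n = 7, p = 0.007)
burden mean (sem) by group: {'PSC-CM': '8.7 (2.8)', 'PSC-CM+AA': '1.0 (0.3)',
 'PSC-CM+CA': '5.5 (4.4)', 'RA-PSC-CM': '15.5 (1.1)'}
```

Reading: of 900 spots, 56 are graft (human) — all five genes planted with a
4-fold RA shift top the DE table with log2FC ≈ 2 — and in the cohort table
the arrhythmogenic CD200⁺ cardiomyocyte percentage of the injected dose
correlates strongly with arrhythmia burden (r = 0.81 in standard-dose
recipients, r = 0.89 when atrial/pacemaker-enriched doses are added),
while the CD200⁻ fraction anticorrelates (−0.77 / −0.83).

The same stages are available as a CLI (`xenospot simulate | classify |
interface | deconvolve | de | cohort | run | demo`) and as one
YAML-configured pipeline (`xenospot run --config …`) that writes a JSON
manifest sufficient to reproduce every output byte-for-byte.

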