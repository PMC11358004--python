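# Methods

## Setting and data model

A xenograft spatial-transcriptomics section is a spot array over host
(pig) myocardium containing a human graft. Reads are assigned during
alignment to a hybrid two-species reference, so every feature carries a
species tag recoverable from its ID prefix (`GRCh38_` → human,
`Sscrofa11-1_` / `Sscrofa11.1_` → pig; the prefix table is configurable
because hybrid-reference builders differ in the separator they emit).
Counts are integer and are required to be — fractional input is rejected
rather than rounded. Spots flagged out-of-tissue in the positions file are
dropped at load; pixel coordinates are full-resolution, with
(x, y) := (pxl_col, pxl_row).

## Species classification

Per spot, the human score *h* and pig score *p* are the total reads on
human- and pig-tagged genes; they partition the spot's total. The label
rule is

    human  ⇔  h > τ_h  and  p < τ_p,

with both inequalities strict and defaults τ_h = 30, τ_p = 700 (τ_p is
sample-specific in practice). Quality control removes genes detected in
fewer than 10 spots (species-agnostic) and requires human-labelled spots
to have ≥ 80 detected human genes. Applying the 80-gene floor to *all*
spots would discard essentially every host spot — pig spots detect few
human genes by construction — so by default it gates only human
candidates (spots failing it fall back to pig); `apply_to="all_spots"`
instead marks sub-floor spots as excluded, for datasets where the floor is
meant as a global QC gate.

When τ_p is not supplied, `suggest_pig_threshold` fits a Gaussian KDE
(Silverman bandwidth, configurable) to log10(1 + p) over all spots and
returns the antilog of the deepest local minimum between the two largest
modes. In a barnyard section the pig-score density is bimodal — a graft
mode near zero and a host mode near the library size — and the valley is
the natural cut. If the density is unimodal the function returns nothing
and the caller must choose; the pipeline aborts with an explicit message
rather than guess.

`species_pca_check` projects log1p counts-per-10k (all genes) onto the
first two principal components and reports the silhouette coefficient of
the labelling — a report-only diagnostic, never fed back into
classification.

## Interface mapping

A pig spot is *interfaced* when it lies among the k = 20 nearest
neighbours (Euclidean pixel distance) of at least one human spot and
strictly closer than d_max = 1,500 px. Neighbour search is exact
(all-pairs with lexicographic (distance, barcode) ordering), so results
are deterministic; ties cannot silently change the set. The neighbour pool
defaults to all spots — human spots may occupy neighbour slots — with a
`pig_only` variant for the alternative reading; the choice matters only
in dense mixed regions. The interfaced set grows monotonically in k and
d_max and is invariant to rigid motions of the coordinates, both of which
are property-tested.

## Deconvolution

Each human spot holds roughly 1–9 cells, so its counts mix cell types.
Given reference profiles π (K × G, each row a probability vector over
genes, typically derived from a matched scRNA-seq atlas), the weights w on
the simplex are the multinomial maximum-likelihood estimate, obtained by
EM multiplicative updates

    w_k ← w_k · Σ_g (y_g / N) π_kg / (Σ_j w_j π_jg)

from a uniform start, stopping at max|Δw| < 1e−6 or 500 iterations. The
objective is concave along the EM path and never decreases (asserted in
tests per iteration). Genes with zero probability in every profile are
dropped; remaining zeros are floored at 1e−12. This is the
Poisson/multinomial core of reference-based decomposition without
platform-effect or doublet terms: with a reference matched to the same
platform those terms are unidentifiable, and on synthetic data they are
unnecessary. Argmax ties are broken by cell-type list order.

The independent check clusters the same spots with seeded k-means
(log1p counts-per-10k, all genes) into 2–3 broad categories and scores
agreement with the predominant types by adjusted Rand index, maximised
over type→cluster coarse-grainings (exhaustive for K ≤ 8, greedy beyond).
When a graft is compositionally homogeneous every spot shares one
predominant type and the ARI is 0 by construction — reported as
uninformative rather than as disagreement.

## Pseudobulk differential expression

With one section per condition there are no biological replicates; spots
measured independently across a section stand in. Each condition's spots
are partitioned uniformly at random (seeded, membership recorded) into
m = 3 pools whose sizes differ by at most one — the remainder is spread
round-robin so no spot is discarded — and aggregated per gene. Mean
aggregation is multiplied back by pool size before model fitting (giving
the pool sum, a genuine count, equivalent to sum aggregation up to
size-factor rescaling); a count model cannot take averages directly.

Size factors are pool totals over their geometric mean. Per gene, a
negative-binomial GLM with a condition factor and log-size-factor offset
is fitted by a damped Newton solver vectorised across genes (the
log-likelihood is concave in the log-mean), and the condition effect is
tested by likelihood ratio against χ²₁. Dispersions are per-gene
method-of-moments estimates shrunk 50/50 toward the across-gene median —
a deliberately simple, dependency-free stand-in for empirical-Bayes
machinery that is adequate at m = 3, where per-gene dispersion is barely
estimable anyway. The quasi-likelihood F-test was not used because its
residual-df machinery is underdetermined at 3 vs 3 pools; the all-null
simulation in the test suite is the check that this combination still
controls the error rate (flagged fraction ≈ 0.001 at nominal 0.05).
P values are Benjamini–Hochberg adjusted; genes all-zero in both
conditions get NA and do not enter the ranking.

One caveat the simulations expose: planting large fold changes in a few
genes shifts library composition, so purely library-size normalisation
attributes a small opposite shift to all other genes (TMM-style
trimmed normalisation, which would absorb this, is out of scope). The
planted genes themselves are recovered with log2FC ≈ 2 and rank first.

## Cohort statistics

The packaged per-subject table (16 cell-treated subjects in four groups)
stores every printed value verbatim, with "N/A" cells explicit as missing.
Correlations use pairwise deletion and report exactly which subjects
entered; two-tailed p comes from the t transform t = r√(n−2)/√(1−r²).
Group summaries are mean ± s.e.m. (sd with n−1 over non-missing values).

The four headline correlations relate arrhythmia burden to the CD200⁺
(arrhythmogenic, atrial/pacemaker-like) and CD200⁻ cardiomyocyte
percentages of the injected dose: first over standard-dose recipients
alone (n = 4 — the fifth subject's flow row is missing and drops out
pairwise), then with the three RA-treated (atrial/pacemaker-enriched)
recipients added (n = 7). Anti-arrhythmic-treated subjects are always
excluded (drug suppression confounds the burden measurement); the
ablation-treated group is excluded by default for the same reason, with
`include_ca=True` available — the n = 4 subset is the one that reproduces
the 0.81 / −0.77 pair, which a brute-force check over candidate subsets
confirms is unique.

Known source discrepancy: the table's standard-dose "graft size (% of LV)"
summary row prints 6.4 (0.8) while its per-subject entries (1.9, 3.8, 0.4,
0.3) average 1.6. The fixture keeps the per-subject values, so computed
summaries give 1.6; the discrepancy is flagged here rather than resolved.

## Synthetic-data generator

`simulate_xenograft_dataset` emulates the assumed data-generating process:

- **Geometry.** Hexagonal offset grid (odd rows shifted by pitch/2, row
  spacing pitch·√3/2), default 30 × 30 at 250 px pitch — nearest-neighbour
  distance equals the pitch, so distance-based interface detection is
  exercised on realistic packing. The graft is a disk (default radius
  1,000 px) centred slightly off the grid's symmetry axes, since a real
  graft never aligns with the capture array and exact alignment creates
  degenerate boundary ties.
- **Mixing.** The true human read fraction is
  f_h = logistic((R − d)/s) of the distance d to the graft boundary, with
  transition width s = 5 px — sharp at spot scale, encoding a barnyard
  design in which nearly all spots are species-pure and cross-species
  signal comes from mis-mapping rather than physical mixture. Spots with
  genuinely intermediate area overlap are therefore *under*-represented
  relative to real sections; accuracy numbers should be read accordingly.
- **Counts.** Human reads mix cell-type profiles with per-spot Dirichlet
  weights (concentration 50 about the configured proportions); pig reads
  follow a log-normal background profile. Counts are negative-binomial
  (gamma–Poisson, dispersion 0.05) at expected depth 5,000 UMIs/spot.
- **Bleed-through.** Each gene is paired with a fixed "homolog" of the
  other species; a Binomial(count, ε) portion of its reads is re-labelled
  to the partner (ε = 0.005 by default), conserving per-spot totals —
  homolog mis-mapping without simulating alignment. With ε = 0 a pure
  spot's cross-species score is exactly zero.
- **Planted effects.** Listed (gene, condition, log2FC) entries multiply
  that gene's expected counts by 2^lfc in the named condition.
- Reference profiles share one log-normal baseline per gene with disjoint
  8× marker blocks per type (20 genes each by default), so markers stand
  ≥ 4× above any other type.

`simulate_cohort` draws each group's seven-part flow composition from a
scaled Dirichlet (concentration 40) around group means resembling a
ventricular-directed vs an atrial/pacemaker-enriched dose, and sets
burden = max(0, a + b·CD200⁺% + N(0, σ_c)) with defaults a = 1 h/day,
b = 0.3 h/day per percentage point, σ_c = 2 h/day. Truncation at zero is a
physical constraint (burden is hours/day) and slightly biases correlations
when σ_c is large relative to a; the perfect-correlation contract at
σ_c = 0 therefore refers to the recorded untruncated latent.

What the generator does **not** emulate: spatial autocorrelation of
expression beyond the boundary mixture, UMI collisions, segmented or
multi-focal grafts, per-spot depth gradients, and real homolog similarity
structure (the pairing is by index). Passing tests demonstrate
correctness of the algorithms under the stated model, not performance on
any particular tissue section.

## Problem sizes and numerical choices

The test suite and reproduction script run everything at the generator's
default scale — 30 × 30 spots, 300 + 300 genes, depth 5,000 — with 10
seeds for accuracy measurements, 50 replicates for the all-null DE
simulation, 10 for power, and 200 simulated cohorts for slope recovery;
the full suite completes in well under a minute per statistical block on
one CPU. EM tolerance 1e−6 (max weight change); NB Newton steps clipped
to ±2 with the log-mean bounded in ±30; dispersions floored at 1e−12 so
the Poisson limit is exact to numerical precision (the deviance is
computed via log1p to avoid cancellation at large 1/φ). Empty spots,
all-zero genes, single-type references (K = 1) and unimodal score
densities are all explicit, tested degenerate cases rather than silent
paths.
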