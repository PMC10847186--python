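# Methods

## The problem

Single-cell RNA-seq studies define cell subpopulations — here, neutrophil
subsets — by published marker-gene panels. Many such panels are not actually
specific: the same genes are elevated in several subsets, so a panel that
nominally defines one population will light up in others and corrupt the
annotation. `panelscope` quantifies that risk. For every panel it measures
an **over-expression rate (OER)**: the percentage of co-evaluated cell
populations whose summarized panel expression exceeds graded cutoffs derived
from the panel's *own* population's expression range, and classifies the
panel as **specific**, **associate**, or **reference** (decreasing
trustworthiness as a clustering criterion).

## The procedure

Inputs: a cells × genes count matrix with per-cell subset labels and sample
ids, and a registry of named gene panels (GMT; gene tokens may carry
`(low)`/`(high)` direction suffixes).

1. **QC.** Cells are kept when detected genes (count > 0) lie in
   [500, 7000] and the mitochondrial count fraction (genes with a `MT-`
   prefix by default) is at most 20%. All three bounds are inclusive
   because the stated exclusion criteria are strict inequalities ("less
   than 500", "more than 7000", "more than 20%"). "Detected" is the
   standard count > 0 reading; the mitochondrial prefix is configurable
   since no gene list was specified.
2. **Normalization.** Per-cell library-size scaling to 10,000 followed by
   log1p — the default of the Seurat/scanpy tool family, used because the
   upstream procedure names only "normalized" without details. Raw counts
   are preserved in a `counts` layer.
3. **Detection.** A cell is panel-positive iff *every* high-direction panel
   gene has expression above `positive_min` (default 0, on raw counts:
   "positive" = detected transcript). A panel is detected in a subset when
   its positive-cell proportion strictly exceeds `positivity_threshold`.
   The default 0.10 is a deliberately conservative round value — the source
   procedure acknowledges a threshold but never prints one, and warns that
   lowering it reduces specificity. Low-direction genes are excluded from
   the positivity rule and from scoring because no convention exists for
   folding negative markers into either; both behaviours are configurable.
4. **Scoring.** Per-cell panel score = mean log-normalized expression over
   the panel's high-direction genes. Each detected panel defines one
   population in the evaluation universe: the cells of the subset where its
   positivity is highest. N, the *total subset number*, is the number of
   detected panels and is shared by all profiles of a run. Within the own
   population the highest per-cell score is Q3 and the lowest is Q1 (the
   literal reading of the procedure; a 75th/25th-percentile mode exists
   behind `quartile=True` because the names suggest quartiles).
5. **Cutoff ladder.** `cutoff(k%) = (Q3 − Q1)/10 × (k/10) + Q1` for
   k ∈ {10, …, 60}. When Q1 = Q3 the ladder collapses; the profile is
   flagged degenerate and populations split into "<10" (s ≤ Q1) and ">60"
   (s > Q1).
6. **Binning.** Every population j — the own population included — is
   summarized by its mean per-cell score s_j and assigned to exactly one of
   {<10, 10–20, 20–30, 30–40, 40–50, 50–60, >60} by the strictly-greater
   rule (a score exactly equal to a cutoff stays below it). Self-inclusion
   is required to reproduce the published reference table: a perfectly
   specific panel shows 31/32 populations below cutoff(10%) and its own
   population (3.12% = 1/32) in ">60". Because the own population is
   summarized by its *mean* (< its max = Q3), it can legitimately land
   below ">60"; `force_self_top=True` pins it there instead.
7. **OER.** OER per bin = 100 × count / N, rounded half-to-even to two
   decimals — the only rounding consistent with every printed reference
   value (96.875 → 96.88, 3.125 → 3.12, 21.875 → 21.88, 9.375 → 9.38).
   Cumulative n_>30 and n_>60 are summed on raw integers before the single
   rounding. Per-population SEMs are computed and reported but do not enter
   the binning.
8. **Classification.** With threshold T on the cumulative counts:
   specific ⟺ n_>30 < T; associate ⟺ not specific and n_>60 ≤ T;
   reference otherwise. The default T = floor(0.1·N) ("count" mode). The
   literal formula T = 0.1·N ("exact" mode) is available, but at N = 32 it
   would call a panel with n_>30 = 3 specific (3 < 3.2), contradicting the
   published table membership (such a panel is printed as associate); the
   integer threshold reproduces the published 10/3/19 split exactly. The
   two modes differ only when n_>30 = floor(0.1·N).
9. **Resolution and proportions.** When several detected panels compete for
   a subset, the most specific one wins: smallest n_>30, ties by smallest
   n_>60, then lexicographic name (deterministic and order-invariant).
   Per-sample panel proportions follow from the exclusive assignment.
10. **Group comparison.** Per-panel two-sided rank-sum test on per-sample
    proportions. For total n ≤ 10 samples an exact tie-aware permutation
    enumeration is used (identical groups give p = 1.0 exactly; 3 vs 3
    fully separated gives p = 0.1); larger designs use the normal
    approximation with tie correction. No multiplicity correction by
    default, with an optional Benjamini–Hochberg flag.

## The bundled reference table

The 32-panel healthy-peripheral-blood OER table ships with the package as
the canonical regression surface (percentages as printed, N = 32). Bin
counts are reconstructed as `round(OER × 32 / 100)`; recomputing OER from
those counts reproduces all 256 printed cells exactly, and classification
yields 10 specific, 3 associate, 19 reference panels. Two rows
("IFNactive neutrophils", "SPP1_Neu") are internally inconsistent in the
source: their printed percentages sum to 96.87%, leaving one population
unaccounted, so their reconstructed counts sum to 31; `compute_oer` accepts
these in non-strict mode for auditing while the pipeline itself always
produces strict profiles. The companion GMT file carries only the 32 panel
*names* with synthetic placeholder gene lists (the real member lists are in
non-redistributed supplementary material); it exists for name-level
plumbing and must not be used to score real data.

## The synthetic generator

Counts are negative binomial with mean μ0 · FC^(gene planted for the cell's
subset) · lib and variance μ + μ²/φ, where lib is a per-cell log-normal
factor with unit mean. Defaults, chosen once as the package's reference
study conditions:

| parameter | default | rationale |
|---|---|---|
| subsets | 32 × 200 cells | cohort size at which the specificity call is attainable; matches the reference evaluation's N = 32. The classification threshold floor(0.1·N) must exceed the one bin the panel's own population always occupies, which structurally requires a few tens of co-evaluated panels — small cohorts (e.g. 7) can never yield a specific call. |
| panels | one 3-gene panel per subset, fold-change 50 | one expressing subset per panel; FC 50 is the strong-signal condition of the recovery study |
| μ0 | 1.5 | background per-gene detection probability ≈ 0.67, so 3-gene panels stay detectable genome-wide (all-positive ≈ 0.30 > 0.10) and QC remains meaningful |
| φ | 2.0 | strong over-dispersion typical of UMI counts |
| σ_lib | 0.3 | moderate library-size spread; ~10% of cells drop below the 500-gene QC bound, exercising the filter |
| n_genes | 900 | scaled-down gene space (real data have ~20k genes); chosen so background detected-gene counts (~600) sit inside the stated 500–7000 QC window |

Multi-sample studies draw per-sample subset proportions from a Dirichlet
centred on group-level base proportions (concentration 200), with optional
per-group multiplicative shifts, then multinomial subset sizes; counts per
sample reuse the NB model with per-sample child seeds. `counts=False`
returns only the ground-truth proportion table for cheap null/power
calibration.

**What the generator does not emulate** — batch effects, ambient RNA,
doublets, realistic gene–gene correlation, skewed library-size tails, or
panels with partially overlapping gene sets. Passing simulation tests
therefore demonstrates that the arithmetic and the classification logic
behave as specified under a clean NB world, not that the thresholds are
robust on real tissue atlases.

## Numerical choices and degeneracies

- Percentages: decimal (not binary-float) half-to-even at two decimals.
- Bin ties: strictly-greater everywhere; a score equal to a cutoff stays in
  the lower bin.
- Resolution ties: (n_>30, n_>60, name) lexicographic.
- Zero detected panels, empty subsets, zero-count cells, undetectable
  panels, and cycle-containing hierarchies are hard errors, not warnings.
- QC removing every cell raises and names the dominant exclusion reason.
- Determinism: every stochastic path takes a single integer seed; repeated
  runs are byte-identical.

## Problem sizes

The recovery study runs 100 seeds per condition at 6400 cells × 900 genes
(~1 s per run); the analysis drivers use 25 seeds to stay interactive. The
null calibration of the group test uses 200 proportion-level entities with
7 vs 7 samples, where the large-sample p-values are continuous enough for a
Kolmogorov–Smirnov uniformity check.

## Known limitations

- The positivity threshold (0.10) and the positivity layer (raw counts) are
  package defaults for knobs the source procedure leaves unstated; both are
  exposed in the config and results can shift if they are changed.
- Cross-dataset OER harmonization, probabilistic per-cell assignment,
  differential-expression-based panel discovery, and batch integration are
  out of scope; multi-sample inputs are analyzed with `sample` as a
  grouping covariate only.
- With very few co-evaluated panels (N < 10) no panel can be classified
  specific under either threshold mode; the package reports the classes it
  computes rather than guessing.
- Proportions are compositional: planting an enrichment in one subset
  necessarily depresses the others, so group comparisons on simulated
  cohorts show compensatory signals in unshifted panels.
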