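# Methods

## Screen model and assumptions

`opscreen` analyses colony-array screens in which a query perturbation
(an overproduction plasmid: empty vector, GFP-op, tGFP-op or NES-tGFP-op)
is combined with an arrayed mutant collection and fitness is read out as
colony size on dense agar plates.  The analysis assumes:

- four adjacent colonies per strain, pinned as a 2×2 block, with the whole
  experiment duplicated (`rep1`/`rep2` are independent pinnings);
- two media conditions (`ura_minus`, `leu_ura_minus`) controlling plasmid
  copy number and hence overproduction dose;
- colony size is proportional to strain fitness times smooth multiplicative
  plate artifacts (print gradients, nutrient bowls, edge growth advantage)
  times positive, right-skewed measurement noise;
- the query fitness `W_B` is absorbed into the per-plate normalization and
  fixed at 1, making the interaction score additive:
  `ε = W_AB − W_A · W_B = W_AB − W_A`.

## Normalization chain

Raw pixel sizes are converted to fitness `W` in plate-median units ("U",
interior plate median = 1) by a fixed-order chain:

1. **Plate-median scaling.**  All sizes divided by the median over
   *interior, present, non-marker* colonies.
2. **Row/column median polish.**  Alternating division by row and column
   medians (computed over the same support) until all medians are within
   `polish_tol` (default 1e-9) of 1, at most `polish_max_iter` (20)
   rounds.  Removes separable print/nutrient gradients exactly.
3. **Moving-median spatial correction.**  Each size divided by the median
   of its `window`×`window` (default 7×7) neighborhood, truncated at
   plate borders.  Cells belonging to the center colony's own replicate
   group are excluded from its neighborhood: with quadruplicate 2×2
   pinning a strain's own colonies otherwise vote on its local reference
   and bias real effects toward zero (we measured ~15% attenuation of a
   planted ε = −0.3 without this exclusion).
4. A closing plate-median scaling restores the interior median to exactly
   1, since stages 2–3 preserve it only approximately.

The outer `edge_depth` (default 2) rows and columns never contribute to
any median: on 1536-format arrays they hold border controls and show a
systematic growth advantage.  Marker-pathway (his/lys/arg) colonies are
likewise excluded from every median because their sizes reflect selection
carryover, not fitness.  The stage order is fixed, not configurable:
reordering changes results and would silently fork analyses.

The chain is idempotent (re-application is a no-op to machine precision)
for separable row/column artifacts on homogeneous plates; for radial
artifacts and heterogeneous baselines, re-application perturbs sizes at
the residual-curvature level (~1e-4), which is why the idempotence test
exercises the separable case.  A contiguous run of true hits spanning most
of an array row is indistinguishable from a row artifact and is polished
away — real collections interleave mutants, and the generator's scattered
planting reflects that.

## GI scoring and calling

Per condition and experiment replicate, `ε = W_AB − W_A` pairs each
mutant's overproduction fitness with its vector-control fitness.  Records
with vector `W` below `dead_floor` (default 0.05 U) are dropped: epistasis
is not measurable on no growth.  The threshold matters only for strains
near death; marker strains (carryover W ≈ 0.1–0.35) deliberately survive
it so the downstream carryover filter, not the dead floor, removes them.

**Confidence.**  The screen's published record does not specify its
p-value computation beyond requiring that it reflect both local colony
variability and array-wide strain variability; we fix a variance-floored
Welch test.  For colony samples of the op and vector plates (n ≥ 2 each),
each sample variance is floored at the across-array median per-strain
colony variance for the same construct and condition before forming the
Welch statistic with Welch–Satterthwaite degrees of freedom, two-sided.
The floor operationalizes "array-wide variability": quadruplicates that
agree by chance cannot manufacture significance.  An exact label-
permutation oracle (`permutation_pvalue`, all C(8,4)=70 reassignments for
4+4 colonies) is kept in the package as the independent small-sample
check; the two routes are rank-concordant wherever the discrete
permutation null can distinguish cases.

**Calling.**  A mutant is called when both replicate ε pass the threshold
on the same side (symmetric ±0.08 by default; +0.16/−0.12 for the
tGFP-based constructs, following the asymmetric convention established for
those screens) and both p-values are < `p_max` (0.05).  Discordant signs
are never averaged into a call — averaging them would manufacture spurious
intermediate scores.  `eps_mean` exists only for called records;
`|eps_mean| > 0.2` under −Leu/Ura defines the strong sets used for
interpretation and enrichment.

Reproducibility reporting computes Pearson r between duplicates over three
nested subsets (all complete pairs; both p significant; both |ε| past
threshold) and between conditions over called records present in both.

## Fluorescence (GFPunit)

Per plate and channel, colony medians are divided by the plate arithmetic
mean of medians ("plate average median" read as the mean; a
median-of-medians variant is available via `plate_statistic="median"`).
The per-colony ratio F488/F532 then cancels colony biomass, and the first
two present colonies of each strain (row-major order, matching the
two-colony measurement design) are averaged.  Per-plate per-channel
scanner gains cancel exactly — this invariance is asserted in tests.  The
GFP_L/GFP_H split is strict-below vs at-or-above the per-construct mean;
ties classify high because GFP_L is defined by "lower than average".
F532 is treated purely as a biomass normalizer; no spectral cross-talk
correction is applied (none is modeled).

## Classification, clustering, enrichment

The quadrant interpretation is the total map {(negative, GFP_L) →
sensitive_to_overproduction, (negative, GFP_H) → production_enhancing,
(positive, GFP_L) → production_reducing, (positive, GFP_H) →
resistant_to_overproduction}.  The carryover filter retains positive calls
only when vector-control `W` is strictly greater than 0.39 U (the rule is
strict because the cut was set at the largest carryover colony observed);
it applies to positive calls only, since carryover inflates only apparent
positives.  Fitness-advantage candidates are positive∩GFP_H strains with
vector `W` above mean + 1 sd of the vector distribution (the source
analysis says only "higher than other strains"; mean + 1 sd is our
default, exposed in config).

Profiles over (GFP, tGFP, NES_tGFP) are clustered with average-linkage
hierarchical clustering on Euclidean distances, cut into exactly k = 15
clusters.  The distance metric is our choice (only the linkage is
specified by the screen's convention) and is configurable.  Strains called
in ≥ 1 construct enter; a scored-but-uncalled construct contributes ε = 0
(no measured interaction) with an `imputed_*` flag; strains unscored in
any construct are excluded.  Rows are sorted by strain id before linkage
and clusters relabelled by their lexicographically smallest member, making
the assignment invariant to input order.

Enrichment uses the hypergeometric upper tail `P(X ≥ k)` accumulated in
log space (logsumexp of log-pmf terms), exact at the support boundary, with
Benjamini–Hochberg FDR across the tested family.  The universe defaults to
the strains actually scored in the relevant screen — only a scored strain
could have been called — and multiple alleles of one gene collapse to the
gene by default (`gene_level=False` switches to allele-level counting).
Terms with fewer than `min_term_size` (3) universe genes are dropped.

## Synthetic-screen generator

`simulate_screen` builds the screen the analysis assumes: strains in 2×2
blocks inside a 2-deep border of control colonies on 32×48 plates (308
mutant strains per plate), expected normalized size
`clamp(W_i + ε_{i,c,d}, 0)` (interactions planted additively, matching the
additive form of the score with `W_B = 1`), multiplied by a linear-in-row ×
linear-in-column × radial-bowl gradient field, an edge factor on the outer
two rows/columns, log-normal multiplicative noise, and a global pixel
scale.  Duplicate experiments re-sample noise only.  Marker strains get
carryover-level vector growth (uniform 0.08–0.35 U) plus an artifact boost
on op plates so they surface as false positives for the carryover filter
to remove.  `simulate_fluorescence` adds F532 = biomass × per-plate gain ×
noise and F488 = g_true × biomass × gain × noise.  Colonies of one strain
are adjacent on purpose — spatially correlated neighbors are the hard case
for the moving-median correction.

`paper_shaped_scenario` mirrors the study design: ~4,323 deletion-like +
~1,016 TS-like strains, three op constructs + vector, both conditions,
duplicates, a negative-skewed planted spectrum on ~3% of strains per
construct with 20% of hits shared across constructs (burden-like common
processes), condition-correlated effects (ε_low-copy = 0.7·ε + N(0, 0.06)),
1% marker strains, continuous reporter-expression spread (log-normal,
sd 0.15) with an 8% left tail of production reducers, and 5% colony and
fluorescence noise.

**What the generator does not emulate:** pinning failures beyond uniform
dropout, batch effects between plates of one run, agar drying fronts,
neighbor competition (big colonies starving small ones), saturating camera
response, spectral cross-talk, or biological pathway structure beyond the
planted sets.  Passing tests therefore demonstrate correctness of the
analysis under the stated noise model, not robustness to every real-world
artifact; replicate correlations on synthetic screens are accordingly
higher than those observed in real data.

## Numerical choices and degenerate inputs

- Medians over even counts are the usual midpoint average; "interior
  median exactly 1" holds to the last closing plate-median division.
- Zero-variance Welch inputs: equal means give p = 1; unequal means with
  zero floored variance give p = 0 (the floor is positive in practice).
- `gfp_unit` drops colonies with zero F532 (warn) and is undefined when no
  colony survives; classification requires ≥ 2 defined units per
  construct.
- Rows/columns or neighborhoods with no median support leave their cells
  uncorrected; all-absent interior is a hard error naming the plate.
- Hypergeometric inputs at or below the support minimum return exactly 1.
- All output tables are sorted on identity columns and floats rendered at
  fixed precision, so identical inputs yield byte-identical files.

## Problem sizes

Tests run one-layout-plate screens (308 strains) for unit-level checks;
the call-calibration check uses 4,000 strains (13 layout plates,
vector + GFP, one condition, duplicates — 52 plates of 1,536 positions)
with 200 planted |ε| = 0.3 interactions and an equally sized null screen;
the end-to-end paper-shaped run in `scripts/acceptance.py` uses 1,232
strains (a 4.3:1 deletion:TS mix) across all four constructs, both
conditions and duplicates (64 plates).  These sizes keep the full suite
and the acceptance script in the minutes range on one CPU while exercising
every code path at realistic plate density.
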