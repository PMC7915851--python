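# Methods

This note documents the statistical procedures, the generative model
behind the synthetic cohorts, the numerical choices, and the known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design and data model

The package targets a three-group observational design — restricting
anorexia nervosa (ANR), binge-purge anorexia nervosa (ANBP), healthy
controls (CTRL) — with two paired feature tables per cohort: 16S OTU
counts with Greengenes-style six-rank lineages, and GC-MS
semi-quantitative metabolite peak areas with an internal-standard column.
All in-memory matrices are samples × features; group labels require at
least two samples per group. The canonical cohort has 17/6/20 samples,
150 taxa and 224 metabolites.

## Synthetic cohort generator

The generator exists so that every downstream stage has a ground truth to
be scored against.

**Taxa.** A baseline composition π is drawn log-normally (σ = 1.5) and
normalised. For group *g* the planted taxa's baseline entries are
multiplied by 2^lfc and the composition renormalised; per sample,
p ~ Dirichlet(θ·π_g) with concentration θ = 200 (overdispersion in the
range of Dirichlet-multinomial fits to real stool data), and counts are
Multinomial(depth, p) with depth uniform on [5000, 15000]. Planted taxa
are pinned at a 2% baseline proportion: the taxa a differential-abundance
stage is expected to flag are percent-range community members, and
leaving their baseline to the log-normal draw would confound effect
recovery with rare-taxon detection limits.

**Metabolites.** Peak areas are log-normal around μ_m·2^lfc_g with noise
σ = 0.4 (natural-log scale), multiplied by a per-sample injection factor
(CV 0.25) that also forms the internal-standard column — so
internal-standard division exactly removes it. The default planted set
mirrors the direction mix of the published selection pattern for this
design: about two-fifths of planted metabolites move in opposite
directions in the two AN subtypes, the rest are decreased in both with
one subtype lower, at |log2FC| between 1.5 and 3. The opposite-direction
pairs are what make the AN subtypes mutually separable rather than
merely separable from controls. No missingness is simulated by default;
optional left-censoring at a detection quantile is available.

**What the generator does not emulate:** chromatograms, retention-time
drift, batch effects, compositional correlation between taxa beyond the
Dirichlet coupling, taxon-metabolite causal links. Passing recovery
tests therefore demonstrates the statistical machinery under the stated
moment structure, not performance on any real cohort.

## Preprocessing

Metabolites: divide by the internal standard, replace zeros by half the
smallest positive value of that metabolite, take the natural log, then
autoscale each column (mean 0, sd 1, n−1 denominator). The log precedes
autoscaling by necessity: autoscaled data contain negatives on which a
log is undefined. Constant columns are centered, left unscaled, and
flagged. OTUs: rarefaction (seeded multivariate-hypergeometric
subsampling to the minimum sample depth by default; shallower samples
dropped), relative abundance, and lineage-prefix aggregation with empty
ranks pooled as `unclassified_<parent>`. Every processed table carries a
transform record whose replay reproduces it bit for bit.

## Diversity

Chao1 uses the bias-corrected form (finite at F2 = 0). Pairwise group
tests on Chao1 are two-sided Welch t-tests, reported raw — a small
number of planned comparisons, matching the convention of reporting
unadjusted diversity p-values. NMDS minimises Kruskal stress-1 by
alternating isotonic regression of disparities on dissimilarity ranks
with SMACOF updates; defaults are 20 random starts, 300 iterations,
tolerance 1e-7; stress decreases monotonically within a start and the
best start is kept. PERMANOVA uses the standard partition of squared
distances; p = (1 + #{F_perm ≥ F_obs})/(B + 1) with B = 999 by default,
or the exact fraction over all distinct labellings in exhaustive mode.

## LEfSe-style differential abundance

Clades at all ranks (phylum→genus, per-sample scale 10⁶) are screened by
Kruskal-Wallis at α = 0.05. Survivors get an LDA effect size: the
enriched group (largest mean) versus the rest, 30 bootstrap rounds at
2/3 subsampling (a round needs ≥3 samples per side), effect =
log₁₀(mean of (|projected mean difference| + |raw mean difference|)/2),
floored at 1 before the log. A clade is reported at effect ≥ 2.0 and
screen p < 0.01. The subclass (within-group strata) stage of the
original tool is omitted — this design has no strata. Note the display
threshold p < 0.01 is unreachable below roughly n = 11 (the
Kruskal-Wallis statistic is bounded at small n), which the tiny test
fixture respects by asserting on effect sizes only.

## PLS-DA, VIP, cross-validation, permutation test

NIPALS PLS2 against the centered one-hot class matrix (Y is centered,
not variance-scaled). Per component the weight vector iterates to the
dominant eigenvector with tolerance 1e-10; X and Y are deflated by the
score outer products; coefficients are B = W(PᵀW)⁻¹Cᵀ and a sample is
assigned to the argmax class of the predicted Y row (ties to the lowest
class index, logged). Score vectors are mutually orthogonal and weight
vectors unit norm; predictions agree with an independent NIPALS
implementation to 1e-6 on random instances.

VIP scores use the explained-Y-variance weighting; they satisfy
Σ_j VIP_j² = p exactly, so 1 is the indifference level and 1.5 the
selection threshold. Cross-validation is stratified 5-fold × 10 repeats
(degrading to leave-one-out when the smallest class cannot fill the
folds); Q²(A) = 1 − PRESS(A)/SS_tot with PRESS pooled over folds and
repeats, R²(A) from the full fit, accuracy pooled out-of-fold; the
chosen A maximises Q². The permutation test reruns the full CV on B
relabelings; p = (1 + #{≥ observed})/(B + 1). Accuracy is the default
statistic for reporting; for calibration studies Q² is preferable
because accuracy's heavy ties at small n make the lattice p-values
conservative rather than uniform.

## MetaCost and the genetic algorithm

The cost matrix charges errors by inverse class size, C(i,j) = n_max/n_j
off-diagonal — with 17/6/20 the off-diagonal columns are (1.18, 3.33,
1.0) — making mistakes on the six-member ANBP group weigh most. MetaCost
trains m = 30 bagged PLS-DA models on resamples of 0.67n, averages hard
votes into P(j|x), and relabels each training point to argmin_i Σ_j
P(j|x)C(i,j); the final model is a plain PLS-DA on the relabeled data.
Votes are pooled over **all** models by default. The out-of-bag pooling
variant is available (`oob_only=True`) but is not the default at this
design's scale: with only six minority samples, out-of-bag estimates of
P(minority|x) inherit the bagged models' bias against the minority and
conditional-risk relabeling then removes the class — the opposite of the
method's purpose. Both pooling schemes appear in Domingos' original
description of the procedure.

The GA selector uses binary chromosomes (one bit per feature),
tournament selection (size 3), uniform crossover (rate 0.8), per-bit
mutation (rate 1/p), elitism of 2, population 50 for 100 generations by
default; fitness is stratified-CV accuracy of PLS-DA on the masked
features, with an LRU cache over masks. Elitism makes the best-fitness
trace non-decreasing; empty masks are repaired to a random single
feature. Wrapper selection optimises accuracy, not completeness: once a
feature subset saturates accuracy the GA has no pressure to include
further informative features, so recovery of planted effects is assessed
on the union of the GA mask and the VIP rule, which is also how the
selection table is assembled.

## Selection and directions

Flags use strict inequalities (VIP > 1.5, p < 0.05). ANOVA p-values over
the metabolome are reported raw to mirror the reporting convention for
this analysis; a Benjamini-Hochberg switch exists, off by default.
Direction arrows compare group means of the processed values: up if
above control, down otherwise, upgraded to down-down only when strictly
below both control and the other AN subtype; exact ties break toward
down with a logged warning. Significance is a separate column, not
folded into the arrow. The summary-statistics ANOVA route is
algebraically identical to the raw-data route (SS_between from n·(m−m̄)²,
SS_within from (n−1)s²) and carries Tukey-Kramer post hoc p-values from
the studentized-range distribution.

## Pathway analysis

Over-representation is the exact hypergeometric upper tail with the
background fixed to the measured metabolites mappable to the library —
not the whole database — so adding irrelevant pathways to a library
leaves existing p-values unchanged. Compounds absent from the background
are excluded from N. Impact is Σ_hits BC_rel / Σ_all BC_rel with
relative betweenness normalised by (N−1)(N−2) ordered pairs (directed
graphs; an undirected mode exists); edgeless pathways are scored 0 and
flagged. The bundled toy library is synthetic (HMDB-like codes in the
simulated namespace) and exists for tests and examples; real libraries
load from edge-list + membership TSVs.

## Integration

Spearman ρ is the Pearson correlation of midranks with the
t-approximation p on n−2 df (p = 0 at |ρ| = 1); groups below n = 4 are
skipped. The correlation rank defaults to family — the rank used in the
results this analysis style reports — and is a parameter. Row and column
orders come from average-linkage clustering on 1 − ρ of the control
grid and are shared across groups so heatmaps stay comparable
(per-group clustering by flag; ties in the linkage broken
lexicographically by label, making the order deterministic). In
concordance summaries a ρ of exactly 0 matches no sign, and NaN cells
(constant margins) are excluded from numerators and denominators.

## Numerical and scale choices

Tolerances: NIPALS 1e-10 (1e-14 in oracle tests), NMDS 1e-7, VIP
identity asserted at 1e-8, summary-vs-raw ANOVA at 1e-10. Default test
and acceptance runs use scaled problem sizes chosen to keep the whole
suite in the low minutes on one CPU while leaving the statistical
thresholds untouched: GA recovery uses population 24 × 20 generations
with 3-fold CV fitness over 10–12 cohorts; LEfSe recovery 25–40 cohorts;
calibration studies 200–300 replicates at B = 19–99 with randomised-PIT
Kolmogorov-Smirnov checks; the MetaCost comparison 8–10 paired cohorts.

## Limitations

Results on synthetic cohorts validate the machinery, not any biological
claim. The LEfSe implementation omits the subclass stage; the NMDS and
GA are stochastic heuristics (seeded, multi-start, but not guaranteed
global); PLS-DA class probabilities are not calibrated probabilities;
the pathway impact depends entirely on the supplied graph topology; and
with a six-member group, every per-group statistic (2-class Q²,
ANBP-only correlations, minority recall) has large seed-to-seed
variance.
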