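# microbiometab

Statistical analysis of paired gut-microbiome (16S OTU counts) and fecal
metabolome (GC-MS semi-quantitative peak areas) profiles in a three-group
case-control design: women with restricting-type anorexia nervosa (ANR),
women with binge-purge-type anorexia nervosa (ANBP), and healthy controls
(CTRL). The package reimplements the full analysis chain of such a study
as tested, reusable code, and ships a synthetic cohort generator with
planted, recoverable group effects so that every stage can be exercised
and validated without access to restricted clinical data.

## What it computes

**Diversity.** Per-sample bias-corrected Chao1 richness,
`S_obs + F1(F1-1) / (2(F2+1))`, with Welch t-tests between groups;
Bray-Curtis dissimilarities `d(u,v) = 1 - 2 Σ min(u_i,v_i) / (Σu_i + Σv_i)`
on rarefied relative abundances; non-metric multidimensional scaling
(Kruskal stress-1 via isotonic-regression/SMACOF alternation); one-way
PERMANOVA with a label-permutation null.

**Differential abundance.** LEfSe-style screening: Kruskal-Wallis per
clade at every rank from phylum to genus (per-sample abundances scaled to
10⁶), then bootstrapped one-vs-rest linear discriminant effect sizes on
the log₁₀ scale; plus per-phylum Mann-Whitney comparisons and the
Bacteroidetes/Firmicutes ratio.

**Cost-sensitive PLS-DA.** NIPALS PLS2 on the autoscaled, log-transformed,
internal-standard-normalised metabolite matrix against a centered one-hot
class matrix. Class imbalance (6 ANBP vs 17 ANR vs 20 CTRL) is handled by
MetaCost: bagged PLS-DA vote estimates of P(class|x) and conditional-risk
relabeling under an inverse-class-size cost matrix `C(i,j) = n_max / n_j`.
Dimensionality is reduced by a genetic-algorithm wrapper whose fitness is
cross-validated accuracy. Model quality is reported as R², Q² = 1 −
PRESS/SS_tot, and out-of-fold accuracy per component count, with a
label-permutation test against overfitting. Variable importance in
projection for metabolite *j*:

    VIP_j = sqrt( p · Σ_a SSY_a (w_aj / ||w_a||)² / Σ_a SSY_a )

**Metabolite selection.** A metabolite is reported when its 3-class VIP
exceeds 1.5, its 2-class (ANR vs ANBP) VIP exceeds 1.5, or its one-way
ANOVA p (with Tukey HSD post hoc) is below 0.05; directions per AN group
are annotated against the control mean, with a double-down mark when a
group lies below both the control and the other AN subtype. Summary-level
ANOVA (`anova_from_summary`) reproduces F statistics directly from
published per-group n/mean/SD rows.

**Pathway topology.** MetPa-style analysis of the selected metabolites:
exact hypergeometric over-representation P(X ≥ k) against the measured,
library-mappable background, and a topology impact score — the fraction
of the pathway's relative betweenness centrality (directed, normalised by
(N−1)(N−2)) carried by the hit compounds.

**Integration.** Per-group Spearman correlation grids between taxon-family
abundances and the selected metabolites (midranks, t-approximation p),
dually ordered by average-linkage clustering on 1 − ρ computed on the
control grid, with concordance summaries: fraction of positive and of
significant correlations per group, and same-sign fractions between
groups.

## Worked example

```python
import numpy as np
from microbiometab import (SimulationParams, simulate_cohort, metacost_relabel,
                           cross_validate, vip_scores, PLSDAClassifier)
from microbiometab.preprocess import normalize_internal_standard, log_then_autoscale

otu, met, labels, truth = simulate_cohort(SimulationParams(seed=1))
processed, _ = log_then_autoscale(normalize_internal_standard(met))
X = processed.matrix()
y = labels.as_array(processed.sample_ids)

y_cost = metacost_relabel(X, y, seed=1)              # cost-sensitive relabeling
cv = cross_validate(X, y_cost, a_max=5, folds=5, repeats=5, seed=1, scale=False)
print(f"chosen components: {cv.chosen}")
print(f"Q2 = {cv.chosen_q2:.3f}, R2 = {cv.chosen_r2:.3f}, accuracy = {cv.chosen_accuracy:.3f}")

model = PLSDAClassifier(n_components=cv.chosen, scale=False).fit(X, y_cost)
vip = vip_scores(model)
print(f"metabolites with VIP > 1.5: {(vip > 1.5).sum()}")
planted = truth.planted_metabolite_ids(1.5)
ids = np.array(processed.feature_ids)
print(f"planted effects recovered: {np.isin(planted, ids[vip > 1.5]).sum()}/{len(planted)}")
```

prints

```
chosen components: 5
Q2 = 0.787, R2 = 0.998, accuracy = 1.000
metabolites with VIP > 1.5: 20
planted effects recovered: 20/20
```

i.e. on a default 17/6/20 synthetic cohort with 224 metabolites, the
cross-validated discriminant model is strongly predictive (Q² ≈ 0.79, far
above the zero expected under no class structure) and the VIP > 1.5 rule
recovers exactly the 20 planted group-discriminating metabolites.

The same workflow is available end to end from the shell:

```bash
microbiometab --seed 1 --outdir results simulate
microbiometab --seed 1 --outdir results all \
    --otu results/otu_table.tsv --metabolites results/metabolites.csv \
    --metadata results/metadata.tsv
```

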