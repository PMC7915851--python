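"""End-to-end orchestration: preprocess -> diversity -> differential
abundance -> cost-sensitive PLS-DA with GA selection -> metabolite
selection -> pathway analysis -> microbiome-metabolome integration.

Each stage is a plain function over in-memory tables; :func:`run_pipeline`
chains them, writes every result as a headered TSV (config hash + seed),
and returns the full result bundle. The same stage functions back the CLI
subcommands.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from microbiometab import io as mio
from microbiometab.datamodel import AnalysisConfig, CohortLabels, FeatureTable
from microbiometab.diff_abundance import bf_ratio, lefse, phylum_compare
from microbiometab.diversity import (alpha_group_test, bray_curtis, chao1_per_sample,
                                     nmds, permanova)
from microbiometab.imbalance import GaParams, cost_from_class_sizes, ga_select, metacost_relabel
from microbiometab.integration import build_grids, concordance
from microbiometab.pathway import analyze_pathways, toy_library
from microbiometab.plsda import PLSDAClassifier, cross_validate, permutation_test, vip_scores
from microbiometab.preprocess import (aggregate_rank, log_then_autoscale,
                                      normalize_internal_standard, rarefy,
                                      relative_abundance)
from microbiometab.selection import (annotate_direction, anova_oneway,
                                     select_metabolites)
from microbiometab.simulate import SimulationParams, simulate_cohort

log = logging.getLogger("microbiometab")


def stage_preprocess(otu_table: FeatureTable, met_table: FeatureTable,
                     config: AnalysisConfig):
    """IS-normalise + log/autoscale metabolites; rarefy + relative OTUs."""
    normalized = normalize_internal_standard(met_table)
    processed, constant = log_then_autoscale(normalized)
    if constant:
        log.warning("constant metabolite columns flagged: %s", constant)
    rarefied = rarefy(otu_table, seed=config.seed)
    relative = relative_abundance(rarefied)
    return {"metabolites": processed, "otu_rarefied": rarefied, "otu_relative": relative}


def stage_diversity(rarefied: FeatureTable, relative: FeatureTable,
                    labels: CohortLabels, config: AnalysisConfig):
    chao = chao1_per_sample(rarefied)
    alpha_tests = alpha_group_test(chao, labels.subset(chao.index))
    dist = bray_curtis(relative)
    ordination = nmds(dist, k=2, n_starts=config.nmds_starts,
                      max_iter=config.nmds_max_iter, tol=config.nmds_tol,
                      seed=config.seed)
    perm = permanova(dist, labels.subset(dist.index),
                     n_permutations=config.permanova_permutations, seed=config.seed)
    return {"chao1": chao, "alpha_tests": alpha_tests, "distances": dist,
            "nmds": ordination, "permanova": perm}


def stage_diff_abundance(relative: FeatureTable, labels: CohortLabels,
                         config: AnalysisConfig):
    lef = lefse(relative, labels.subset(relative.sample_ids),
                screen_alpha=config.lefse_screen_alpha,
                display_alpha=config.lefse_display_alpha,
                lda_threshold=config.lda_threshold, seed=config.seed)
    phyla = phylum_compare(relative, labels.subset(relative.sample_ids))
    try:
        ratio, h, p = bf_ratio(relative, labels.subset(relative.sample_ids))
    except ValueError as exc:
        log.warning("B/F ratio skipped: %s", exc)
        ratio, h, p = pd.Series(dtype=float), np.nan, np.nan
    return {"lefse": lef, "phylum_tests": phyla,
            "bf_ratio": ratio, "bf_ratio_kw": (h, p)}


def stage_plsda(metabolites: FeatureTable, labels: CohortLabels, config: AnalysisConfig):
    """Cost-sensitive PLS-DA with GA feature selection; 3-class and 2-class VIPs.

    MetaCost relabeling is applied first (inverse-class-size costs), the GA
    then selects features under the relabeled targets, and the final
    models (3-class on all groups; 2-class on the AN subtypes only) are
    fit on the selected features. VIPs of unselected features are 0.
    """
    X = metabolites.matrix()
    ids = metabolites.feature_ids
    y3 = labels.as_array(metabolites.sample_ids)

    classes, cost = cost_from_class_sizes(y3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y3_re = metacost_relabel(X, y3, cost=cost, m=config.metacost_models,
                                 frac=config.metacost_fraction, seed=config.seed)
    ga_params = GaParams(population=config.ga_population, generations=config.ga_generations,
                         crossover_rate=config.ga_crossover_rate,
                         mutation_rate=config.ga_mutation_rate,
                         elitism=config.ga_elitism, tournament=config.ga_tournament,
                         cv_folds=config.cv_folds, seed=config.seed)
    ga = ga_select(X, y3_re, ga_params)
    mask = ga.mask
    Xs = X[:, mask]

    # model diagnostics (Q2/R2/accuracy) on the GA-selected features;
    # VIPs on the full metabolome so importance is comparable across all
    # measured metabolites, selected or not
    cv3 = cross_validate(Xs, y3_re, a_max=config.max_components,
                         folds=config.cv_folds, repeats=config.cv_repeats,
                         seed=config.seed, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model3 = PLSDAClassifier(n_components=cv3.chosen, scale=False).fit(X, y3_re)
    vip3 = pd.Series(vip_scores(model3), index=ids)

    an_samples = [s for s in metabolites.sample_ids if labels[s] != "CTRL"]
    vip2 = pd.Series(0.0, index=ids)
    cv2 = None
    if len(an_samples) >= 4:
        X2 = metabolites.values.loc[an_samples].to_numpy(dtype=float)
        y2 = labels.as_array(an_samples)
        cv2 = cross_validate(X2[:, mask], y2, a_max=config.max_components,
                             folds=config.cv_folds, repeats=config.cv_repeats,
                             seed=config.seed, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model2 = PLSDAClassifier(n_components=cv2.chosen, scale=False).fit(X2, y2)
        vip2 = pd.Series(vip_scores(model2), index=ids)

    perm = permutation_test(Xs, y3_re, statistic="accuracy",
                            n_permutations=config.n_permutations, seed=config.seed,
                            a_max=cv3.chosen, folds=config.cv_folds)
    return {"relabeled": pd.Series(y3_re, index=metabolites.sample_ids),
            "cost_matrix": pd.DataFrame(cost, index=classes, columns=classes),
            "ga_mask": pd.Series(mask, index=ids), "ga_trace": ga.trace,
            "cv_3class": cv3, "cv_2class": cv2,
            "vip_3class": vip3, "vip_2class": vip2, "permutation": perm}


def stage_selection(metabolites: FeatureTable, labels: CohortLabels,
                    vip3: pd.Series, vip2: pd.Series, config: AnalysisConfig):
    y = labels.as_array(metabolites.sample_ids)
    ps = pd.Series({m: anova_oneway(metabolites.values[m].to_numpy(), y).p
                    for m in metabolites.feature_ids})
    hmdb = None
    if metabolites.feature_meta is not None and "hmdb" in metabolites.feature_meta:
        hmdb = metabolites.feature_meta["hmdb"]
    sel = select_metabolites(vip3, vip2, ps, vip_threshold=config.vip_threshold,
                             anova_alpha=config.anova_alpha, hmdb=hmdb)
    directions = annotate_direction(metabolites.values, labels)
    return {"selection": sel, "anova_p": ps, "directions": directions}


def stage_pathway(selection, metabolites: FeatureTable, library=None):
    library = library if library is not None else toy_library()
    hmdb = metabolites.feature_meta["hmdb"] if metabolites.feature_meta is not None else pd.Series(dtype=str)
    selected_codes = set(hmdb.reindex(selection.selected.index).dropna()) - {""}
    measured = set(hmdb.dropna()) - {""}
    background = measured & set().union(*(pw.membership for pw in library))
    results = analyze_pathways(selected_codes, library, background=background)
    return {"pathways": results}


def stage_integration(relative: FeatureTable, metabolites: FeatureTable,
                      labels: CohortLabels, selection, config: AnalysisConfig):
    families = aggregate_rank(relative, config.correlation_rank)
    selected_ids = [m for m in selection.selected.index if m in metabolites.feature_ids]
    selected_table = metabolites.with_values(metabolites.values[selected_ids])
    grids = build_grids(families, selected_table, labels,
                        alpha=config.correlation_alpha)
    summary = concordance(grids) if len(grids) >= 2 else None
    return {"grids": grids, "concordance": summary}


def run_pipeline(config: AnalysisConfig, outdir, otu_table=None, met_table=None,
                 labels=None, sim_params: SimulationParams | None = None,
                 library=None) -> dict:
    """Run every stage and write the result bundle under *outdir*.

    Either pass the three inputs (otu_table, met_table, labels) or leave
    them None to simulate a cohort (``sim_params`` defaults to the
    study-design defaults with the config seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log.info("pipeline start: seed=%d config_hash=%s", config.seed, chash)

    if otu_table is None or met_table is None or labels is None:
        sim_params = sim_params or SimulationParams(seed=config.seed)
        otu_table, met_table, labels, truth = simulate_cohort(sim_params)
        truth_rows = ([{"feature": t, "kind": "taxon", "group": g, "log2fc": fc}
                       for t, fcs in truth.taxa.items() for g, fc in fcs.items()] +
                      [{"feature": m, "kind": "metabolite", "group": g, "log2fc": fc}
                       for m, fcs in truth.metabolites.items() for g, fc in fcs.items()])
        mio.write_result_tsv(pd.DataFrame(truth_rows), outdir / "ground_truth.tsv",
                             chash, config.seed, index=False)
    otu_table.check_aligned(labels)
    met_table.check_aligned(labels)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    pre = _stage("preprocess", stage_preprocess, otu_table, met_table, config)
    div = _stage("diversity", stage_diversity, pre["otu_rarefied"], pre["otu_relative"],
                 labels, config)
    diff = _stage("diff_abundance", stage_diff_abundance, pre["otu_relative"], labels, config)
    pls = _stage("plsda", stage_plsda, pre["metabolites"], labels, config)
    sel = _stage("selection", stage_selection, pre["metabolites"], labels,
                 pls["vip_3class"], pls["vip_2class"], config)
    pwy = _stage("pathway", stage_pathway, sel["selection"], pre["metabolites"], library)
    integ = _stage("integration", stage_integration, pre["otu_relative"],
                   pre["metabolites"], labels, sel["selection"], config)

    w = lambda df, name, **kw: mio.write_result_tsv(df, outdir / name, chash, config.seed, **kw)
    w(div["chao1"].to_frame(), "diversity_chao1.tsv")
    w(div["alpha_tests"], "diversity_alpha_tests.tsv", index=False)
    w(div["distances"], "diversity_bray_curtis.tsv")
    w(div["nmds"].coordinates.assign(stress=div["nmds"].stress), "diversity_nmds.tsv")
    w(pd.DataFrame([{"pseudo_F": div["permanova"].pseudo_f,
                     "p": div["permanova"].p_value,
                     "n_permutations": div["permanova"].n_permutations}]),
      "diversity_permanova.tsv", index=False)
    w(diff["lefse"].table, "diffabund_lefse.tsv", index=False)
    w(diff["lefse"].edges, "diffabund_cladogram_edges.tsv", index=False)
    w(diff["phylum_tests"], "diffabund_phylum_tests.tsv", index=False)
    w(diff["bf_ratio"].to_frame(), "diffabund_bf_ratio.tsv")
    w(pls["cost_matrix"], "plsda_cost_matrix.tsv")
    w(pls["relabeled"].to_frame("relabeled_group"), "plsda_metacost_labels.tsv")
    w(pls["ga_mask"].to_frame("selected"), "plsda_ga_mask.tsv")
    w(pd.DataFrame({"generation": range(len(pls["ga_trace"])),
                    "best_fitness": pls["ga_trace"]}), "plsda_ga_trace.tsv", index=False)
    cv3 = pls["cv_3class"]
    w(pd.DataFrame({"components": cv3.components, "r2": cv3.r2, "q2": cv3.q2,
                    "accuracy": cv3.accuracy}), "plsda_cv_3class.tsv", index=False)
    w(pd.DataFrame([{"statistic": pls["permutation"].statistic,
                     "observed": pls["permutation"].observed,
                     "p": pls["permutation"].p_value}]), "plsda_permutation.tsv", index=False)
    table = sel["selection"].table.join(sel["directions"], how="left")
    w(table, "selection_table.tsv")
    w(pwy["pathways"], "pathway_results.tsv", index=False)
    for g, grid in integ["grids"].items():
        w(grid.rho, f"integration_rho_{g}.tsv")
        w(grid.p, f"integration_p_{g}.tsv")
        w(grid.mask.astype(int), f"integration_mask_{g}.tsv")
    if integ["concordance"] is not None:
        w(integ["concordance"].per_group, "integration_concordance_groups.tsv", index=False)
        w(integ["concordance"].per_pair, "integration_concordance_pairs.tsv", index=False)
    log.info("pipeline done: outputs in %s", outdir)
    return {"preprocess": pre, "diversity": div, "diff_abundance": diff,
            "plsda": pls, "selection": sel, "pathway": pwy, "integration": integ}
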