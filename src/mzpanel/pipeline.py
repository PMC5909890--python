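"""End-to-end two-cohort biomarker workflow.

Chains the pipeline stages the way the original study ran them:
annotate both cohorts by monoisotopic-mass matching, normalize
(half-minimum imputation, glog, auto-scaling; optional cross-cohort
batch adjustment on the glog scale), rank analytes in the discovery
cohort, take the top-k panel, restrict it to analytes common to both
cohorts, then evaluate with logistic regression: discovery ROC and
pooled 10-fold-CV internal validation in cohort 1, refitted replication
ROC in cohort 2, and a Hanley-McNeil z-test between the
internal-validation and replication AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import DEFAULT_THRESHOLD, annotate_table, intersect_common
from .evaluation import ROCResult, evaluate_cv10, evaluate_discovery, evaluate_replication
from .io import FeatureTable
from .library import CompoundLibrary, builtin_reference_library
from .preprocessing import autoscale, batch_correct, glog_transform, impute_missing
from .selection import (
    PanelDefinition,
    build_panel,
    lasso_selection_frequency,
    linear_svm_ranking,
    plsda_vip,
    random_forest_importance,
    univariate_stats,
)
from .simulate import SyntheticConfig, simulate_two_cohorts
from .stats import ROCComparison, compare_independent_rocs


@dataclass
class WorkflowResult:
    """All artifacts of one two-cohort run, keyed by selector."""

    annotated: tuple[FeatureTable, FeatureTable]
    normalized: tuple[FeatureTable, FeatureTable]
    panels: dict[str, PanelDefinition]
    refined_panels: dict[str, PanelDefinition]
    discovery: dict[str, ROCResult]
    internal: dict[str, ROCResult]
    replication: dict[str, ROCResult]
    comparisons: dict[str, ROCComparison]


def normalize_pair(
    raw1: FeatureTable,
    raw2: FeatureTable,
    glog_a: float = 1.0,
    apply_batch_correct: bool = True,
) -> tuple[FeatureTable, FeatureTable]:
    """Impute, glog and autoscale both cohorts (own fitted parameters),
    with optional location-scale batch adjustment between them."""
    g1 = glog_transform(impute_missing(raw1), a=glog_a)
    g2 = glog_transform(impute_missing(raw2), a=glog_a)
    if apply_batch_correct:
        g1, g2 = batch_correct([g1, g2])
    t1, _ = autoscale(g1)
    t2, _ = autoscale(g2)
    return t1, t2


def rank_features(
    table: FeatureTable,
    method: str,
    seed: int = 0,
    lasso_subsamples: int = 100,
):
    """Dispatch one selection method on an autoscaled table."""
    if method in ("univariate_auc", "ttest", "fold_change"):
        return univariate_stats(table)[method]
    if method == "lasso_frequency":
        return lasso_selection_frequency(table, n_subsamples=lasso_subsamples, seed=seed)
    if method == "linear_svm":
        return linear_svm_ranking(table, seed=seed)
    if method == "plsda_vip":
        return plsda_vip(table)
    if method == "random_forest":
        return random_forest_importance(table, seed=seed)
    raise ValueError(f"unknown selection method {method!r}")


def run_two_cohort_workflow(
    config: SyntheticConfig,
    selectors: tuple[str, ...] = ("linear_svm", "lasso_frequency"),
    k: int = 10,
    threshold: float = DEFAULT_THRESHOLD,
    library: CompoundLibrary | None = None,
    apply_batch_correct: bool = True,
    glog_a: float = 1.0,
    lasso_subsamples: int = 100,
) -> WorkflowResult:
    """Simulate, annotate, normalize, select, evaluate and compare."""
    if library is None:
        library = builtin_reference_library()
    raw1, raw2 = simulate_two_cohorts(config, library)
    ann1, _ = annotate_table(raw1, library, threshold)
    ann2, _ = annotate_table(raw2, library, threshold)
    t1, t2 = normalize_pair(ann1, ann2, glog_a=glog_a, apply_batch_correct=apply_batch_correct)

    panels, refined, discovery, internal, replication, comparisons = {}, {}, {}, {}, {}, {}
    for method in selectors:
        ranked = rank_features(t1, method, seed=config.seed, lasso_subsamples=lasso_subsamples)
        panel = build_panel(ranked, k=k)
        panels[method] = panel
        common = intersect_common(panel, t2)
        refined[method] = common
        if len(common) == 0:
            continue
        discovery[method] = evaluate_discovery(t1, common)
        internal[method] = evaluate_cv10(t1, common, seed=config.seed)
        replication[method] = evaluate_replication(t2, common)
        comparisons[method] = compare_independent_rocs(internal[method], replication[method])
    return WorkflowResult(
        annotated=(ann1, ann2),
        normalized=(t1, t2),
        panels=panels,
        refined_panels=refined,
        discovery=discovery,
        internal=internal,
        replication=replication,
        comparisons=comparisons,
    )
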