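"""End-to-end synthetic experiment: simulate -> quantify -> select -> train
-> evaluate.

This is the desk-scale rehearsal of the targeted episignature assay: a
synthetic cohort is generated under the study conditions, methylation is
quantified through one of the two backends (deep amplicon sequencing or
calibrated Sanger traces), features are selected by the shadow-feature
procedure, and a linear SVM on the merged two-CpG locus is trained and
evaluated on a held-out split. The result carries everything a caller
needs: the matrix, the selection verdicts, the model (with its raw-scale
cut-off) and train/test performance reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import (
    CASE_LABEL,
    CONTROL_LABEL,
    ClassifierModel,
    EvalReport,
    classify as apply_model,
    compare_combinations,
    evaluate,
    impute_missing,
    shadow_feature_select,
    split_train_test,
    train_cutoff_model,
)
from .cohort import (
    SyntheticConfig,
    default_config,
    generate_cohort,
    labels_series,
    simulate_model_traces,
    simulate_reads,
    simulate_traces,
    synthetic_references,
)
from .ngs import merge_features, panel_merged_pairs, quantify_cohort
from .panel import load_panel, merged_feature_name
from .sanger import build_calibration, quantify_traces

__all__ = ["ExperimentResult", "run_synthetic_experiment", "TARGET_FEATURE"]

# the merged two-CpG GCNT2-promoter locus the signature reduces to
TARGET_FEATURE = merged_feature_name("chr6", 10556199, 10556204)


@dataclass
class ExperimentResult:
    config: SyntheticConfig
    backend: str
    matrix: pd.DataFrame
    labels: pd.Series
    selection: dict[str, str]
    feature: str
    model: ClassifierModel
    train_report: EvalReport
    test_report: EvalReport
    extra_predictions: pd.DataFrame | None = None
    ranked: pd.DataFrame | None = None
    dropped_features: list[str] = field(default_factory=list)


def simulate_cohort_matrix(
    config: SyntheticConfig,
    backend: str = "ngs",
    panel=None,
    min_coverage: int = 100,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a cohort and quantify it through the chosen backend.

    Returns the samples x features percent matrix (per-CpG plus merged
    features) and the label series.
    """
    if panel is None:
        panel = load_panel()
    cohort = generate_cohort(config)
    refs = synthetic_references(panel)
    rng = np.random.default_rng(config.seed)

    if backend == "ngs":
        reads = {
            s.sample_id: simulate_reads(s, panel, refs, config, rng=rng)
            for s in cohort
        }
        matrix = quantify_cohort(reads, panel, refs, min_coverage=min_coverage)
    elif backend == "sanger":
        models = simulate_model_traces(panel, config, rng=rng, insert_seqs=refs)
        calib = build_calibration(models)
        traces = {
            s.sample_id: simulate_traces(s, panel, config, rng=rng, insert_seqs=refs)
            for s in cohort
        }
        names = {
            p: f"{a.insert_chrom}:{p}" for a in panel for p in a.encompassed_cpgs
        }
        matrix = quantify_traces(traces, calib, names)
        matrix, _ = merge_features(matrix, panel_merged_pairs(panel))
    else:
        raise ValueError("backend must be 'ngs' or 'sanger'")
    return matrix, labels_series(cohort)


def run_synthetic_experiment(
    seed: int = 0,
    backend: str = "ngs",
    config: SyntheticConfig | None = None,
    feature: str = TARGET_FEATURE,
    split_ratio: float = 0.7,
    n_boruta_iter: int = 30,
    n_estimators: int = 60,
    alpha: float = 0.01,
    min_coverage: int = 100,
    shuffle_labels: bool = False,
    rank_combinations: bool = False,
    max_k: int = 2,
) -> ExperimentResult:
    """Run the full synthetic experiment under one seed.

    By default the cohort holds only the control and case groups (the
    classes the model is trained on); pass a config with ``n_vus`` /
    ``n_overlap`` > 0 to also classify VUS carriers and overlapping-syndrome
    samples with the trained model. ``shuffle_labels=True`` permutes the
    class labels before any learning step — the negative control under
    which no feature should be selected and AUC should sit near 0.5.
    """
    if config is None:
        config = default_config(seed=seed, n_vus=0, n_overlap=0)
    elif config.seed != seed:
        config = replace(config, seed=seed)

    panel = load_panel()
    matrix, labels = simulate_cohort_matrix(
        config, backend=backend, panel=panel, min_coverage=min_coverage
    )

    core = labels.isin([CONTROL_LABEL, CASE_LABEL])
    core_matrix, core_labels = matrix.loc[core], labels.loc[core]
    if shuffle_labels:
        rng = np.random.default_rng(seed)
        core_labels = pd.Series(
            rng.permutation(core_labels.to_numpy()),
            index=core_labels.index,
            name=core_labels.name,
        )

    train_x, test_x, train_y, test_y = split_train_test(
        core_matrix, core_labels, ratio=split_ratio, seed=seed
    )
    train_x, test_x, info = impute_missing(train_x, test_x)
    selection = shadow_feature_select(
        train_x,
        train_y,
        n_iter=n_boruta_iter,
        alpha=alpha,
        seed=seed,
        n_estimators=n_estimators,
    )

    ranked = None
    chosen = feature
    important = [f for f, s in selection.items() if s == "important"]
    if rank_combinations and important:
        ranked = compare_combinations(
            train_x, train_y, important, max_k=max_k, seed=seed
        )
    if chosen not in train_x.columns:
        # fall back to the best available single feature when the target
        # locus was dropped (possible for sparse Sanger data)
        pool = important or list(train_x.columns)
        best = compare_combinations(train_x, train_y, pool, max_k=1, seed=seed)
        chosen = best.iloc[0]["features"]

    model = train_cutoff_model(train_x, train_y, [chosen], seed=seed)
    train_report = evaluate(model, train_x, train_y, seed=seed)
    test_report = evaluate(model, test_x, test_y, seed=seed)

    extra = None
    if (~core).any():
        extra_matrix = matrix.loc[~core, train_x.columns].fillna(info["medians"])
        extra = apply_model(model, extra_matrix)
        extra["true_group"] = labels.loc[~core]

    return ExperimentResult(
        config=config,
        backend=backend,
        matrix=matrix,
        labels=labels,
        selection=selection,
        feature=chosen,
        model=model,
        train_report=train_report,
        test_report=test_report,
        extra_predictions=extra,
        ranked=ranked,
        dropped_features=info["dropped_features"],
    )
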