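"""End-to-end screening pipeline on feature blocks.

Wires the stages together the way a full screening study runs them: per-block
feature filtering and standardization (statistics from training rows only),
grid-optimized GBT and MLP learners per block, per-model probability
thresholds optimized on the training partition and frozen, then consensus 1
(probability pooling) and consensus 2 (unanimity voting) per learner family
and over all primary models, evaluated on every validation set with
AUC/MCC/Sn/Sp and exclusion bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._utils import derive_seed
from .consensus import (MODES, ProbabilityMatrix, agreement_mask, pool)
from .featurization import (FeatureBlock, apply_standardizer, filter_features,
                            fit_standardizer)
from .learners import (FittedModel, LearnerSpec, SplitPlan, grid_train,
                       make_splits, out_of_fold_probabilities,
                       predict_active_probability)
from .metrics import (EvaluationReport, MetricsRecord, ReportEntry, confusion,
                      mcc, sensitivity, specificity)
from .roc import apply_threshold, optimal_threshold, roc
from .synthetic import SyntheticSpec, gen_feature_dataset


@dataclass
class PipelineConfig:
    """Run-level knobs; defaults reproduce the full grid-search study."""

    data: SyntheticSpec = field(default_factory=SyntheticSpec)
    k: int = 5
    test_fraction: float = 0.30
    corr_limit: float = 0.997
    gbt_depths: Sequence[int] = (2, 4, 6, 8, 10)
    mlp_layers: Sequence[int] = (1, 2)
    mlp_neurons: Sequence[int] = (16, 64, 256)
    mlp_max_iter: int = 200
    include_cv: bool = False  # out-of-fold consensus evaluation (k extra fits)


def fast_config(n: int = 3000) -> PipelineConfig:
    """Single-point grids for repeated-seed experiments on one CPU."""
    return PipelineConfig(data=SyntheticSpec(n=n), gbt_depths=(6,),
                          mlp_layers=(1,), mlp_neurons=(32,),
                          mlp_max_iter=150)


@dataclass
class PipelineResult:
    report: EvaluationReport
    models: dict[str, FittedModel]
    thresholds: dict[str, float]          # per primary model, frozen
    probabilities: dict[str, np.ndarray]  # per model, all rows
    plan: SplitPlan
    labels: np.ndarray
    dropped_columns: dict[str, list[str]]

    def matrix(self, model_names: Sequence[str], mask: np.ndarray
               ) -> ProbabilityMatrix:
        values = np.column_stack([self.probabilities[m][mask]
                                  for m in model_names])
        ids = [f"row{i}" for i in np.flatnonzero(mask)]
        return ProbabilityMatrix(ids, list(model_names), values,
                                 self.labels[mask])


def _prepare_block(block: FeatureBlock, train_mask: np.ndarray,
                   corr_limit: float) -> tuple[FeatureBlock, list[str]]:
    """Filter on training rows only, then standardize with training statistics."""
    train_view = FeatureBlock(block.block_name,
                              [i for i, m in zip(block.ids, train_mask) if m],
                              list(block.columns), block.values[train_mask])
    filtered_train, dropped = filter_features(train_view, corr_limit)
    keep = [block.columns.index(c) for c in filtered_train.columns]
    full = FeatureBlock(block.block_name, list(block.ids),
                        list(filtered_train.columns), block.values[:, keep])
    scaler = fit_standardizer(full, train_mask)
    return apply_standardizer(scaler, full), dropped


def _metrics_at(labels, probs, threshold: float) -> MetricsRecord:
    curve = roc(labels, probs)
    c = confusion(labels, apply_threshold(probs, threshold))
    return MetricsRecord(auc=curve.auc, mcc=mcc(c), sn=sensitivity(c),
                         sp=specificity(c), n=c.n)


def _consensus_rows(report: EvaluationReport, learner: str, block: str,
                    matrices: dict[str, ProbabilityMatrix],
                    model_names: list[str],
                    thresholds: dict[str, float]) -> None:
    """Add consensus 1 and 2 rows for one model group across validation sets.

    Pooled-probability thresholds (and, for scheme 2, the per-model vote
    thresholds) come from the training set and are frozen for every other
    validation set.
    """
    t = np.array([thresholds[m] for m in model_names])
    train = matrices["training"]

    # consensus 1: pooled threshold from training pooling
    for mode in MODES:
        t_pool = optimal_threshold(
            roc(train.labels, pool(train, mode))).threshold
        for vset, mat in matrices.items():
            rec = _metrics_at(mat.labels, pool(mat, mode), t_pool)
            report.add(ReportEntry(learner, block, "consensus1", mode, vset,
                                   metrics=rec, excluded_ratio=0.0,
                                   active_ratio_kept=float(mat.labels.mean())))

    # consensus 2: unanimity vote with frozen per-model thresholds
    def kept(mat: ProbabilityMatrix) -> ProbabilityMatrix:
        classes = np.column_stack([
            apply_threshold(mat.values[:, j], t[j])
            for j in range(mat.n_models)])
        return mat.subset(agreement_mask(classes))

    train_kept = kept(train)
    for mode in MODES:
        t_pool = optimal_threshold(
            roc(train_kept.labels, pool(train_kept, mode))).threshold
        for vset, mat in matrices.items():
            sub = kept(mat)
            if len(np.unique(sub.labels)) < 2:
                warnings.warn(
                    f"consensus 2 kept rows single-class on {vset}; "
                    "row omitted", stacklevel=2)
                continue
            rec = _metrics_at(sub.labels, pool(sub, mode), t_pool)
            report.add(ReportEntry(
                learner, block, "consensus2", mode, vset, metrics=rec,
                excluded_ratio=1.0 - len(sub.ids) / len(mat.ids),
                active_ratio_kept=float(sub.labels.mean())))


def run_pipeline(seed: int, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run the full study on one synthetic dataset; returns the report.

    All randomness (data generation, splits, learner initialization) derives
    from ``seed``, so a run is replayable end to end.
    """
    config = config or PipelineConfig()
    data_spec = replace(config.data, seed=derive_seed(seed, "data"))
    blocks, labels = gen_feature_dataset(data_spec)
    plan = make_splits(labels, k=config.k, test_fraction=config.test_fraction,
                       seed=derive_seed(seed, "splits"))
    train = plan.train_mask

    models: dict[str, FittedModel] = {}
    probs: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    dropped: dict[str, list[str]] = {}
    oof: dict[str, np.ndarray] = {}  # out-of-fold probabilities, train rows

    report = EvaluationReport()
    for block_name, raw in blocks.items():
        prepped, dropped[block_name] = _prepare_block(raw, train,
                                                      config.corr_limit)
        for family in ("gbt", "mlp"):
            spec = LearnerSpec(
                family=family, tree_depth=config.gbt_depths,
                hidden_layers=config.mlp_layers,
                neurons_per_layer=config.mlp_neurons,
                mlp_max_iter=config.mlp_max_iter,
                seed=derive_seed(seed, family, block_name))
            fitted = grid_train(spec, prepped, labels, plan)
            name = f"{family}_{block_name}"
            models[name] = fitted
            probs[name] = predict_active_probability(fitted, prepped)
            thresholds[name] = optimal_threshold(
                roc(labels[train], probs[name][train])).threshold
            if config.include_cv:
                oof[name] = out_of_fold_probabilities(
                    spec, fitted.hyperparameters, prepped, labels, plan)

    result = PipelineResult(report=report, models=models,
                            thresholds=thresholds, probabilities=probs,
                            plan=plan, labels=labels, dropped_columns=dropped)

    # primary-model rows
    vsets = {"training": train, "test": plan.is_test}
    for name, fitted in models.items():
        family, block_name = name.split("_", 1)
        for vset, mask in vsets.items():
            rec = _metrics_at(labels[mask], probs[name][mask],
                              thresholds[name])
            report.add(ReportEntry(family, block_name, "primary", "-", vset,
                                   metrics=rec,
                                   active_ratio_kept=float(
                                       labels[mask].mean())))
        if config.include_cv:
            rec = _metrics_at(labels[train], oof[name][train],
                              thresholds[name])
            report.add(ReportEntry(family, block_name, "primary", "-", "cv",
                                   metrics=rec,
                                   active_ratio_kept=float(
                                       labels[train].mean())))

    # consensus rows per family and for all six primary models
    groups = {
        ("gbt", "all"): [n for n in models if n.startswith("gbt_")],
        ("mlp", "all"): [n for n in models if n.startswith("mlp_")],
        ("gbt+mlp", "all"): list(models),
    }
    for (learner, block), names in groups.items():
        matrices = {vset: result.matrix(names, mask)
                    for vset, mask in vsets.items()}
        if config.include_cv:
            cv_vals = np.column_stack([oof[m][train] for m in names])
            matrices["cv"] = ProbabilityMatrix(
                [f"row{i}" for i in np.flatnonzero(train)], names,
                cv_vals, labels[train])
        _consensus_rows(report, learner, block, matrices, names, thresholds)
    return result
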