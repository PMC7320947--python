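"""Probabilistic base learners, validation splits and grid optimization.

Two learner families are supported: gradient-boosted trees (optimized over
the tree depth) and multi-layer perceptrons (optimized over the number of
hidden layers and neurons per layer).  Hyperparameters are chosen by brute
force: every grid point is scored by stratified cross-validated AUC and the
winner is refit on the full training partition.  Any object exposing
``predict_active_probability``-compatible probabilities can stand in for a
fitted model downstream — the consensus layer is family-agnostic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from ._utils import derive_seed
from .featurization import FeatureBlock

FAMILIES = ("gbt", "mlp")

DEFAULT_GBT_DEPTHS = (2, 4, 6, 8, 10)
DEFAULT_MLP_LAYERS = (1, 2)
DEFAULT_MLP_NEURONS = (16, 64, 256)


@dataclass
class LearnerSpec:
    """Learner family plus its hyperparameter grid and seed.

    The grid is family-specific: ``tree_depth`` values for gbt; the cross
    product of ``hidden_layers`` and ``neurons_per_layer`` for mlp.
    """

    family: str
    tree_depth: Sequence[int] = DEFAULT_GBT_DEPTHS
    hidden_layers: Sequence[int] = DEFAULT_MLP_LAYERS
    neurons_per_layer: Sequence[int] = DEFAULT_MLP_NEURONS
    seed: int = 0
    mlp_max_iter: int = 200

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        grid = self.grid_points()
        if not grid:
            raise ValueError("empty hyperparameter grid")
        for point in grid:
            if any(int(v) <= 0 for v in point.values()):
                raise ValueError(f"non-positive grid value in {point}")

    def grid_points(self) -> list[dict[str, int]]:
        if self.family == "gbt":
            return [{"tree_depth": int(d)} for d in self.tree_depth]
        return [{"hidden_layers": int(l), "neurons_per_layer": int(n)}
                for l in self.hidden_layers for n in self.neurons_per_layer]

    def complexity(self, point: dict[str, int]) -> tuple:
        """Orders grid points from simpler to more complex (tie-breaking)."""
        if self.family == "gbt":
            return (point["tree_depth"],)
        return (point["hidden_layers"] * point["neurons_per_layer"],
                point["hidden_layers"])


@dataclass
class SplitPlan:
    """Stratified k-fold assignment plus a stratified train/test mask."""

    fold: np.ndarray          # fold index per row, -1 for test rows
    is_test: np.ndarray       # boolean mask
    k: int
    seed: int

    def __post_init__(self):
        self.fold = np.asarray(self.fold, dtype=int)
        self.is_test = np.asarray(self.is_test, dtype=bool)
        if self.fold.shape != self.is_test.shape:
            raise ValueError("fold and test masks misaligned")
        train_folds = self.fold[~self.is_test]
        if set(np.unique(train_folds)) != set(range(self.k)):
            raise ValueError("folds must partition the training rows")
        if np.any(self.fold[self.is_test] != -1):
            raise ValueError("test rows must carry fold = -1")

    @property
    def train_mask(self) -> np.ndarray:
        return ~self.is_test

    def to_csv(self, path: str | Path, ids: Sequence[str] | None = None
               ) -> None:
        import pandas as pd
        ids = ids if ids is not None else [str(i) for i in
                                           range(len(self.fold))]
        pd.DataFrame({"compound_id": ids, "fold": self.fold,
                      "is_test": self.is_test.astype(int)}
                     ).to_csv(path, index=False)


def make_splits(labels, k: int = 5, test_fraction: float = 0.30,
                seed: int = 0) -> SplitPlan:
    """Stratified 5-fold CV assignment nested inside a stratified 70/30 split.

    The train/test split is stratified so both partitions preserve the class
    ratio; the k folds then partition the *training* rows, each fold's class
    ratio within one compound of the global ratio.  Deterministic given seed.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels,
        random_state=derive_seed(seed, "train-test"))
    if np.min(np.bincount(labels[train_idx])) < k:
        raise ValueError(f"a class has fewer than k={k} training members")
    fold = np.full(len(labels), -1, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=derive_seed(seed, "folds"))
    for f, (_, val) in enumerate(skf.split(train_idx, labels[train_idx])):
        fold[train_idx[val]] = f
    is_test = np.zeros(len(labels), dtype=bool)
    is_test[test_idx] = True
    return SplitPlan(fold=fold, is_test=is_test, k=k, seed=seed)


# ---------------------------------------------------------------------------
# Fitted models


@dataclass
class FittedModel:
    """A trained probabilistic classifier plus its training metadata."""

    family: str
    hyperparameters: dict[str, int]
    block_name: str
    n_train: int
    seed: int
    cv_auc: float
    estimator: object = field(repr=False)
    feature_columns: list[str] = field(default_factory=list)

    def metadata(self) -> dict:
        return {"family": self.family,
                "hyperparameters": self.hyperparameters,
                "feature_block": self.block_name,
                "feature_columns": self.feature_columns,
                "n_train": self.n_train, "seed": self.seed,
                "cv_auc": self.cv_auc}

    def save_metadata(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2) + "\n")


def _make_estimator(spec: LearnerSpec, point: dict[str, int], seed: int):
    if spec.family == "gbt":
        return HistGradientBoostingClassifier(
            max_depth=point["tree_depth"], random_state=seed)
    hidden = (point["neurons_per_layer"],) * point["hidden_layers"]
    return MLPClassifier(hidden_layer_sizes=hidden, max_iter=spec.mlp_max_iter,
                         random_state=seed)


def _cv_auc(spec: LearnerSpec, point: dict[str, int], X: np.ndarray,
            y: np.ndarray, fold: np.ndarray) -> float:
    aucs = []
    for f in np.unique(fold):
        tr, va = fold != f, fold == f
        est = _make_estimator(spec, point, derive_seed(spec.seed, "cv", int(f)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            est.fit(X[tr], y[tr])
            p = est.predict_proba(X[va])[:, 1]
        aucs.append(roc_auc_score(y[va], p))
    return float(np.mean(aucs))


def grid_train(spec: LearnerSpec, features: FeatureBlock, labels,
               plan: SplitPlan) -> FittedModel:
    """Brute-force grid search by mean CV AUC, then refit on all training rows.

    Every grid point is scored with the plan's stratified folds (training
    partition only).  The highest mean CV AUC wins; ties break toward the
    simpler model.  A single-point grid skips the search and just refits.
    Grid points whose training fails are skipped with a warning; if every
    point fails, an error is raised.
    """
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != len(labels):
        raise ValueError("feature rows misaligned with labels")
    train = plan.train_mask
    X, y, fold = features.values[train], labels[train], plan.fold[train]

    points = spec.grid_points()
    scored: list[tuple[float, tuple, dict[str, int]]] = []
    if len(points) == 1:
        scored.append((float("nan"), spec.complexity(points[0]), points[0]))
    else:
        for point in points:
            try:
                auc = _cv_auc(spec, point, X, y, fold)
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"grid point {point} failed: {exc}",
                              stacklevel=2)
                continue
            scored.append((auc, spec.complexity(point), point))
        if not scored:
            raise RuntimeError("every grid point failed to train")
        scored.sort(key=lambda t: (-t[0], t[1]))
    best_auc, _, best_point = scored[0]

    est = _make_estimator(spec, best_point, derive_seed(spec.seed, "refit"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return FittedModel(family=spec.family, hyperparameters=best_point,
                       block_name=features.block_name, n_train=int(train.sum()),
                       seed=spec.seed, cv_auc=best_auc, estimator=est,
                       feature_columns=list(features.columns))


def out_of_fold_probabilities(spec: LearnerSpec, point: dict[str, int],
                              features: FeatureBlock, labels,
                              plan: SplitPlan) -> np.ndarray:
    """Held-out probabilities for every training row via the plan's folds.

    Fits the given grid point once per fold on the other folds and predicts
    the held-out fold.  Returns a full-length vector with NaN on test rows.
    """
    labels = np.asarray(labels, dtype=int)
    out = np.full(len(labels), np.nan)
    train_idx = np.flatnonzero(plan.train_mask)
    X, y = features.values[train_idx], labels[train_idx]
    fold = plan.fold[train_idx]
    for f in np.unique(fold):
        tr, va = fold != f, fold == f
        est = _make_estimator(spec, point, derive_seed(spec.seed, "oof", int(f)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[tr], y[tr])
            out[train_idx[va]] = np.clip(
                est.predict_proba(X[va])[:, 1], 0.0, 1.0)
    return out


def predict_active_probability(model: FittedModel,
                               features: FeatureBlock) -> np.ndarray:
    """Active-class probabilities in [0, 1] for rows matching the training schema."""
    if list(features.columns) != list(model.feature_columns):
        missing = set(model.feature_columns) - set(features.columns)
        extra = set(features.columns) - set(model.feature_columns)
        raise ValueError(
            f"feature schema mismatch: missing={sorted(missing)[:5]}, "
            f"extra={sorted(extra)[:5]}")
    p = model.estimator.predict_proba(features.values)[:, 1]
    return np.clip(p, 0.0, 1.0)
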