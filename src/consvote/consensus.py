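"""Consensus modeling over per-model active-class probabilities.

Two schemes combine M primary classifiers:

* **consensus 1** — pool the per-model probabilities row-wise (minimum,
  average or maximum) and evaluate the pooled score as a new classifier.
* **consensus 2** — unanimity voting: first threshold each model at its own
  optimized cutoff, keep only the compounds on which every model casts the
  same class call, then pool as above on the kept rows.  Excluded compounds
  are explicit "no-calls", not silent drops.

The statsmodels-style entry point is :class:`ConsensusModel`, whose
``fit()`` returns a :class:`ConsensusResults` with per-mode curves,
thresholds, metrics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .roc import RocCurve, ThresholdResult, apply_threshold, roc, \
    optimal_threshold
from .metrics import MetricsRecord, confusion, mcc, sensitivity, specificity

MODES = ("min", "ave", "max")


@dataclass
class ProbabilityMatrix:
    """Active-class probabilities from M primary models plus true labels."""

    ids: list[str]
    model_names: list[str]
    values: np.ndarray           # shape (n_compounds, M), each in [0, 1]
    labels: np.ndarray           # binary, 1 = active

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        n, m = self.values.shape
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError("row labels/ids misaligned with matrix")
        if len(self.model_names) != m:
            raise ValueError("model names misaligned with matrix")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing/non-finite probability cells")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("probabilities outside [0, 1]")

    @property
    def n_models(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "ProbabilityMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ProbabilityMatrix(
            [i for i, keep in zip(self.ids, mask) if keep],
            list(self.model_names), self.values[mask], self.labels[mask])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.model_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "compound_id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProbabilityMatrix":
        df = pd.read_csv(path)
        model_cols = [c for c in df.columns
                      if c not in ("compound_id", "label")]
        return cls(df["compound_id"].astype(str).tolist(), model_cols,
                   df[model_cols].to_numpy(), df["label"].to_numpy())


def pool(matrix: ProbabilityMatrix, mode: str) -> np.ndarray:
    """Row-wise min/mean/max pooling of the per-model probabilities."""
    if matrix.values.size == 0:
        raise ValueError("empty probability matrix")
    if mode == "min":
        return matrix.values.min(axis=1)
    if mode == "ave":
        return matrix.values.mean(axis=1)
    if mode == "max":
        return matrix.values.max(axis=1)
    raise ValueError(f"unknown pooling mode {mode!r} (use min/ave/max)")


@dataclass
class ConsensusResult:
    """One pooling mode's consensus output with exclusion bookkeeping."""

    mode: str
    pooled: np.ndarray                 # pooled probabilities on kept rows
    keep_mask: np.ndarray              # over the input rows; all-true for c1
    curve: RocCurve
    threshold: ThresholdResult         # optimized on the pooled probabilities
    excluded_ratio: float
    active_ratio_kept: float

    @property
    def auc(self) -> float:
        return self.curve.auc


def consensus1(matrix: ProbabilityMatrix,
               modes: Sequence[str] = MODES) -> dict[str, ConsensusResult]:
    """Probability pooling without exclusion: every compound keeps a call."""
    out = {}
    keep = np.ones(len(matrix.ids), dtype=bool)
    for mode in modes:
        pooled = pool(matrix, mode)
        curve = roc(matrix.labels, pooled)
        out[mode] = ConsensusResult(
            mode=mode, pooled=pooled, keep_mask=keep, curve=curve,
            threshold=optimal_threshold(curve), excluded_ratio=0.0,
            active_ratio_kept=float(matrix.labels.mean()))
    return out


def agreement_mask(class_matrix: np.ndarray) -> np.ndarray:
    """True where all models assign the identical class (row uniformity)."""
    class_matrix = np.asarray(class_matrix, dtype=int)
    return np.all(class_matrix == class_matrix[:, :1], axis=1)


def consensus2(matrix: ProbabilityMatrix,
               thresholds: Mapping[str, float] | Sequence[float],
               modes: Sequence[str] = MODES) -> dict[str, ConsensusResult]:
    """Unanimity voting: exclude disagreement rows, then pool the rest.

    ``thresholds`` carries each model's own optimized cutoff (mapping by
    model name, or a sequence in column order); each model votes with its
    own threshold, and only unanimous rows enter the pooled evaluation.
    """
    if isinstance(thresholds, Mapping):
        t = np.array([thresholds[m] for m in matrix.model_names])
    else:
        t = np.asarray(list(thresholds), dtype=np.float64)
    if t.shape != (matrix.n_models,):
        raise ValueError("need exactly one threshold per model")

    classes = np.column_stack([
        apply_threshold(matrix.values[:, j], t[j])
        for j in range(matrix.n_models)])
    keep = agreement_mask(classes)
    if not keep.any():
        raise ValueError("consensus 2 excluded every compound "
                         "(no unanimous rows)")
    kept = matrix.subset(keep)
    if len(np.unique(kept.labels)) < 2:
        raise ValueError("consensus 2 kept rows are single-class; "
                         "AUC undefined on the kept subset")
    excluded_ratio = 1.0 - float(keep.mean())
    out = {}
    for mode in modes:
        pooled = pool(kept, mode)
        curve = roc(kept.labels, pooled)
        out[mode] = ConsensusResult(
            mode=mode, pooled=pooled, keep_mask=keep, curve=curve,
            threshold=optimal_threshold(curve),
            excluded_ratio=excluded_ratio,
            active_ratio_kept=float(kept.labels.mean()))
    return out


# ---------------------------------------------------------------------------
# Model/Results interface


class ConsensusModel:
    """Consensus classifier over a matrix of primary-model probabilities.

    Parameters
    ----------
    matrix
        Per-model active-class probabilities with true labels.
    scheme
        1 for probability pooling, 2 for unanimity voting.
    thresholds
        Per-model optimized cutoffs (required context for scheme 2 when the
        matrix rows are evaluation data).  When omitted, each model's cutoff
        is optimized on this matrix's own labels — appropriate only for
        training data.
    """

    def __init__(self, matrix: ProbabilityMatrix, scheme: int = 2,
                 thresholds: Mapping[str, float] | Sequence[float] | None = None):
        if scheme not in (1, 2):
            raise ValueError("scheme must be 1 or 2")
        if scheme == 2 and matrix.n_models < 2:
            raise ValueError("consensus voting needs at least 2 models")
        self.matrix = matrix
        self.scheme = scheme
        self.thresholds = thresholds

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       id_col: str = "compound_id", **kwargs
                       ) -> "ConsensusModel":
        model_cols = [c for c in df.columns if c not in (label_col, id_col)]
        ids = (df[id_col].astype(str).tolist() if id_col in df.columns
               else [str(i) for i in df.index])
        matrix = ProbabilityMatrix(ids, model_cols,
                                   df[model_cols].to_numpy(),
                                   df[label_col].to_numpy())
        return cls(matrix, **kwargs)

    def _model_thresholds(self) -> np.ndarray:
        if self.thresholds is not None:
            if isinstance(self.thresholds, Mapping):
                return np.array([self.thresholds[m]
                                 for m in self.matrix.model_names])
            return np.asarray(list(self.thresholds), dtype=np.float64)
        return np.array([
            optimal_threshold(roc(self.matrix.labels,
                                  self.matrix.values[:, j])).threshold
            for j in range(self.matrix.n_models)])

    def fit(self, modes: Sequence[str] = MODES) -> "ConsensusResults":
        t = self._model_thresholds()
        if self.scheme == 1:
            per_mode = consensus1(self.matrix, modes)
        else:
            per_mode = consensus2(self.matrix, t, modes)
        return ConsensusResults(self, per_mode, t)


class ConsensusResults:
    """Fitted consensus estimates: per-mode curves, cutoffs and metrics."""

    def __init__(self, model: ConsensusModel,
                 per_mode: dict[str, ConsensusResult],
                 model_thresholds: np.ndarray):
        self.model = model
        self.per_mode = per_mode
        self.model_thresholds = model_thresholds

    def __getitem__(self, mode: str) -> ConsensusResult:
        return self.per_mode[mode]

    @property
    def modes(self) -> list[str]:
        return list(self.per_mode)

    def metrics(self, mode: str) -> MetricsRecord:
        """AUC/MCC/Sn/Sp of one mode at its optimized pooled cutoff."""
        res = self.per_mode[mode]
        labels = self.model.matrix.labels[res.keep_mask]
        preds = apply_threshold(res.pooled, res.threshold.threshold)
        c = confusion(labels, preds)
        return MetricsRecord(auc=res.auc, mcc=mcc(c), sn=sensitivity(c),
                             sp=specificity(c), n=c.n)

    def predict(self, mode: str = "ave") -> pd.DataFrame:
        """Per-compound calls: kept flag, pooled probability, class or no-call."""
        res = self.per_mode[mode]
        n = len(self.model.matrix.ids)
        pooled = np.full(n, np.nan)
        pooled[res.keep_mask] = res.pooled
        pred = np.full(n, -1, dtype=int)  # -1 = no-call (excluded)
        pred[res.keep_mask] = apply_threshold(res.pooled,
                                              res.threshold.threshold)
        return pd.DataFrame({
            "compound_id": self.model.matrix.ids,
            "kept": res.keep_mask,
            "pooled_prob": pooled,
            "predicted_class": pred})

    def summary(self) -> str:
        rows = []
        for mode in self.per_mode:
            m = self.metrics(mode)
            res = self.per_mode[mode]
            rows.append({
                "mode": mode, "AUC": m.auc, "MCC": m.mcc, "Sn": m.sn,
                "Sp": m.sp, "threshold": res.threshold.threshold,
                "d": res.threshold.distance, "n_kept": m.n,
                "excluded_ratio": res.excluded_ratio,
                "actives_kept_%": 100 * res.active_ratio_kept})
        df = pd.DataFrame(rows).set_index("mode").round(3)
        header = (f"Consensus {self.model.scheme} "
                  f"({self.model.matrix.n_models} primary models, "
                  f"n={len(self.model.matrix.ids)}; active = positive class)")
        return header + "\n" + df.to_string()
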