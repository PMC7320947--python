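"""Confusion-matrix metrics (MCC, sensitivity, specificity) and reporting.

"Active" is the positive class throughout.  Reported tables round to two
decimals; the machine-readable report keeps full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("negative confusion counts")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels, predictions) -> ConfusionCounts:
    """Tally the 2x2 confusion matrix (active = positive = 1)."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {labels.shape} vs {predictions.shape}")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fn=int(np.sum((labels == 1) & (predictions == 0))))


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any margin is empty."""
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / denom


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate tp/(tp+fn); NaN when no positives were evaluated."""
    if c.tp + c.fn == 0:
        return float("nan")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate tn/(tn+fp); NaN when no negatives were evaluated."""
    if c.tn + c.fp == 0:
        return float("nan")
    return c.tn / (c.tn + c.fp)


@dataclass
class MetricsRecord:
    """One evaluation cell: AUC plus threshold-based confusion metrics."""

    auc: float
    mcc: float
    sn: float
    sp: float
    n: int

    @classmethod
    def from_predictions(cls, labels, probs, predictions, auc: float
                         ) -> "MetricsRecord":
        c = confusion(labels, predictions)
        return cls(auc=float(auc), mcc=mcc(c), sn=sensitivity(c),
                   sp=specificity(c), n=c.n)


# ---------------------------------------------------------------------------
# Structured multi-table report

#: report key order: learner family / feature block / scheme / pooling mode /
#: validation set
KEY_FIELDS = ("learner", "block", "scheme", "mode", "validation")


@dataclass
class ReportEntry:
    learner: str          # "gbt", "mlp" or "gbt+mlp" for 6-model consensus
    block: str            # feature block, or "all" for 6-model consensus
    scheme: str           # "primary", "consensus1", "consensus2"
    mode: str             # "-" for primary, else "min"/"ave"/"max"
    validation: str       # "training", "cv", "test", "external"
    metrics: MetricsRecord
    excluded_ratio: float = 0.0
    active_ratio_kept: float = float("nan")

    @property
    def key(self) -> tuple[str, ...]:
        return (self.learner, self.block, self.scheme, self.mode,
                self.validation)


class EvaluationReport:
    """Collection of evaluation cells with table rendering and round-trip I/O."""

    def __init__(self):
        self._entries: dict[tuple[str, ...], ReportEntry] = {}

    def add(self, entry: ReportEntry) -> None:
        if entry.key in self._entries:
            raise ValueError(f"duplicate report key {entry.key}")
        self._entries[entry.key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def entries(self) -> list[ReportEntry]:
        return list(self._entries.values())

    def get(self, **query) -> list[ReportEntry]:
        out = []
        for e in self._entries.values():
            if all(getattr(e, k) == v for k, v in query.items()):
                out.append(e)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self._entries.values():
            row = dict(zip(KEY_FIELDS, e.key))
            row.update(asdict(e.metrics))
            row["excluded_ratio"] = e.excluded_ratio
            row["active_ratio_kept"] = e.active_ratio_kept
            rows.append(row)
        return pd.DataFrame(rows)

    def render(self, metric: str = "auc") -> str:
        """Plain-text pivot (validation sets as rows) of one metric."""
        df = self.to_frame()
        pivot = df.pivot_table(index="validation",
                               columns=["learner", "block", "scheme", "mode"],
                               values=metric, aggfunc="first")
        order = [v for v in ("training", "cv", "test", "external")
                 if v in pivot.index]
        return pivot.loc[order].round(2).to_string()

    # -- lossless JSON round trip -------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = []
        for e in self._entries.values():
            d = dict(zip(KEY_FIELDS, e.key))
            d["metrics"] = asdict(e.metrics)
            d["excluded_ratio"] = e.excluded_ratio
            d["active_ratio_kept"] = e.active_ratio_kept
            payload.append(d)
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "EvaluationReport":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        report = cls()
        for d in json.loads(text):
            report.add(ReportEntry(
                **{k: d[k] for k in KEY_FIELDS},
                metrics=MetricsRecord(**d["metrics"]),
                excluded_ratio=d["excluded_ratio"],
                active_ratio_kept=d["active_ratio_kept"]))
        return report


def build_report(runs: Mapping[tuple[str, str, str, str, str], dict]
                 ) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from keyed run results.

    ``runs`` maps (learner, block, scheme, mode, validation) to a dict with a
    ``metrics`` :class:`MetricsRecord` and optional ``excluded_ratio`` /
    ``active_ratio_kept`` fields.  Duplicate keys raise.
    """
    if not runs:
        raise ValueError("at least one run is required")
    report = EvaluationReport()
    for key, payload in runs.items():
        report.add(ReportEntry(
            *key, metrics=payload["metrics"],
            excluded_ratio=payload.get("excluded_ratio", 0.0),
            active_ratio_kept=payload.get("active_ratio_kept", float("nan"))))
    return report
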