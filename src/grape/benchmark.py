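"""Binary-classification metrics for benchmarking stability predictors.

A predictor calls a mutation stabilizing when its score passes the
algorithm's threshold; experiment calls it stabilizing when the measured
ΔΔG is at or below −|threshold| (negative = stabilizing) or the measured
ΔTm is at or above the threshold (default 1.5 °C). Crossing the two labels
gives the confusion counts, from which sensitivity, specificity, precision,
accuracy and F1 are computed. The ensemble ("union") row labels a mutation
predicted-stabilizing when any member algorithm selects it — union can only
add predicted positives, so ensemble sensitivity never drops below any
member's while specificity never exceeds any member's.

Metrics with a zero denominator are reported as ``None`` (rendered ``NA``)
rather than 0, so undefined values never silently deflate averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ThresholdConfig

__all__ = [
    "LabeledMutation",
    "ConfusionCounts",
    "ClassificationMetrics",
    "label_stabilizing",
    "confusion",
    "metrics",
    "f1_from_rates",
    "benchmark_report",
    "read_labeled_csv",
]


@dataclass(frozen=True)
class LabeledMutation:
    """A mutation with an experimental stability measurement and predictor
    scores. ``measure`` says which convention the value uses: ``"ddg"``
    (kcal/mol, negative = stabilizing) or ``"dtm"`` (°C, positive =
    stabilizing)."""

    mutation: str
    experimental_value: float
    measure: str
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.measure not in ("ddg", "dtm"):
            raise ValueError(f"measure must be 'ddg' or 'dtm', got {self.measure!r}")
        if not math.isfinite(self.experimental_value):
            raise ValueError(f"non-finite experimental value for {self.mutation}")


def label_stabilizing(
    data: list[LabeledMutation],
    experimental_threshold: float | None = None,
    measure: str = "ddg",
) -> list[bool]:
    """Experimental stabilizing labels.

    ddg mode: stabilizing iff ΔΔG <= −|threshold| (default threshold 0);
    dtm mode: stabilizing iff ΔTm >= threshold (default 1.5 °C). Both
    boundaries are inclusive.
    """
    if experimental_threshold is None:
        experimental_threshold = 0.0 if measure == "ddg" else 1.5
    labels = []
    for item in data:
        if item.measure != measure:
            raise ValueError(
                f"{item.mutation}: measure {item.measure!r} does not match "
                f"requested {measure!r}"
            )
        if measure == "ddg":
            labels.append(item.experimental_value <= -abs(experimental_threshold))
        else:
            labels.append(item.experimental_value >= experimental_threshold)
    return labels


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted: list[bool], actual: list[bool]) -> ConfusionCounts:
    """Cross-tabulate predicted vs experimental stabilizing labels."""
    if len(predicted) != len(actual):
        raise ValueError(
            f"label length mismatch: {len(predicted)} vs {len(actual)}"
        )
    p = np.asarray(predicted, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(p & a)),
        fp=int(np.sum(p & ~a)),
        tn=int(np.sum(~p & ~a)),
        fn=int(np.sum(~p & a)),
    )


@dataclass(frozen=True)
class ClassificationMetrics:
    """Sensitivity, specificity, precision, accuracy and F1; ``None`` marks
    an undefined (0/0) metric."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    f1: float | None


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """Standard metric set from confusion counts.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    precision = tp/(tp+fp), accuracy = (tp+tn)/total,
    f1 = 2·precision·sensitivity/(precision+sensitivity).
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    acc = _ratio(counts.tp + counts.tn, counts.total)
    f1 = None
    if prec is not None and sens is not None and prec + sens > 0:
        f1 = f1_from_rates(prec, sens)
    elif prec is not None and sens is not None:
        f1 = 0.0 if counts.tp == 0 and (counts.fp or counts.fn) else None
    return ClassificationMetrics(sens, spec, prec, acc, f1)


def f1_from_rates(precision: float, sensitivity: float) -> float | None:
    """Harmonic mean of precision and sensitivity (recall).

    This identity lets published metric rows be cross-checked: the printed
    F1 of a predictor must equal ``f1_from_rates`` of its printed precision
    and sensitivity up to input rounding.
    """
    for value in (precision, sensitivity):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"rate {value} outside [0, 1]")
    if precision + sensitivity == 0:
        return None
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def benchmark_report(
    data: list[LabeledMutation],
    thresholds: ThresholdConfig | None = None,
    measure: str = "ddg",
    experimental_threshold: float | None = None,
) -> pd.DataFrame:
    """Metric table, one row per scoring algorithm plus a ``union`` ensemble
    row where predicted-stabilizing means selected by any algorithm.

    Column order: algorithm, threshold, sensitivity, specificity, precision,
    accuracy, f1. An algorithm is skipped for a mutation it did not score
    (treated as not-selected for that mutation).
    """
    thresholds = thresholds or ThresholdConfig()
    algorithms = sorted({a for item in data for a in item.scores})
    if not algorithms:
        raise ValueError("no scored algorithms in the data")
    actual = label_stabilizing(data, experimental_threshold, measure)

    def row(name: str, threshold, predicted: list[bool]) -> dict:
        m = metrics(confusion(predicted, actual))
        return {
            "algorithm": name, "threshold": threshold,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "precision": m.precision, "accuracy": m.accuracy, "f1": m.f1,
        }

    rows = []
    per_algo_predicted: dict[str, list[bool]] = {}
    for algo in algorithms:
        predicted = [
            algo in item.scores and thresholds.passes(algo, item.scores[algo])
            for item in data
        ]
        per_algo_predicted[algo] = predicted
        rows.append(row(algo, thresholds.thresholds.get(algo), predicted))
    union_predicted = [
        any(per_algo_predicted[a][i] for a in algorithms)
        for i in range(len(data))
    ]
    rows.append(row("union", "/".join(
        str(thresholds.thresholds.get(a)) for a in algorithms), union_predicted))
    return pd.DataFrame(rows, columns=[
        "algorithm", "threshold", "sensitivity", "specificity",
        "precision", "accuracy", "f1",
    ])


def read_labeled_csv(path) -> list[LabeledMutation]:
    """Read a labeled-data CSV ``mutation,experimental_value,measure,<algo>...``."""
    df = pd.read_csv(path)
    required = {"mutation", "experimental_value", "measure"}
    if not required <= set(df.columns):
        raise ValueError(f"labeled CSV needs columns {sorted(required)}")
    score_cols = [c for c in df.columns if c not in required]
    out = []
    for _, r in df.iterrows():
        scores = {c: float(r[c]) for c in score_cols if pd.notna(r[c])}
        out.append(LabeledMutation(
            mutation=str(r["mutation"]),
            experimental_value=float(r["experimental_value"]),
            measure=str(r["measure"]),
            scores=scores,
        ))
    return out
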