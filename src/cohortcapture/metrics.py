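"""Per-database diagnostic accuracy against a gold standard.

Confusion-matrix metrics (accuracy, precision/PPV, NPV, recall/sensitivity,
specificity, F1) with percentile-bootstrap 95% intervals over patient-level
resamples.  Zero-denominator cells (e.g. a registry database that flags
everyone, leaving no negatives) are reported as 0 together with a
structured warning rather than NaN, matching the convention of clinical
validation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion",
    "metrics",
    "bootstrap_intervals",
    "rank_by_precision",
    "database_metrics_table",
    "DegenerateCellWarning",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "precision", "npv", "recall", "specificity", "f1")


class DegenerateCellWarning(UserWarning):
    """A metric had a zero denominator and was reported as 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSet:
    """Point estimates (and optionally intervals) of the six metrics."""

    accuracy: float
    precision: float
    npv: float
    recall: float
    specificity: float
    f1: float
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    degenerate: tuple[str, ...] = ()
    coverage_count: int | None = None
    coverage_fraction: float | None = None

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x).astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return arr


def confusion(pred, truth) -> ConfusionCounts:
    """Confusion counts from aligned binary prediction and truth vectors."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(
            f"pred and truth must align: lengths {p.shape[0]} vs {t.shape[0]}"
        )
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & (1 - t))),
        fn=int(np.count_nonzero((1 - p) & t)),
        tn=int(np.count_nonzero((1 - p) & (1 - t))),
    )


def _ratio(num: int, denom: int, name: str, degenerate: list[str]) -> float:
    if denom == 0:
        degenerate.append(name)
        return 0.0
    return num / denom


def metrics(counts: ConfusionCounts, warn: bool = True) -> MetricSet:
    """The six standard metrics from a confusion table.

    Undefined ratios (zero denominator) come back as 0 and are listed in
    ``MetricSet.degenerate``; a ``DegenerateCellWarning`` is emitted unless
    ``warn=False``.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics over zero evaluated patients")
    degenerate: list[str] = []
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision", degenerate)
    npv = _ratio(counts.tn, counts.tn + counts.fn, "npv", degenerate)
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall", degenerate)
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity", degenerate)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if degenerate and warn:
        warnings.warn(
            f"zero-denominator metrics reported as 0: {degenerate}",
            DegenerateCellWarning,
            stacklevel=2,
        )
    return MetricSet(
        accuracy=accuracy,
        precision=precision,
        npv=npv,
        recall=recall,
        specificity=specificity,
        f1=f1,
        degenerate=tuple(degenerate),
    )


def bootstrap_intervals(
    pred, truth, n_reps: int = 1000, seed: int = 0, alpha: float = 0.05
) -> MetricSet:
    """Point metrics with percentile bootstrap intervals.

    Patients are resampled with replacement ``n_reps`` times; the
    2.5th/97.5th percentiles of each metric across resamples form the
    interval.  Deterministic for a fixed ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError("pred and truth must align")
    if len(np.unique(t)) < 2:
        warnings.warn(
            "gold-standard labels are all one class; intervals cover defined "
            "metrics only",
            DegenerateCellWarning,
            stacklevel=2,
        )
    point = metrics(confusion(p, t), warn=False)
    rng = np.random.default_rng(seed)
    n = p.shape[0]
    samples: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        ms = metrics(confusion(p[idx], t[idx]), warn=False)
        for m in METRIC_NAMES:
            samples[m].append(ms[m])
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    point.intervals = {
        m: (
            float(np.percentile(samples[m], lo)),
            float(np.percentile(samples[m], hi)),
        )
        for m in METRIC_NAMES
    }
    return point


def rank_by_precision(metric_sets: dict[str, MetricSet]) -> list[str]:
    """Databases ordered by descending precision point estimate.

    Ties keep the declared (insertion) order — a stable sort — so equally
    precise databases rank in the order supplied.
    """
    if not metric_sets:
        raise ValueError("need at least one database")
    names = list(metric_sets)
    return sorted(names, key=lambda n: -metric_sets[n].precision)


def database_metrics_table(
    membership: pd.DataFrame,
    gold: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One validation-table row per database, evaluated on the gold standard.

    ``gold`` needs ``patient_id`` and binary ``label`` columns.  Coverage
    is the count (and fraction) of gold-standard patients flagged in the
    database; flags for patients absent from ``membership`` are treated
    as 0 (missing-as-zero convention).
    """
    gold = gold.set_index("patient_id") if "patient_id" in gold.columns else gold
    truth = gold["label"].astype(int)
    aligned = membership.reindex(truth.index).fillna(0).astype(int)
    rows = []
    for i, db in enumerate(aligned.columns):
        pred = aligned[db].to_numpy()
        ms = bootstrap_intervals(pred, truth.to_numpy(), n_reps=n_reps, seed=seed + i)
        cov = int(pred.sum())
        row: dict[str, object] = {
            "database": db,
            "coverage_count": cov,
            "coverage_fraction": cov / len(truth),
        }
        for m in METRIC_NAMES:
            lo, hi = ms.intervals[m]
            row[m] = ms[m]
            row[f"{m}_lo"] = lo
            row[f"{m}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
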