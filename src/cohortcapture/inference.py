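"""Recursive Jaccard capture-recapture estimation of total cohort size.

The protocol integrates flagged-positive patient sets from many partially
overlapping databases, ordered by diagnostic precision:

1. Start from the primary database (diagnostic billing codes); its flagged
   count times its precision gives the base true-positive estimate.
2. Take the remaining databases in descending order of precision.  At each
   step, compute the overlap between the running "Combined" union and the
   next database; the patients unique to the new database (flagged minus
   intersection) are multiplied by that database's precision and added to
   the cumulative true-positive estimate, and the union absorbs them.
3. Repeat until no databases remain.

The running union tracks *flagged* patients (not precision-discounted
ones), while the cumulative total tracks estimated true positives.  The
method assumes each database's precision applies equally to patients in
the intersection and patients unique to it; where unique strata are in
truth less precise, the protocol overestimates — it is an upper estimate.

Two modes are supported: ``set_based`` (actual patient-id sets, overlaps
computed exactly) and ``summary_replay`` (printed flagged/intersection
counts from a published table are consumed directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._rounding import round_half_away, round_half_up_places

__all__ = [
    "InferenceStep",
    "InferenceTrace",
    "order_databases",
    "run_inference_sets",
    "replay_summary",
    "load_bundled_summary",
    "combine_estimates",
    "missed_fraction",
]


@dataclass(frozen=True)
class InferenceStep:
    """One row of the capture-recapture trace.

    ``jaccard_with_combined`` is reported to 3 decimal places (half-up);
    ``None`` for the base (primary-database) step, where the whole flagged
    set is unique by construction.
    """

    database: str
    flagged: int
    jaccard_with_combined: float | None
    intersection: int
    unique: int
    precision: float
    incremental_tp: int
    cumulative_tp: int
    combined_size: int

    def __post_init__(self) -> None:
        if self.unique != self.flagged - self.intersection:
            raise ValueError("unique must equal flagged - intersection")
        if self.cumulative_tp > self.combined_size:
            raise ValueError(
                "cumulative true positives cannot exceed the combined union size"
            )


@dataclass
class InferenceTrace:
    """Ordered capture-recapture steps plus the final totals."""

    steps: list[InferenceStep] = field(default_factory=list)
    mode: str = "summary_replay"

    @property
    def combined_size(self) -> int:
        return self.steps[-1].combined_size if self.steps else 0

    @property
    def cumulative_tp(self) -> int:
        return self.steps[-1].cumulative_tp if self.steps else 0

    @property
    def integrated(self) -> list[str]:
        return [s.database for s in self.steps]

    def step_for(self, database: str) -> InferenceStep:
        for s in self.steps:
            if s.database == database:
                return s
        raise KeyError(database)

    def to_frame(self) -> pd.DataFrame:
        """Trace as a table mirroring the published layout."""
        return pd.DataFrame(
            {
                "database": [s.database for s in self.steps],
                "flagged": [s.flagged for s in self.steps],
                "jaccard_with_combined": [s.jaccard_with_combined for s in self.steps],
                "intersection": [s.intersection for s in self.steps],
                "unique": [s.unique for s in self.steps],
                "precision": [s.precision for s in self.steps],
                "incremental_tp": [s.incremental_tp for s in self.steps],
                "cumulative_tp": [s.cumulative_tp for s in self.steps],
                "combined_size": [s.combined_size for s in self.steps],
            }
        )


def order_databases(
    precisions: Mapping[str, float], primary_name: str
) -> list[str]:
    """Primary database first, the rest sorted by precision descending.

    Ties keep the declared (insertion) order of ``precisions`` — a stable
    sort — so equally precise databases integrate in the order listed.
    """
    if primary_name not in precisions:
        raise KeyError(f"primary database {primary_name!r} not among precisions")
    rest = [name for name in precisions if name != primary_name]
    rest.sort(key=lambda name: -precisions[name])
    return [primary_name, *rest]


def _base_step(name: str, flagged: int, precision: float) -> InferenceStep:
    if flagged < 0:
        raise ValueError("flagged count must be non-negative")
    if not 0.0 <= precision <= 1.0:
        raise ValueError(f"precision must lie in [0, 1], got {precision}")
    tp = round_half_away(flagged * precision)
    return InferenceStep(
        database=name,
        flagged=flagged,
        jaccard_with_combined=None,
        intersection=0,
        unique=flagged,
        precision=precision,
        incremental_tp=tp,
        cumulative_tp=tp,
        combined_size=flagged,
    )


def _next_step(
    prev: InferenceStep,
    name: str,
    flagged: int,
    intersection: int,
    precision: float,
) -> InferenceStep:
    combined = prev.combined_size
    if intersection > min(flagged, combined):
        raise ValueError(
            f"intersection {intersection} exceeds min(flagged={flagged}, "
            f"combined={combined}) at database {name!r}"
        )
    if not 0.0 <= precision <= 1.0:
        raise ValueError(f"precision must lie in [0, 1], got {precision}")
    union = combined + flagged - intersection
    j = round_half_up_places(intersection / union, 3) if union else 0.0
    unique = flagged - intersection
    incremental = round_half_away(unique * precision)
    return InferenceStep(
        database=name,
        flagged=flagged,
        jaccard_with_combined=j,
        intersection=intersection,
        unique=unique,
        precision=precision,
        incremental_tp=incremental,
        cumulative_tp=prev.cumulative_tp + incremental,
        combined_size=combined + unique,
    )


def run_inference_sets(
    flagged_sets: Mapping[str, Iterable],
    precisions: Mapping[str, float],
    primary: str,
) -> InferenceTrace:
    """Capture-recapture over actual flagged patient-id sets.

    Overlaps with the running combined set are computed exactly, so the
    final ``combined_size`` equals the true size of the union of all
    flagged sets.
    """
    order = order_databases(precisions, primary)
    missing = [n for n in order if n not in flagged_sets]
    if missing:
        raise KeyError(f"no flagged set supplied for databases: {missing}")
    sets = {name: set(flagged_sets[name]) for name in order}
    trace = InferenceTrace(mode="set_based")
    combined: set = set(sets[order[0]])
    trace.steps.append(_base_step(order[0], len(combined), precisions[order[0]]))
    for name in order[1:]:
        s = sets[name]
        step = _next_step(
            trace.steps[-1], name, len(s), len(combined & s), precisions[name]
        )
        combined |= s
        assert len(combined) == step.combined_size
        trace.steps.append(step)
    return trace


def replay_summary(summary: pd.DataFrame) -> InferenceTrace:
    """Replay a published summary table through the protocol.

    ``summary`` needs columns ``database``, ``flagged``, ``intersection``
    and ``precision``, with the primary database first and the remaining
    rows in protocol (precision-descending) order; each ``intersection``
    is the printed overlap with the running combined set at that point.
    Printed intersections are consumed directly rather than re-derived
    from 3-decimal Jaccard values, which would introduce ±1 rounding
    errors.
    """
    required = {"database", "flagged", "intersection", "precision"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary table is missing columns: {sorted(missing)}")
    if len(summary) < 1:
        raise ValueError("summary table is empty")
    rows = summary.reset_index(drop=True)
    trace = InferenceTrace(mode="summary_replay")
    first = rows.iloc[0]
    trace.steps.append(
        _base_step(str(first["database"]), int(first["flagged"]), float(first["precision"]))
    )
    for _, row in rows.iloc[1:].iterrows():
        trace.steps.append(
            _next_step(
                trace.steps[-1],
                str(row["database"]),
                int(row["flagged"]),
                int(row["intersection"]),
                float(row["precision"]),
            )
        )
    return trace


def load_bundled_summary() -> pd.DataFrame:
    """The bundled published capture-recapture summary table.

    Eleven databases of a single-centre inflammatory bowel disease cohort:
    flagged-positive counts, intersections with the running combined set,
    and gold-standard precisions, in protocol order.
    """
    with resources.files("cohortcapture.data").joinpath("reference_summary.csv").open() as fh:
        return pd.read_csv(fh)


def combine_estimates(
    model_confident_tp: int, unaccounted_unique_tps: Sequence[int]
) -> int:
    """Combined estimate: model-identified true positives plus the
    unaccounted-for unique true positives of additional databases."""
    if model_confident_tp < 0 or any(x < 0 for x in unaccounted_unique_tps):
        raise ValueError("estimates must be non-negative")
    return int(model_confident_tp) + int(sum(unaccounted_unique_tps))


def missed_fraction(baseline_estimate: int, full_estimate: int) -> float:
    """Percentage of the full cohort missed by the baseline estimate, 1 d.p.

    100 · (full − baseline) / full, requiring full ≥ baseline > 0.
    """
    if full_estimate <= 0:
        raise ValueError("full estimate must be positive")
    if baseline_estimate <= 0 or baseline_estimate > full_estimate:
        raise ValueError("need full >= baseline > 0")
    return round_half_up_places(
        100.0 * (full_estimate - baseline_estimate) / full_estimate, 1
    )
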