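"""Pairwise set-overlap analysis of database membership.

Computes Jaccard similarity indices between databases, the closed-form
intersection size implied by a Jaccard index and two set sizes, and
UpSet-style cardinality summaries (how many patients appear in exactly /
at least k databases, and per-combination counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rounding import round_half_away

__all__ = [
    "jaccard",
    "intersection_from_jaccard",
    "jaccard_matrix",
    "cardinality_summary",
    "classify_jaccard",
    "JaccardMatrix",
    "CardinalitySummary",
    "EmptyColumnWarning",
    "HIGH_JACCARD",
    "LOW_JACCARD",
]

# Conventional interpretation thresholds for database-comparison work:
# above 0.75 the overlap is considered high, below 0.35 low.
HIGH_JACCARD = 0.75
LOW_JACCARD = 0.35


class EmptyColumnWarning(UserWarning):
    """A flagged-only subset left a database with no members."""


def jaccard(set_a, set_b) -> float:
    """Jaccard similarity |A ∩ B| / |A ∪ B| between two collections.

    Raises ``ValueError`` when both sets are empty (the index is undefined).
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index is undefined for two empty sets")
    return len(a & b) / len(union)


def intersection_from_jaccard(size_a: int, size_b: int, j: float) -> int:
    """Invert the Jaccard index: intersection size from |A|, |B| and J.

    From J = I / (|A| + |B| - I) it follows that
    I = J (|A| + |B|) / (1 + J).  The result is rounded half away from
    zero, so a 3-decimal J reproduces printed intersection counts to ±1.
    """
    if size_a < 0 or size_b < 0:
        raise ValueError("set sizes must be non-negative")
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard index must lie in [0, 1], got {j}")
    return round_half_away(j * (size_a + size_b) / (1.0 + j))


@dataclass
class JaccardMatrix:
    """Symmetric matrix of pairwise Jaccard indices between databases."""

    values: pd.DataFrame
    subset: str  # "all_patients" or "flagged_only"

    @property
    def databases(self) -> list[str]:
        return list(self.values.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format (db_a, db_b, subset, jaccard) table, upper triangle."""
        rows = []
        names = self.databases
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                rows.append(
                    {"db_a": a, "db_b": b, "subset": self.subset,
                     "jaccard": self.values.loc[a, b]}
                )
        return pd.DataFrame(rows)


def classify_jaccard(j: float) -> str:
    """Categorize an index as ``high`` (> 0.75), ``low`` (< 0.35) or ``moderate``."""
    if j > HIGH_JACCARD:
        return "high"
    if j < LOW_JACCARD:
        return "low"
    return "moderate"


def jaccard_matrix(
    membership: pd.DataFrame,
    subset: str = "all_patients",
    flags: pd.DataFrame | None = None,
) -> JaccardMatrix:
    """Pairwise Jaccard matrix over the columns of a binary membership table.

    Parameters
    ----------
    membership:
        Binary patient × database table (index = patient id).
    subset:
        ``"all_patients"`` computes overlap on the raw membership columns;
        ``"flagged_only"`` restricts each database to its flag-positive set
        (``flags`` if given, otherwise ``membership`` itself, which for a
        0/1 flag matrix is the same thing).
    """
    if membership.shape[1] < 2:
        raise ValueError("need at least two databases to compare")
    if subset not in ("all_patients", "flagged_only"):
        raise ValueError(f"unknown subset {subset!r}")
    table = membership if subset == "all_patients" or flags is None else flags
    mat = table.to_numpy(dtype=bool)
    names = list(table.columns)
    n = len(names)
    out = np.zeros((n, n))
    sizes = mat.sum(axis=0)
    for i in range(n):
        for k in range(i, n):
            inter = int(np.count_nonzero(mat[:, i] & mat[:, k]))
            union = int(sizes[i] + sizes[k] - inter)
            if union == 0:
                warnings.warn(
                    f"databases {names[i]!r} and {names[k]!r} are both empty "
                    f"under subset {subset!r}; Jaccard reported as 0",
                    EmptyColumnWarning,
                    stacklevel=2,
                )
                val = 0.0
            else:
                val = inter / union
            out[i, k] = out[k, i] = val
    return JaccardMatrix(
        values=pd.DataFrame(out, index=names, columns=names), subset=subset
    )


@dataclass
class CardinalitySummary:
    """Degree distribution and per-combination counts of a membership table."""

    exact_degree: pd.Series  # index k -> patients in exactly k databases
    at_least_degree: pd.Series  # index k -> patients in >= k databases
    combinations: pd.DataFrame = field(repr=False)  # non-empty combos only
    n_patients: int = 0

    def patients_in_at_least(self, k: int) -> int:
        if k > self.at_least_degree.index.max():
            return 0
        return int(self.at_least_degree.loc[k])


def cardinality_summary(membership: pd.DataFrame) -> CardinalitySummary:
    """Exact/at-least degree counts and non-empty combination counts.

    Only combinations with at least one patient are tabulated; with 11
    databases the full 2^11 combination table is mostly empty.
    """
    if membership.shape[1] < 1:
        raise ValueError("need at least one database")
    mat = membership.to_numpy(dtype=bool)
    degrees = mat.sum(axis=1)
    max_deg = membership.shape[1]
    exact = pd.Series(
        np.bincount(degrees, minlength=max_deg + 1), index=range(max_deg + 1)
    )
    at_least = exact[::-1].cumsum()[::-1]
    names = list(membership.columns)
    combo_counts: dict[tuple[str, ...], int] = {}
    for row in mat:
        combo = tuple(n for n, present in zip(names, row) if present)
        if combo:
            combo_counts[combo] = combo_counts.get(combo, 0) + 1
    combos = pd.DataFrame(
        {
            "combination": ["|".join(c) for c in combo_counts],
            "degree": [len(c) for c in combo_counts],
            "count": list(combo_counts.values()),
        }
    ).sort_values("count", ascending=False, ignore_index=True)
    return CardinalitySummary(
        exact_degree=exact,
        at_least_degree=at_least,
        combinations=combos,
        n_patients=int(mat.shape[0]),
    )
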