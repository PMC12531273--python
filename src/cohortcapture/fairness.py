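"""Stratified discrimination audit of model scores across demographic groups.

Computes the AUROC within each level of each audited attribute (sex,
ethnicity, age band, deprivation band) and the maximum pairwise AUROC gap
per attribute.  Groups below a minimum size, or with a single label class,
are flagged as underpowered/undefined rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "FairnessReport",
    "stratified_auc",
    "age_bands",
    "imd_quintiles",
    "audit_attributes",
]


def age_bands(ages, width: int = 10) -> pd.Series:
    """Decadal (by default) age bands, labelled e.g. ``'50-59'``."""
    a = pd.Series(ages).astype(float)
    lo = (a // width * width).astype(int)
    return (lo.astype(str) + "-" + (lo + width - 1).astype(str)).rename("age_band")


def imd_quintiles(deciles) -> pd.Series:
    """Collapse deprivation deciles 1–10 into quintiles 1–5."""
    d = pd.Series(deciles).astype(int)
    if not d.between(1, 10).all():
        raise ValueError("IMD deciles must lie in 1..10")
    return ((d + 1) // 2).rename("imd_quintile")


@dataclass
class FairnessReport:
    """Per-group AUROCs and per-attribute maximum pairwise gaps."""

    table: pd.DataFrame  # attribute, group, n, auroc, underpowered, note
    gaps: dict[str, float]
    min_group_size: int

    def group_auc(self, attribute: str, group) -> float:
        sel = self.table[
            (self.table["attribute"] == attribute)
            & (self.table["group"].astype(str) == str(group))
        ]
        if sel.empty:
            raise KeyError((attribute, group))
        return float(sel["auroc"].iloc[0])


def stratified_auc(
    probabilities,
    labels,
    group_assignments: dict[str, pd.Series] | pd.DataFrame,
    min_group_size: int = 30,
) -> FairnessReport:
    """AUROC within each demographic group, per audited attribute.

    ``group_assignments`` maps attribute name → per-patient group labels
    aligned with ``probabilities``.  Groups smaller than
    ``min_group_size`` are reported but flagged underpowered; groups with
    one label class get ``auroc = NaN`` with a note.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if isinstance(group_assignments, pd.DataFrame):
        group_assignments = {c: group_assignments[c] for c in group_assignments.columns}
    rows = []
    gaps: dict[str, float] = {}
    for attribute, groups in group_assignments.items():
        g = np.asarray(groups)
        if len(g) != len(p):
            raise ValueError(
                f"group assignments for {attribute!r} do not cover all "
                f"{len(p)} evaluated patients"
            )
        defined: list[float] = []
        for level in pd.unique(g):
            mask = g == level
            n = int(mask.sum())
            note = ""
            if len(np.unique(y[mask])) < 2:
                auc = float("nan")
                note = "single label class; AUROC undefined"
            else:
                auc = float(roc_auc_score(y[mask], p[mask]))
                defined.append(auc)
            rows.append(
                {
                    "attribute": attribute,
                    "group": level,
                    "n": n,
                    "auroc": auc,
                    "underpowered": n < min_group_size,
                    "note": note,
                }
            )
        gaps[attribute] = (max(defined) - min(defined)) if len(defined) >= 2 else float("nan")
    return FairnessReport(
        table=pd.DataFrame(rows), gaps=gaps, min_group_size=min_group_size
    )


def audit_attributes(demographics: pd.DataFrame) -> dict[str, pd.Series]:
    """Default audit strata from a demographics table: sex, ethnicity,
    decadal age bands, and deprivation quintiles."""
    return {
        "sex": demographics["sex"],
        "ethnicity": demographics["ethnicity"],
        "age_band": age_bands(demographics["age"]).set_axis(demographics.index),
        "imd_band": imd_quintiles(demographics["imd_decile"]).set_axis(demographics.index),
    }
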