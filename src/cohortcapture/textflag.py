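"""Regex flagging of clinical free text for inflammatory bowel disease.

Two stages:

1. **Synonym normalization** — abbreviations and surface variants
   ("UC", "crohns", "ibdu", ...) are rewritten to one of five normalized
   disease terms.  A small bundled dictionary covers the common
   abbreviations; a user-supplied thesaurus file (tab- or comma-separated
   ``surface_form<sep>normalized_term``) can extend or replace it.

2. **Pattern matching** — five case-insensitive substring patterns flag a
   document as suggestive of disease: ``olitis``, ``rohn``, ``octitis``,
   ``flammatory bowel disease`` and ``ibd``.  The patterns are deliberately
   permissive prefix-wildcards — ``olitis`` matches *every* colitis,
   including ischemic or diverticular colitis — trading precision for
   maximal recall, which is the intended screening behaviour.

A patient is flagged for a given document source if any one of their
documents of that type is flagged; patients with no documents of that type
are scored 0 (missing-as-zero convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "NORMALIZED_TERMS",
    "PATTERNS",
    "DOC_TYPES",
    "SynonymMap",
    "FlagResult",
    "default_synonym_map",
    "load_synonym_map",
    "normalize_terms",
    "flag_document",
    "flag_patients",
]

NORMALIZED_TERMS = (
    "Ulcerative Colitis",
    "Crohn's Disease",
    "IBD",
    "Inflammatory Bowel Disease",
    "Proctitis",
)

# Five substring patterns; a leading wildcard is implicit (plain substring
# search on lowercased text).  No word boundaries: 'olitis' intentionally
# over-matches all colitides.
PATTERNS: dict[str, str] = {
    "olitis": "olitis",
    "rohn": "rohn",
    "octitis": "octitis",
    "flammatory bowel disease": "flammatory bowel disease",
    "ibd": "ibd",
}

DOC_TYPES = ("letter", "endoscopy", "histopathology")

_DEFAULT_SYNONYMS: dict[str, str] = {
    "ulcerative colitis": "Ulcerative Colitis",
    "uc": "Ulcerative Colitis",
    "u.c.": "Ulcerative Colitis",
    "crohn's disease": "Crohn's Disease",
    "crohns disease": "Crohn's Disease",
    "crohn's": "Crohn's Disease",
    "crohns": "Crohn's Disease",
    "crohn": "Crohn's Disease",
    "cd": "Crohn's Disease",
    "inflammatory bowel disease": "Inflammatory Bowel Disease",
    "ibd": "IBD",
    "ibd-u": "IBD",
    "ibdu": "IBD",
    "ibd unclassified": "IBD",
    "proctitis": "Proctitis",
}


@dataclass
class SynonymMap:
    """Case-insensitive surface-form → normalized-term lookup.

    Every normalized term must be one of the five in ``NORMALIZED_TERMS``.
    Replacement is longest-match-first and idempotent: the normalized
    terms themselves participate in the alternation mapping to themselves,
    so already-normalized text is left untouched.
    """

    mapping: dict[str, str]
    _regex: re.Pattern = field(init=False, repr=False)
    _lookup: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - set(NORMALIZED_TERMS)
        if bad:
            raise ValueError(
                f"normalized terms must be one of {NORMALIZED_TERMS}; got {sorted(bad)}"
            )
        # Fixed-point trick: include the normalized terms as identity
        # entries so longest-match-first leaves normalized text unchanged.
        lookup = {t.lower(): t for t in NORMALIZED_TERMS}
        lookup.update({k.lower(): v for k, v in self.mapping.items()})
        alternation = "|".join(
            re.escape(s) for s in sorted(lookup, key=len, reverse=True)
        )
        # Lookarounds rather than \b: surface forms like "u.c." end in a
        # non-word character, where \b would never match.
        self._regex = re.compile(
            rf"(?<!\w)(?:{alternation})(?!\w)", re.IGNORECASE
        )
        self._lookup = lookup

    def __contains__(self, surface: str) -> bool:
        return surface.lower() in self._lookup


def default_synonym_map() -> SynonymMap:
    """The bundled abbreviation dictionary (UC, CD, IBD-U, ...)."""
    return SynonymMap(dict(_DEFAULT_SYNONYMS))


def load_synonym_map(path: str | Path) -> SynonymMap:
    """Load a user thesaurus: one ``surface<TAB-or-comma>normalized`` per line."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        surface, _, normalized = line.partition(sep)
        mapping[surface.strip()] = normalized.strip()
    if not mapping:
        raise ValueError(f"thesaurus file {path} contains no entries")
    return SynonymMap(mapping)


def normalize_terms(text: str, synonym_map: SynonymMap | None = None) -> str:
    """Rewrite every mapped surface form to its normalized disease term.

    Unmapped text passes through unchanged; the operation is idempotent.
    """
    if not text:
        return text
    smap = synonym_map or default_synonym_map()
    return smap._regex.sub(lambda m: smap._lookup[m.group(0).lower()], text)


@dataclass(frozen=True)
class FlagResult:
    """Outcome of pattern-matching one document."""

    doc_id: str
    flagged: bool
    matched_patterns: tuple[str, ...]
    matched_spans: tuple[tuple[int, int], ...]  # 0-based half-open offsets

    def __post_init__(self) -> None:
        assert self.flagged == bool(self.matched_patterns)


def flag_document(
    text: str, doc_id: str = "", ibd_word_boundary: bool = False
) -> FlagResult:
    """Apply the five patterns to one document (lowercased before matching).

    ``ibd_word_boundary=True`` restricts the ``ibd`` pattern to whole-word
    occurrences (so e.g. "Gibbs" is not flagged); the default matches the
    bare substring as printed.
    """
    lowered = text.lower()
    matched: list[str] = []
    spans: list[tuple[int, int]] = []
    for name, pattern in PATTERNS.items():
        if name == "ibd" and ibd_word_boundary:
            hits = [m.span() for m in re.finditer(r"\bibd\b", lowered)]
        else:
            hits = [
                (m.start(), m.end())
                for m in re.finditer(re.escape(pattern), lowered)
            ]
        if hits:
            matched.append(name)
            spans.extend(hits)
    return FlagResult(
        doc_id=doc_id,
        flagged=bool(matched),
        matched_patterns=tuple(matched),
        matched_spans=tuple(sorted(spans)),
    )


def flag_patients(
    documents: pd.DataFrame,
    doc_type: str,
    patient_index: Iterable | None = None,
    ibd_word_boundary: bool = False,
) -> pd.Series:
    """Per-patient binary flags for one free-text document source.

    ``documents`` needs columns ``patient_id``, ``doc_type`` and ``text``.
    A patient is flagged iff at least one of their documents of the given
    type matches any pattern.  When ``patient_index`` is supplied the
    result covers exactly those patients, scoring 0 for anyone without a
    flagged document of that type (missing-as-zero convention).
    """
    if doc_type not in DOC_TYPES:
        raise ValueError(f"doc_type must be one of {DOC_TYPES}, got {doc_type!r}")
    required = {"patient_id", "doc_type", "text"}
    missing = required - set(documents.columns)
    if missing:
        raise ValueError(f"documents table is missing columns: {sorted(missing)}")
    subset = documents[documents["doc_type"] == doc_type]
    flags_by_patient: dict = {}
    for pid, text in zip(subset["patient_id"], subset["text"]):
        if flags_by_patient.get(pid):
            continue
        flags_by_patient[pid] = int(
            flag_document(text, ibd_word_boundary=ibd_word_boundary).flagged
        )
    if patient_index is None:
        index = pd.Index(sorted(flags_by_patient), name="patient_id")
    else:
        index = pd.Index(patient_index, name="patient_id")
    out = pd.Series(0, index=index, dtype=int, name=doc_type)
    present = [p for p in flags_by_patient if p in out.index]
    if present:
        out.loc[present] = np.array([flags_by_patient[p] for p in present], dtype=int)
    return out


def flag_report(
    documents: pd.DataFrame, ibd_word_boundary: bool = False
) -> pd.DataFrame:
    """Per-document match report: doc index, type, flagged, patterns."""
    rows = []
    for i, row in documents.iterrows():
        res = flag_document(
            str(row["text"]), doc_id=str(i), ibd_word_boundary=ibd_word_boundary
        )
        rows.append(
            {
                "doc_id": str(i),
                "patient_id": row["patient_id"],
                "doc_type": row["doc_type"],
                "flagged": int(res.flagged),
                "matched_patterns": ";".join(res.matched_patterns),
            }
        )
    return pd.DataFrame(rows)
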