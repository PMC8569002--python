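"""Complication classification, tabulation, rates, and the binary event series.

Complications after fracture reverse shoulder arthroplasty (fRSA) are graded
into two classes: *minor* events need neither considerable revision surgery
nor long-term medication, while *major* events require revision surgery or
long-term antibiotics, or compromise the surgical outcome.  Events judged
unrelated to the prosthesis placement (e.g. a post-operative fall onto the
shoulder) carry ``attributable = False`` and are excluded from every rate and
from the binary CUSUM.

Severity is decided by a small declarative keyword ruleset applied to the
structured treatment/outcome annotation — auditable by inspection, no
free-text inference.  Rates are counted over *patients*, not events: a
patient with two minor events counts once in the minor class.

The packaged reference register (``data/reference_complications.csv``)
transcribes the complication listing of a 50-patient fRSA learning-curve
cohort: six patients with a minor complication (three transient nerve
palsies, three cerclage-cable removals), three with a major one (subacromial
decompression, stem revision, open shoulder reduction), and two excluded
fall-related events.  The source listing gives no case numbers, so the
``case_index`` column holds arbitrary distinct placeholders; only the counts
are meaningful.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import pandas as pd

from .cohort import CaseRecord, CohortError, ComplicationEvent, load_complications

__all__ = [
    "SeverityRules",
    "DEFAULT_SEVERITY_RULES",
    "classify_severity",
    "ComplicationTable",
    "ComplicationRates",
    "complication_rate",
    "events_to_binary_series",
    "load_reference_complications",
]

REFERENCE_COHORT_SIZE = 50


@dataclass(frozen=True)
class SeverityRules:
    """Keyword patterns (regexes, case-insensitive) that mark an event major.

    An annotation matching any pattern is *major*; a non-empty annotation
    matching none is *minor*; an empty annotation cannot be classified and is
    surfaced for manual review — never silently minor.
    """

    major_patterns: tuple[str, ...] = (
        r"\brevision\b",
        r"\bacromioplasty\b",
        r"\bdecompression\b",
        r"\bopen\b.*\breduction\b",
        r"\binternal fixation\b",
        r"long.?(term|time)\s+antibiotic",
        r"\bcompromised\b",
    )
    _compiled: tuple[re.Pattern[str], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "_compiled",
            tuple(re.compile(p, re.IGNORECASE) for p in self.major_patterns),
        )

    def is_major(self, annotation: str) -> bool:
        return any(p.search(annotation) for p in self._compiled)


DEFAULT_SEVERITY_RULES = SeverityRules()


def classify_severity(
    event: ComplicationEvent, rules: SeverityRules = DEFAULT_SEVERITY_RULES
) -> str:
    """Classify an event as ``"minor"``, ``"major"`` or ``"unclassified"``.

    The decision is taken on the treatment/outcome annotation (falling back
    to the description when no separate annotation exists).  An event with no
    annotation at all returns ``"unclassified"`` for manual review.
    """
    annotation = " ".join(s for s in (event.treatment, event.description) if s).strip()
    if not annotation:
        return "unclassified"
    return "major" if rules.is_major(annotation) else "minor"


@dataclass(frozen=True)
class ComplicationTable:
    """All complication events of a cohort, with the cohort size as denominator."""

    rows: tuple[tuple[int, ComplicationEvent], ...]
    n_cohort: int

    def __post_init__(self) -> None:
        if self.n_cohort <= 0:
            raise CohortError("n_cohort must be positive")
        for case_ix, _ in self.rows:
            if not 1 <= case_ix <= self.n_cohort:
                raise CohortError(f"event references unknown case {case_ix}")

    @classmethod
    def from_cohort(cls, records: Sequence[CaseRecord]) -> "ComplicationTable":
        rows = tuple(
            (rec.case_index, ev) for rec in records for ev in rec.complications
        )
        return cls(rows=rows, n_cohort=len(records))

    def attributable(self) -> tuple[tuple[int, ComplicationEvent], ...]:
        return tuple((ix, ev) for ix, ev in self.rows if ev.attributable)


@dataclass(frozen=True)
class ComplicationRates:
    """Patient-level complication counts and percentages of the cohort size."""

    n_cohort: int
    minor_patients: int
    major_patients: int
    any_patients: int
    minor_pct: float
    major_pct: float
    any_pct: float
    n_events: int  # attributable events, all classes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"class": "minor", "patients": self.minor_patients, "pct": self.minor_pct},
                {"class": "major", "patients": self.major_patients, "pct": self.major_pct},
                {"class": "any", "patients": self.any_patients, "pct": self.any_pct},
            ],
            columns=["class", "patients", "pct"],
        )


def complication_rate(table: ComplicationTable) -> ComplicationRates:
    """Per-severity patient counts and percentages over the cohort.

    Each patient counts at most once per severity class; the overall rate
    counts patients with at least one attributable event of any class.
    Non-attributable events are ignored entirely.
    """
    minor_cases: set[int] = set()
    major_cases: set[int] = set()
    attributable = table.attributable()
    for case_ix, ev in attributable:
        (minor_cases if ev.severity == "minor" else major_cases).add(case_ix)
    any_cases = minor_cases | major_cases
    n = table.n_cohort
    return ComplicationRates(
        n_cohort=n,
        minor_patients=len(minor_cases),
        major_patients=len(major_cases),
        any_patients=len(any_cases),
        minor_pct=100.0 * len(minor_cases) / n,
        major_pct=100.0 * len(major_cases) / n,
        any_pct=100.0 * len(any_cases) / n,
        n_events=len(attributable),
    )


def events_to_binary_series(records: Sequence[CaseRecord]) -> list[bool]:
    """One boolean per case: did the case have ≥ 1 attributable complication?

    This is the input series of the binary complication CUSUM; length equals
    the cohort size and order follows ``case_index``.
    """
    return [
        any(ev.attributable for ev in rec.complications) for rec in records
    ]


def load_reference_complications() -> ComplicationTable:
    """Load the packaged 50-patient fRSA complication register."""
    path = resources.files("surglearn").joinpath("data/reference_complications.csv")
    with resources.as_file(path) as p:
        by_case = load_complications(p)
    rows = tuple((ix, ev) for ix, events in sorted(by_case.items()) for ev in events)
    return ComplicationTable(rows=rows, n_cohort=REFERENCE_COHORT_SIZE)
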