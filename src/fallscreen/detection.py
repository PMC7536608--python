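"""Stay-level fall detection over narrative clinical notes.

The unit of classification is the hospital stay. Nurses' and physicians'
narrative progress notes are the richest signal — a fall is not always charted
by both professions, so every note is scanned identically regardless of author
role. Evidence aggregates with an ANY rule: one unsuppressed fall-term match
anywhere in the stay that the present-on-admission filter does not explain
away makes the stay algorithm-positive. Stays whose only fall mentions are
classified as pre-admission get the distinct verdict
``present_on_admission_only`` so that the review workflow (and the evaluation
of false positives) can see them.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from enum import Enum
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .admission_filter import POARule, is_present_on_admission
from .lexicon import Category, Lexicon, TermMatch, find_matches, normalize_text

__all__ = [
    "ClinicalNote",
    "HospitalStay",
    "Verdict",
    "MatchEvidence",
    "StayClassification",
    "filter_eligible",
    "classify_note",
    "classify_stay",
    "run_corpus",
    "classifications_to_frame",
]

logger = logging.getLogger(__name__)

#: Notes timestamped slightly outside the stay (transcription lag) are
#: tolerated within this window; beyond it the record is rejected at load.
NOTE_TIMESTAMP_SLACK = timedelta(days=1)

AuthorRole = Literal["nurse", "physician", "other"]
NoteType = Literal["progress", "admission_anamnesis", "discharge_summary", "other"]


class ClinicalNote(BaseModel):
    """One timestamped free-text note belonging to a hospital stay."""

    note_id: str
    stay_id: str
    author_role: AuthorRole = "other"
    note_type: NoteType = "progress"
    timestamp: datetime
    text: str


class HospitalStay(BaseModel):
    """One admission: demographics, stay window, and its notes.

    ``primary_diagnosis`` is a free categorical label (e.g. ``cardiac``,
    ``neurological``); it is descriptive only and never enters the detection
    rules.
    """

    stay_id: str
    age: float = Field(ge=0)
    sex: Literal["female", "male"]
    admission: datetime
    discharge: datetime
    primary_diagnosis: str = "unknown"
    notes: list[ClinicalNote] = []

    @model_validator(mode="after")
    def _check(self) -> "HospitalStay":
        if not self.discharge > self.admission:
            raise ValueError(
                f"stay {self.stay_id!r}: discharge must be after admission"
            )
        lo = self.admission - NOTE_TIMESTAMP_SLACK
        hi = self.discharge + NOTE_TIMESTAMP_SLACK
        for note in self.notes:
            if note.stay_id != self.stay_id:
                raise ValueError(
                    f"note {note.note_id!r} references stay {note.stay_id!r}, "
                    f"not {self.stay_id!r}"
                )
            if not lo <= note.timestamp <= hi:
                raise ValueError(
                    f"note {note.note_id!r}: timestamp {note.timestamp} lies outside "
                    f"stay {self.stay_id!r} (±1 day tolerance)"
                )
        return self

    @property
    def length_of_stay(self) -> timedelta:
        return self.discharge - self.admission

    @property
    def length_of_stay_days(self) -> float:
        return self.length_of_stay.total_seconds() / 86400.0


class Verdict(str, Enum):
    """Stay-level outcome of the screen."""

    IN_HOSPITAL_FALL = "in_hospital_fall"
    PRESENT_ON_ADMISSION_ONLY = "present_on_admission_only"
    NO_FALL = "no_fall"


@dataclass(frozen=True)
class MatchEvidence:
    """One unsuppressed fall-term match with its POA assessment."""

    match: TermMatch
    poa: bool
    poa_reason: str | None = None


@dataclass
class StayClassification:
    """The screen's verdict for one stay, with auditable evidence.

    ``evidence`` holds every unsuppressed inclusion match with its POA
    assessment; ``all_matches`` additionally keeps suppressed matches and
    admission-context hits for error analysis. ``flagged_notes`` are the ids
    of notes contributing unsuppressed inclusion matches.
    """

    stay_id: str
    verdict: Verdict
    evidence: list[MatchEvidence] = field(default_factory=list)
    all_matches: list[TermMatch] = field(default_factory=list)
    flagged_notes: list[str] = field(default_factory=list)

    @property
    def positive(self) -> bool:
        """Algorithm-positive for evaluation purposes (in-hospital fall)."""
        return self.verdict is Verdict.IN_HOSPITAL_FALL


def filter_eligible(
    stays: list[HospitalStay],
    *,
    min_age: float = 18.0,
    min_los: timedelta = timedelta(hours=24),
) -> tuple[list[HospitalStay], list[tuple[HospitalStay, str]]]:
    """Apply the study eligibility rules: adults with a stay of ≥ 24 hours.

    Returns ``(eligible, excluded)`` where each excluded entry carries the
    first reason that applied (``age`` before ``length_of_stay``).
    """
    eligible: list[HospitalStay] = []
    excluded: list[tuple[HospitalStay, str]] = []
    for stay in stays:
        if stay.age < min_age:
            excluded.append((stay, f"age {stay.age:g} < {min_age:g} years"))
        elif stay.length_of_stay < min_los:
            excluded.append(
                (stay, f"length of stay {stay.length_of_stay_days:.2f} days < "
                       f"{min_los.total_seconds() / 86400.0:g} days"))
        else:
            eligible.append(stay)
    return eligible, excluded


def classify_note(note: ClinicalNote, lexicon: Lexicon) -> list[TermMatch]:
    """Scan one note's text; matches carry the note id.

    Nurse and physician notes are processed identically — the author role
    never influences matching.
    """
    return find_matches(note.text, lexicon, note_id=note.note_id)


def classify_stay(
    stay: HospitalStay,
    lexicon: Lexicon,
    poa_rule: POARule | None = None,
) -> StayClassification:
    """Aggregate note-level matches into the stay verdict.

    Collects unsuppressed inclusion matches across all notes, assesses each
    with the present-on-admission filter, and applies the ANY rule:

    * no unsuppressed inclusion match anywhere → ``no_fall``;
    * matches exist but every one is pre-admission → ``present_on_admission_only``;
    * at least one non-POA match → ``in_hospital_fall``.

    A stay without notes cannot be assessed; it classifies ``no_fall`` and a
    ``UserWarning`` is emitted.
    """
    poa_rule = poa_rule or POARule()
    if not stay.notes:
        _warnings.warn(
            f"stay {stay.stay_id!r} has no notes; classified no_fall by default",
            UserWarning, stacklevel=2,
        )
        return StayClassification(stay_id=stay.stay_id, verdict=Verdict.NO_FALL)

    evidence: list[MatchEvidence] = []
    all_matches: list[TermMatch] = []
    flagged: list[str] = []
    for note in stay.notes:
        normalized = normalize_text(note.text)
        matches = find_matches(normalized, lexicon, note_id=note.note_id)
        all_matches.extend(matches)
        context = [m for m in matches if m.category is Category.ADMISSION_CONTEXT]
        unsuppressed = [m for m in matches
                        if m.category is Category.INCLUSION and not m.suppressed]
        if unsuppressed and note.note_id not in flagged:
            flagged.append(note.note_id)
        for match in unsuppressed:
            poa, reason = is_present_on_admission(
                match, note, stay, lexicon, poa_rule,
                context_matches=context, normalized=normalized,
            )
            evidence.append(MatchEvidence(match=match, poa=poa, poa_reason=reason))

    if not evidence:
        verdict = Verdict.NO_FALL
    elif all(ev.poa for ev in evidence):
        verdict = Verdict.PRESENT_ON_ADMISSION_ONLY
    else:
        verdict = Verdict.IN_HOSPITAL_FALL
    return StayClassification(
        stay_id=stay.stay_id, verdict=verdict, evidence=evidence,
        all_matches=all_matches, flagged_notes=flagged,
    )


def run_corpus(
    stays: list[HospitalStay],
    lexicon: Lexicon,
    poa_rule: POARule | None = None,
) -> list[StayClassification]:
    """Classify every stay in a corpus; deterministic, one verdict per stay.

    Raises
    ------
    ValueError
        If two stays share a ``stay_id``.
    """
    seen: set[str] = set()
    for stay in stays:
        if stay.stay_id in seen:
            raise ValueError(f"duplicate stay_id {stay.stay_id!r} in corpus")
        seen.add(stay.stay_id)

    results = [classify_stay(stay, lexicon, poa_rule) for stay in stays]
    counts = {v: 0 for v in Verdict}
    for r in results:
        counts[r.verdict] += 1
    logger.info(
        "classified %d stays: %d flagged in-hospital, %d present-on-admission only, %d negative",
        len(results), counts[Verdict.IN_HOSPITAL_FALL],
        counts[Verdict.PRESENT_ON_ADMISSION_ONLY], counts[Verdict.NO_FALL],
    )
    return results


def classifications_to_frame(results: list[StayClassification]) -> pd.DataFrame:
    """Tabulate verdicts for CSV export: one row per stay with an evidence summary."""
    rows = []
    for r in results:
        summary = "; ".join(
            f"{ev.match.term}@{ev.match.note_id}"
            + (f" [POA:{ev.poa_reason}]" if ev.poa else "")
            for ev in r.evidence
        )
        rows.append({
            "stay_id": r.stay_id,
            "verdict": r.verdict.value,
            "n_matches": len(r.all_matches),
            "n_unsuppressed": len(r.evidence),
            "n_poa": sum(ev.poa for ev in r.evidence),
            "flagged_notes": ";".join(r.flagged_notes),
            "evidence": summary,
        })
    return pd.DataFrame(
        rows, columns=["stay_id", "verdict", "n_matches", "n_unsuppressed",
                       "n_poa", "flagged_notes", "evidence"])
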