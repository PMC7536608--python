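"""Present-on-admission (POA) classification of detected fall mentions.

A keyword screen over a whole hospital record flags any documented fall — but
many documented falls happened *before* admission (at home, prompting an
emergency admission) and must not count as in-hospital events. This module
decides, for a single unsuppressed fall-term match, whether the mention
describes a pre-admission event, using three signals:

(a) an admission-context term (``Notfall``, ``Ambulanz``, ``zu Hause``,
    ``eingeliefert``) co-occurs with the match within the configured window
    (whole note by default, optionally same sentence);
(b) the note is of a type that records pre-admission history (admission
    anamnesis by default); or
(c) the note was written within a short period after admission (24 h by
    default) *and* contains an admission-context term.

The filter deliberately errs toward under-suppression: a flagged stay costs a
few minutes of manual review, whereas a wrongly suppressed in-hospital fall is
silently lost. Tightening is a lexicon/config exercise, not a code change.
"""

from __future__ import annotations

from datetime import timedelta
from typing import TYPE_CHECKING, Literal, Sequence

from pydantic import BaseModel, Field

from .lexicon import Category, Lexicon, NormalizedText, TermMatch, find_matches, normalize_text

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .detection import ClinicalNote, HospitalStay

__all__ = ["POARule", "load_poa_rule", "is_present_on_admission"]

#: Tolerance for notes timestamped slightly before admission (transcription lag).
_PRE_ADMISSION_SLACK = timedelta(days=1)


class POARule(BaseModel):
    """Configuration of the present-on-admission decision.

    Parameters
    ----------
    context_window
        Scope within which an admission-context term must co-occur with a
        fall-term match for clause (a): the whole note (``same-note``,
        default — the weakest assumption) or the same sentence.
    admission_period_hours
        Duration after admission during which context co-occurrence in *any*
        note triggers clause (c). Default 24 h.
    admission_note_types
        Note types treated as pre-admission history for clause (b).
    """

    context_window: Literal["same-note", "same-sentence"] = "same-note"
    admission_period_hours: float = Field(default=24.0, ge=0)
    admission_note_types: list[str] = ["admission_anamnesis"]

    @property
    def admission_period(self) -> timedelta:
        return timedelta(hours=self.admission_period_hours)


def load_poa_rule(config_source: dict | None = None) -> POARule:
    """Build a POARule from the ``poa_rule`` key of a config mapping (or defaults)."""
    if config_source is None:
        return POARule()
    return POARule(**config_source.get("poa_rule", {}))


def _sentence_index(text: str) -> list[int]:
    """Sentence id for every character position, splitting on ``. ! ?``."""
    idx, current = [], 0
    for ch in text:
        idx.append(current)
        if ch in ".!?":
            current += 1
    return idx


def _same_sentence(text: str, a: TermMatch, b: TermMatch) -> bool:
    idx = _sentence_index(text)
    return idx[a.span[0]] == idx[b.span[0]]


def is_present_on_admission(
    match: TermMatch,
    note: "ClinicalNote",
    stay: "HospitalStay",
    lexicon: Lexicon,
    rule: POARule | None = None,
    *,
    context_matches: Sequence[TermMatch] | None = None,
    normalized: NormalizedText | None = None,
) -> tuple[bool, str | None]:
    """Decide whether a fall-term match describes a pre-admission event.

    Returns ``(poa, reason)`` where *reason* names the first clause that
    fired (``context_cooccurrence``, ``admission_note_type`` or
    ``early_note_with_context``) or is ``None`` when the mention counts as
    in-hospital. ``context_matches``/``normalized`` let a caller that has
    already scanned the note avoid re-matching; they must then come from the
    same note text.

    Raises
    ------
    ValueError
        If the note does not belong to the given stay.
    """
    if note.stay_id != stay.stay_id:
        raise ValueError(
            f"note {note.note_id!r} belongs to stay {note.stay_id!r}, not {stay.stay_id!r}"
        )
    rule = rule or POARule()
    if normalized is None:
        normalized = normalize_text(note.text)
    if context_matches is None:
        context_matches = [
            m for m in find_matches(normalized, lexicon)
            if m.category is Category.ADMISSION_CONTEXT
        ]
    else:
        context_matches = [m for m in context_matches
                           if m.category is Category.ADMISSION_CONTEXT]

    has_context = bool(context_matches)
    if has_context:
        if rule.context_window == "same-note":
            in_window = True
        else:
            in_window = any(_same_sentence(normalized.text, match, c)
                            for c in context_matches)
        if in_window:
            return True, "context_cooccurrence"

    if note.note_type in rule.admission_note_types:
        return True, "admission_note_type"

    if has_context:
        delta = note.timestamp - stay.admission
        if -_PRE_ADMISSION_SLACK <= delta <= rule.admission_period:
            return True, "early_note_with_context"

    return False, None
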