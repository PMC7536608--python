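"""Term lexicon and text-matching semantics for fall screening.

The screening method is deliberately simple and auditable: a configurable list
of fall-indicating surface strings (*inclusion terms*, e.g. ``am Boden``,
``Sturz``, ``synkopiert``) is matched case-insensitively as plain substrings of
narrative note text. Substring — not word-boundary — matching is essential in
German, where compounding buries terms inside longer words (``Sturzereignis``,
``Bodenbett``). The price of substring matching is decoy compounds: a
``Bodenbett`` (floor-level bed, a fall-*prevention* device) contains ``Boden``
without describing a fall. Such decoys are listed as *exclusion compounds*;
any inclusion match lying wholly inside an occurrence of one is reported with
``suppressed=True`` rather than dropped, so downstream review can audit what
was suppressed and why.

A third list, *admission-context terms* (``Notfall``, ``Ambulanz``,
``zu Hause``, ``eingeliefert``), marks wording typical of pre-admission events
(emergency transport, falls at home). These matches are never suppressed; they
feed the present-on-admission filter in :mod:`fallscreen.admission_filter`.

Inflection is handled by explicit variant lists (``Sturz``/``Stürze``,
``Synkope``/``synkopiert``) rather than stemming, so the behaviour of a given
lexicon is fully enumerable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

__all__ = [
    "Category",
    "TermMatch",
    "NormalizedText",
    "Lexicon",
    "LexiconError",
    "DEFAULT_CONFIG",
    "load_lexicon",
    "normalize_text",
    "find_matches",
]


class LexiconError(ValueError):
    """Raised when a lexicon configuration is malformed."""


class Category(str, Enum):
    """What kind of lexicon term produced a match."""

    INCLUSION = "inclusion"
    ADMISSION_CONTEXT = "admission_context"


#: Seed configuration built from the term variants a screening lexicon needs
#: at minimum: the common German fall descriptions, the floor-bed decoy
#: compound, and emergency/at-home context wording. Real deployments extend
#: these lists via a YAML/JSON config file.
DEFAULT_CONFIG: dict = {
    "version": "default-seed-v1",
    "inclusion_terms": [
        "am Boden",
        "Boden",
        "ausgerutscht",
        "Sturz",
        "Stürze",
        "gestürzt",
        "Synkope",
        "synkopiert",
    ],
    "exclusion_compounds": [
        "Bodenbett",
    ],
    "admission_context_terms": [
        "Notfall",
        "Ambulanz",
        "zu Hause",
        "eingeliefert",
    ],
}


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedText:
    """Case-folded, whitespace-collapsed text plus a map back to the raw text.

    ``offsets[i]`` is the index in ``raw`` of the character that produced
    normalized character ``i`` (a collapsed whitespace run maps to its first
    raw character; a multi-character fold such as ``ß → ss`` maps both output
    characters to the ``ß``).
    """

    raw: str
    text: str
    offsets: tuple[int, ...]

    def project(self, span: tuple[int, int]) -> tuple[int, int]:
        """Project a normalized half-open span back onto the raw text."""
        start, end = span
        if not (0 <= start < end <= len(self.text)):
            raise ValueError(f"span {span!r} out of bounds for normalized text")
        return self.offsets[start], self.offsets[end - 1] + 1


def normalize_text(raw: str) -> NormalizedText:
    """Normalize free text for matching: casefold + collapse whitespace.

    Case folding is locale-independent (``str.casefold``): umlauts keep their
    diacritics (``Stürze → stürze``) and ``ß`` folds to ``ss``. Runs of
    whitespace (including newlines) collapse to a single space; leading and
    trailing whitespace is dropped. Total on all strings; idempotent.
    """
    out: list[str] = []
    offsets: list[int] = []
    ws_start: int | None = None
    for i, ch in enumerate(raw):
        if ch.isspace():
            if ws_start is None:
                ws_start = i
            continue
        if ws_start is not None and out:
            out.append(" ")
            offsets.append(ws_start)
        ws_start = None
        for folded in ch.casefold():
            out.append(folded)
            offsets.append(i)
    return NormalizedText(raw=raw, text="".join(out), offsets=tuple(offsets))


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

def _normalize_terms(terms: list[str], field_name: str) -> list[str]:
    seen: dict[str, None] = {}
    for t in terms:
        if not isinstance(t, str):
            raise LexiconError(f"{field_name}: term {t!r} is not a string")
        norm = normalize_text(t).text
        if not norm:
            raise LexiconError(f"{field_name}: empty term is not allowed")
        seen.setdefault(norm)
    return list(seen)


class Lexicon(BaseModel):
    """Validated, normalized term lexicon.

    All terms are stored in normalized form (casefolded, single-spaced) and
    deduplicated preserving order. ``validation_warnings`` lists exclusion
    compounds that contain no inclusion term as a substring — such a compound
    can never suppress anything and is almost certainly a configuration
    mistake.
    """

    model_config = ConfigDict()

    inclusion_terms: list[str]
    exclusion_compounds: list[str] = []
    admission_context_terms: list[str] = []
    version: str = "unversioned"
    validation_warnings: list[str] = []

    @field_validator("inclusion_terms")
    @classmethod
    def _inclusion(cls, v: list[str]) -> list[str]:
        terms = _normalize_terms(v, "inclusion_terms")
        if not terms:
            raise LexiconError("inclusion_terms: must contain at least one term")
        return terms

    @field_validator("exclusion_compounds")
    @classmethod
    def _exclusion(cls, v: list[str]) -> list[str]:
        return _normalize_terms(v, "exclusion_compounds")

    @field_validator("admission_context_terms")
    @classmethod
    def _context(cls, v: list[str]) -> list[str]:
        return _normalize_terms(v, "admission_context_terms")

    @model_validator(mode="after")
    def _flag_inert_compounds(self) -> "Lexicon":
        self.validation_warnings = [
            f"exclusion compound {comp!r} contains no inclusion term and can never suppress"
            for comp in self.exclusion_compounds
            if not any(term in comp for term in self.inclusion_terms)
        ]
        return self


def load_lexicon(config_source: dict | str | Path | None = None) -> Lexicon:
    """Load and validate a lexicon from a config mapping, file path, or the defaults.

    Parameters
    ----------
    config_source
        ``None`` loads :data:`DEFAULT_CONFIG`. A mapping is used directly.
        A path is read as YAML (JSON is a YAML subset, so both work).

    Raises
    ------
    LexiconError
        If the config does not parse, a required key is missing, or a term
        list fails validation. The message names the offending field.
    """
    if config_source is None:
        data = copy.deepcopy(DEFAULT_CONFIG)
    elif isinstance(config_source, dict):
        data = dict(config_source)
    else:
        path = Path(config_source)
        if not path.exists():
            raise LexiconError(f"lexicon config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise LexiconError(f"lexicon config {path} does not parse: {exc}") from exc
        if not isinstance(data, dict):
            raise LexiconError(f"lexicon config {path}: top level must be a mapping")
    for key in ("inclusion_terms", "exclusion_compounds", "admission_context_terms"):
        if key not in data:
            raise LexiconError(f"lexicon config: missing required field {key!r}")
    fields = {k: data[k] for k in
              ("inclusion_terms", "exclusion_compounds", "admission_context_terms")}
    if "version" in data:
        fields["version"] = data["version"]
    try:
        return Lexicon(**fields)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise LexiconError(f"lexicon config: field {loc}: {first['msg']}") from exc


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermMatch:
    """One located occurrence of a lexicon term in a note's normalized text.

    ``span`` is 0-based half-open on the *normalized* text; use
    :meth:`NormalizedText.project` to display it against the raw note.
    ``suppressed`` is True iff the match lies wholly inside an occurrence of
    the exclusion compound named in ``suppression_reason``.
    """

    term: str
    span: tuple[int, int]
    category: Category
    suppressed: bool = False
    suppression_reason: str | None = None
    note_id: str | None = None

    def __post_init__(self) -> None:
        start, end = self.span
        if not start < end:
            raise ValueError(f"invalid span {self.span!r}: start must precede end")
        if self.suppressed != (self.suppression_reason is not None):
            raise ValueError("suppressed must be set iff suppression_reason is set")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    """Yield every (possibly overlapping) start index of needle in haystack."""
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)


def find_matches(text: str | NormalizedText, lexicon: Lexicon,
                 note_id: str | None = None) -> list[TermMatch]:
    """Locate every lexicon-term occurrence in a text.

    Every occurrence of every inclusion and admission-context term is reported
    as a case-insensitive substring match on the normalized text, overlapping
    and nested occurrences included. An inclusion match whose span lies
    entirely inside an occurrence of an exclusion compound is returned with
    ``suppressed=True`` and that compound as the reason (the earliest covering
    occurrence wins if several apply). Matches are sorted by span start, ties
    broken by longer term first. Deterministic; empty text yields ``[]``.
    """
    norm = text if isinstance(text, NormalizedText) else normalize_text(text)
    t = norm.text
    if not t:
        return []

    excl_spans: list[tuple[int, int, str]] = []
    for comp in lexicon.exclusion_compounds:
        for s in _find_all(t, comp):
            excl_spans.append((s, s + len(comp), comp))
    excl_spans.sort()

    matches: list[TermMatch] = []
    for term in lexicon.inclusion_terms:
        for s in _find_all(t, term):
            span = (s, s + len(term))
            reason = next(
                (comp for cs, ce, comp in excl_spans if cs <= span[0] and span[1] <= ce),
                None,
            )
            matches.append(TermMatch(
                term=term, span=span, category=Category.INCLUSION,
                suppressed=reason is not None, suppression_reason=reason,
                note_id=note_id,
            ))
    for term in lexicon.admission_context_terms:
        for s in _find_all(t, term):
            matches.append(TermMatch(
                term=term, span=(s, s + len(term)),
                category=Category.ADMISSION_CONTEXT, note_id=note_id,
            ))

    matches.sort(key=lambda m: (m.span[0], -m.length, m.category.value))
    return matches
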