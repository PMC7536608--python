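"""Diagnostic-accuracy evaluation of fall-detection methods.

Detection methods (the keyword screen, trigger-tool chart review, voluntary
incident reports, patient self-report surveys) are compared per stay against a
*pseudo gold standard*: since no single method is a true gold standard, the
reference is the logical OR of all available methods, with explicit per-stay
adjudication overrides standing in for the human discussion of discordant
cases. From the resulting 2×2 tables the standard metrics are derived —
sensitivity, specificity, positive and negative predictive value — reported as
exact fractions and as integer percents (half-up rounding).

Also provided: Cohen's κ for inter-rater agreement, fall rates per 1000
patient-days, a review-effort model quantifying how much manual chart-review
time a high-sensitivity screen saves, and a discordance report that drives
iterative lexicon refinement (inspecting false positives for misleading terms
and false negatives for term-list gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .detection import HospitalStay, StayClassification, Verdict
from .lexicon import normalize_text

__all__ = [
    "MethodLabels",
    "ConfusionMatrix",
    "AccuracyReport",
    "FallRate",
    "ReviewEffort",
    "DiscordanceEntry",
    "DiscordanceReport",
    "pseudo_gold",
    "confusion",
    "accuracy_metrics",
    "cohen_kappa",
    "fall_rate",
    "review_effort",
    "error_analysis",
]


def percent_half_up(value: Fraction | float) -> int:
    """Integer percent with half-up rounding (0.915 → 92, 0.995 → 100)."""
    with localcontext() as ctx:
        ctx.prec = 50
        if isinstance(value, Fraction):
            d = Decimal(value.numerator) * 100 / Decimal(value.denominator)
        else:
            d = Decimal(repr(value)) * 100
        return int(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MethodLabels:
    """Per-stay binary fall labels from one detection method."""

    method: str
    labels: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {s: v for s, v in self.labels.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"method {self.method!r}: non-binary labels {bad}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts of a method against the reference standard."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AccuracyReport:
    """Sensitivity/specificity/PPV/NPV as exact fractions.

    A metric with a zero denominator is ``None`` (not available) — never 0.
    ``percents`` gives the half-up integer-percent display used in clinical
    reporting; ``intervals`` optionally holds Wilson 95% score intervals.
    """

    sensitivity: Fraction | None
    specificity: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    _METRICS = ("sensitivity", "specificity", "ppv", "npv")

    @property
    def percents(self) -> dict[str, int | None]:
        return {
            name: (None if frac is None else percent_half_up(frac))
            for name in self._METRICS
            for frac in [getattr(self, name)]
        }


def pseudo_gold(
    method_labels: Sequence[MethodLabels],
    overrides: Mapping[str, int] | None = None,
) -> tuple[dict[str, int], list[str]]:
    """Compose the pseudo gold standard: OR across methods, then adjudication.

    Returns ``(gold, discordant)`` where *discordant* lists the stays on which
    the supplied methods disagreed (the cases a human panel would discuss).
    Overrides model the outcome of that discussion and replace the OR verdict
    for the stays they name.

    Raises
    ------
    ValueError
        Fewer than two methods, methods covering different stay sets, or an
        override referencing an unknown stay.
    """
    if len(method_labels) < 2:
        raise ValueError("pseudo gold standard needs at least two methods")
    stay_sets = [set(m.labels) for m in method_labels]
    if any(s != stay_sets[0] for s in stay_sets[1:]):
        raise ValueError("all methods must label the same stay set")
    stays = stay_sets[0]

    gold = {s: int(any(m.labels[s] for m in method_labels)) for s in stays}
    discordant = sorted(
        s for s in stays if len({m.labels[s] for m in method_labels}) > 1
    )
    if overrides:
        unknown = set(overrides) - stays
        if unknown:
            raise ValueError(f"overrides reference unknown stays: {sorted(unknown)}")
        for s, v in overrides.items():
            if v not in (0, 1):
                raise ValueError(f"override for stay {s!r} must be 0 or 1, got {v!r}")
            gold[s] = v
    return gold, discordant


def confusion(
    pred: Mapping[str, int] | Sequence[int],
    gold: Mapping[str, int] | Sequence[int],
) -> ConfusionMatrix:
    """Standard 2×2 counts of predicted vs reference labels.

    Accepts two aligned mappings (stay_id → 0/1) or two equal-length
    sequences.
    """
    if isinstance(pred, Mapping) != isinstance(gold, Mapping):
        raise ValueError("pred and gold must both be mappings or both sequences")
    if isinstance(pred, Mapping):
        if set(pred) != set(gold):
            raise ValueError("pred and gold must cover the same stay set")
        pairs = [(pred[s], gold[s]) for s in pred]
    else:
        if len(pred) != len(gold):
            raise ValueError("pred and gold must have equal length")
        pairs = list(zip(pred, gold))
    tp = sum(1 for p, g in pairs if p and g)
    fp = sum(1 for p, g in pairs if p and not g)
    tn = sum(1 for p, g in pairs if not p and not g)
    fn = sum(1 for p, g in pairs if not p and g)
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_fraction(num: int, den: int) -> Fraction | None:
    return None if den == 0 else Fraction(num, den)


def accuracy_metrics(cm: ConfusionMatrix, *, ci: bool = False) -> AccuracyReport:
    """Derive sensitivity, specificity, PPV and NPV from a 2×2 table.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn); a zero denominator yields ``None``. With ``ci=True``,
    Wilson 95% score intervals are attached (off by default so the integer
    percents match plain fraction arithmetic exactly).
    """
    report = AccuracyReport(
        sensitivity=_safe_fraction(cm.tp, cm.tp + cm.fn),
        specificity=_safe_fraction(cm.tn, cm.tn + cm.fp),
        ppv=_safe_fraction(cm.tp, cm.tp + cm.fp),
        npv=_safe_fraction(cm.tn, cm.tn + cm.fn),
    )
    if ci:
        from statsmodels.stats.proportion import proportion_confint

        counts = {
            "sensitivity": (cm.tp, cm.tp + cm.fn),
            "specificity": (cm.tn, cm.tn + cm.fp),
            "ppv": (cm.tp, cm.tp + cm.fp),
            "npv": (cm.tn, cm.tn + cm.fn),
        }
        for name, (k, n) in counts.items():
            if n > 0:
                lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
                report.intervals[name] = (float(lo), float(hi))
    return report


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's κ for two raters: κ = (p_o − p_e) / (1 − p_e).

    ``p_o`` is the observed agreement fraction and ``p_e`` the agreement
    expected from the raters' marginal label frequencies. Works for any
    hashable label values; symmetric in its arguments and invariant under
    label renaming. When both raters use a single identical label everywhere
    (p_e = 1, perfect agreement), κ is 1 by convention.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    n = len(labels_a)
    if n < 2:
        raise ValueError("kappa needs at least two rated units")
    p_o = Fraction(sum(1 for a, b in zip(labels_a, labels_b) if a == b), n)
    cats = set(labels_a) | set(labels_b)
    p_e = sum(
        Fraction(sum(1 for a in labels_a if a == c), n)
        * Fraction(sum(1 for b in labels_b if b == c), n)
        for c in cats
    )
    if p_e == 1:
        return 1.0 if p_o == 1 else 0.0
    return float((p_o - p_e) / (1 - p_e))


@dataclass(frozen=True)
class FallRate:
    """Falls per 1000 patient-days."""

    n_falls: int
    patient_days: float

    @property
    def rate(self) -> float:
        return 1000.0 * self.n_falls / self.patient_days

    @property
    def rate_2dp(self) -> float:
        return round(self.rate, 2)


def fall_rate(n_falls: int, patient_days: float) -> FallRate:
    """Fall rate per 1000 patient-days; e.g. 15 falls over 3606 days → 4.16."""
    if patient_days <= 0:
        raise ValueError("patient_days must be positive")
    if n_falls < 0:
        raise ValueError("n_falls must be non-negative")
    return FallRate(n_falls=n_falls, patient_days=patient_days)


@dataclass(frozen=True)
class ReviewEffort:
    """Manual review time with and without the screen pre-filtering records."""

    full_minutes: float
    flagged_minutes: float

    @property
    def reduction(self) -> float:
        """Fractional time saved by reviewing only flagged records."""
        if self.full_minutes == 0:
            return 0.0
        return 1.0 - self.flagged_minutes / self.full_minutes

    @property
    def reduction_percent(self) -> int:
        return percent_half_up(self.reduction)


def review_effort(
    n_records: int, minutes_per_record: float, n_flagged: int
) -> ReviewEffort:
    """Chart-review effort: full review of all records vs review of flagged only.

    The percent reduction equals 1 − n_flagged/n_records, independent of the
    minutes spent per record.
    """
    if n_records < 0 or n_flagged < 0 or minutes_per_record < 0:
        raise ValueError("counts and minutes must be non-negative")
    if n_flagged > n_records:
        raise ValueError("n_flagged cannot exceed n_records")
    return ReviewEffort(
        full_minutes=n_records * minutes_per_record,
        flagged_minutes=n_flagged * minutes_per_record,
    )


# ---------------------------------------------------------------------------
# Error analysis
# ---------------------------------------------------------------------------

_SNIPPET_CONTEXT = 60  # chars of raw-text context either side of a match


@dataclass(frozen=True)
class Snippet:
    """One matched term shown in its raw-note context."""

    note_id: str
    term: str
    category: str
    suppressed: bool
    suppression_reason: str | None
    poa: bool
    text: str


@dataclass(frozen=True)
class DiscordanceEntry:
    """One stay on which the screen and the reference disagree."""

    stay_id: str
    kind: str  # "false_positive" | "false_negative"
    verdict: str
    snippets: tuple[Snippet, ...]
    tag: str


@dataclass(frozen=True)
class DiscordanceReport:
    entries: tuple[DiscordanceEntry, ...]

    @property
    def empty(self) -> bool:
        return not self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "stay_id": e.stay_id, "kind": e.kind, "verdict": e.verdict,
            "tag": e.tag, "n_snippets": len(e.snippets),
            "snippets": " | ".join(f"[{s.note_id}] …{s.text}…" for s in e.snippets),
        } for e in self.entries]
        return pd.DataFrame(
            rows, columns=["stay_id", "kind", "verdict", "tag", "n_snippets",
                           "snippets"])

    def to_text(self) -> str:
        if self.empty:
            return "No discordant stays.\n"
        lines = []
        for e in self.entries:
            lines.append(f"{e.kind.upper()} stay {e.stay_id} "
                         f"(verdict {e.verdict}) — {e.tag}")
            for s in e.snippets:
                state = "suppressed by " + s.suppression_reason if s.suppressed \
                    else ("POA" if s.poa else "active")
                lines.append(f"    [{s.note_id}] {s.term} ({s.category}, {state}): "
                             f"…{s.text}…")
        return "\n".join(lines) + "\n"


def _stay_snippets(cls: StayClassification, stay: HospitalStay) -> tuple[Snippet, ...]:
    notes = {n.note_id: n for n in stay.notes}
    poa_spans = {(ev.match.note_id, ev.match.span): ev.poa for ev in cls.evidence}
    snippets = []
    for m in cls.all_matches:
        note = notes.get(m.note_id)
        if note is None:
            continue
        norm = normalize_text(note.text)
        raw_start, raw_end = norm.project(m.span)
        lo = max(0, raw_start - _SNIPPET_CONTEXT)
        hi = min(len(note.text), raw_end + _SNIPPET_CONTEXT)
        snippets.append(Snippet(
            note_id=m.note_id, term=m.term, category=m.category.value,
            suppressed=m.suppressed, suppression_reason=m.suppression_reason,
            poa=poa_spans.get((m.note_id, m.span), False),
            text=note.text[lo:hi],
        ))
    return tuple(snippets)


def _fp_tag(cls: StayClassification, stay: HospitalStay) -> str:
    admission_notes = {n.note_id for n in stay.notes
                       if n.note_type == "admission_anamnesis"}
    if any(ev.poa for ev in cls.evidence) or any(
            ev.match.note_id in admission_notes for ev in cls.evidence):
        return "candidate-POA: fall mention tied to admission context"
    return "no obvious cause: inspect snippets for misleading terms"


def _fn_tag(cls: StayClassification) -> str:
    if not cls.all_matches:
        return "no lexicon term present: term-list gap"
    if not cls.evidence:
        return "all matches suppressed: exclusion compound too broad"
    return "matches classified present-on-admission: POA rule too aggressive"


def error_analysis(
    classifications: Sequence[StayClassification],
    gold: Mapping[str, int],
    stays: Sequence[HospitalStay],
) -> DiscordanceReport:
    """List every false-positive and false-negative stay with its evidence.

    Each discordant stay is shown with its matched snippets (±60 characters of
    raw-note context) and suppression/POA states, plus a diagnostic tag
    suggesting the likely cause — the feedback loop that drives lexicon
    refinement.
    """
    cls_by_stay = {c.stay_id: c for c in classifications}
    stay_by_id = {s.stay_id: s for s in stays}
    if set(cls_by_stay) != set(gold) or not set(gold) <= set(stay_by_id):
        raise ValueError("classifications, gold labels and stays must align")

    entries: list[DiscordanceEntry] = []
    for stay_id in sorted(gold):
        cls = cls_by_stay[stay_id]
        stay = stay_by_id[stay_id]
        pred = int(cls.positive)
        if pred == gold[stay_id]:
            continue
        kind = "false_positive" if pred else "false_negative"
        tag = _fp_tag(cls, stay) if pred else _fn_tag(cls)
        entries.append(DiscordanceEntry(
            stay_id=stay_id, kind=kind, verdict=cls.verdict.value,
            snippets=_stay_snippets(cls, stay), tag=tag,
        ))
    return DiscordanceReport(entries=tuple(entries))
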