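"""Readers and writers for corpus and result files.

Formats are deliberately desk-scale and diff-able: notes as JSONL (one note
object per line), stays / labels / verdicts / truth as UTF-8 CSV with a header
row and ISO-8601 timestamps. A corpus load collects schema-level problems
(malformed JSON, missing fields, bad timestamps) into a rejects report with
line numbers instead of aborting; structural problems (a note referencing an
unknown stay, duplicate ids) raise a load error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import ValidationError

from .detection import ClinicalNote, HospitalStay, StayClassification, classifications_to_frame
from .evaluation import MethodLabels

__all__ = [
    "CorpusLoadError",
    "RejectedLine",
    "read_corpus",
    "write_corpus",
    "write_truth",
    "read_truth",
    "write_classifications",
    "read_binary_labels",
    "read_method_labels",
    "read_overrides",
]

_NOTE_FIELDS = ("note_id", "stay_id", "timestamp", "text")
_STAY_FIELDS = ("stay_id", "age", "sex", "admission", "discharge")


class CorpusLoadError(ValueError):
    """Raised for structural problems a rejects report cannot absorb."""


@dataclass(frozen=True)
class RejectedLine:
    """One input line that failed schema validation."""

    source: str
    line_no: int
    reason: str


def _parse_stay_row(row: Mapping, line_no: int) -> HospitalStay:
    missing = [f for f in _STAY_FIELDS if f not in row or pd.isna(row[f])]
    if missing:
        raise ValueError(f"missing required field(s) {', '.join(missing)}")
    return HospitalStay(
        stay_id=str(row["stay_id"]),
        age=row["age"],
        sex=row["sex"],
        admission=row["admission"],
        discharge=row["discharge"],
        primary_diagnosis=str(row.get("primary_diagnosis", "unknown") or "unknown"),
    )


def read_corpus(
    notes_path: str | Path,
    stays_path: str | Path,
) -> tuple[list[HospitalStay], list[RejectedLine]]:
    """Load stays (CSV or JSONL) and attach their notes (JSONL).

    Returns ``(stays, rejects)``. Schema-level problems on individual lines
    land in *rejects* with their line numbers; a note referencing an unknown
    ``stay_id``, a duplicate id, or a note timestamped outside its stay
    (±1 day) raises :class:`CorpusLoadError`.
    """
    notes_path, stays_path = Path(notes_path), Path(stays_path)
    rejects: list[RejectedLine] = []

    stays: dict[str, HospitalStay] = {}
    if stays_path.suffix.lower() == ".jsonl":
        rows = []
        for line_no, line in enumerate(
                stays_path.read_text(encoding="utf-8").splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rows.append((line_no, json.loads(line)))
            except json.JSONDecodeError as exc:
                rejects.append(RejectedLine(stays_path.name, line_no,
                                            f"invalid JSON: {exc.msg}"))
    else:
        df = pd.read_csv(stays_path, dtype={"stay_id": str})
        rows = [(i + 2, row) for i, row in enumerate(df.to_dict("records"))]

    for line_no, row in rows:
        try:
            stay = _parse_stay_row(row, line_no)
        except (ValueError, ValidationError) as exc:
            rejects.append(RejectedLine(stays_path.name, line_no, _first_error(exc)))
            continue
        if stay.stay_id in stays:
            raise CorpusLoadError(
                f"{stays_path.name}:{line_no}: duplicate stay_id {stay.stay_id!r}")
        stays[stay.stay_id] = stay

    notes_by_stay: dict[str, list[ClinicalNote]] = {s: [] for s in stays}
    seen_note_ids: set[str] = set()
    for line_no, line in enumerate(
            notes_path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            rejects.append(RejectedLine(notes_path.name, line_no,
                                        f"invalid JSON: {exc.msg}"))
            continue
        missing = [f for f in _NOTE_FIELDS if f not in obj]
        if missing:
            rejects.append(RejectedLine(
                notes_path.name, line_no,
                f"missing required field(s) {', '.join(missing)}"))
            continue
        try:
            note = ClinicalNote(**obj)
        except ValidationError as exc:
            rejects.append(RejectedLine(notes_path.name, line_no, _first_error(exc)))
            continue
        if note.stay_id not in stays:
            raise CorpusLoadError(
                f"{notes_path.name}:{line_no}: note {note.note_id!r} references "
                f"unknown stay {note.stay_id!r}")
        if note.note_id in seen_note_ids:
            raise CorpusLoadError(
                f"{notes_path.name}:{line_no}: duplicate note_id {note.note_id!r}")
        seen_note_ids.add(note.note_id)
        notes_by_stay[note.stay_id].append(note)

    result: list[HospitalStay] = []
    for stay_id, stay in stays.items():
        notes = sorted(notes_by_stay[stay_id], key=lambda n: (n.timestamp, n.note_id))
        try:
            result.append(HospitalStay.model_validate(
                {**stay.model_dump(), "notes": notes}))
        except ValidationError as exc:
            raise CorpusLoadError(f"stay {stay_id!r}: {_first_error(exc)}") from exc
    return result, rejects


def _first_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        e = exc.errors()[0]
        loc = ".".join(str(p) for p in e["loc"])
        return f"field {loc}: {e['msg']}" if loc else e["msg"]
    return str(exc)


def write_corpus(
    stays: Sequence[HospitalStay],
    notes_path: str | Path,
    stays_path: str | Path,
) -> None:
    """Write notes as JSONL and stays as CSV (UTF-8, ISO-8601 timestamps)."""
    notes_path, stays_path = Path(notes_path), Path(stays_path)
    with notes_path.open("w", encoding="utf-8") as fh:
        for stay in stays:
            for n in stay.notes:
                fh.write(json.dumps({
                    "note_id": n.note_id, "stay_id": n.stay_id,
                    "author_role": n.author_role, "note_type": n.note_type,
                    "timestamp": n.timestamp.isoformat(), "text": n.text,
                }, ensure_ascii=False) + "\n")
    pd.DataFrame([{
        "stay_id": s.stay_id, "age": s.age, "sex": s.sex,
        "admission": s.admission.isoformat(),
        "discharge": s.discharge.isoformat(),
        "primary_diagnosis": s.primary_diagnosis,
    } for s in stays]).to_csv(stays_path, index=False)


def write_truth(truth: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(truth.items()), columns=["stay_id", "truth"]) \
        .to_csv(Path(path), index=False)


def read_truth(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(Path(path), dtype=str)
    for col in ("stay_id", "truth"):
        if col not in df.columns:
            raise CorpusLoadError(f"{Path(path).name}: missing column {col!r}")
    return dict(zip(df["stay_id"], df["truth"]))


def write_classifications(
    results: Sequence[StayClassification], path: str | Path
) -> None:
    classifications_to_frame(list(results)).to_csv(Path(path), index=False)


def read_binary_labels(path: str | Path, label_col: str = "label") -> dict[str, int]:
    """Read a two-column stay_id/label CSV into a mapping."""
    df = pd.read_csv(Path(path), dtype={"stay_id": str})
    if "stay_id" not in df.columns or label_col not in df.columns:
        raise CorpusLoadError(
            f"{Path(path).name}: need columns stay_id and {label_col}")
    return {s: int(v) for s, v in zip(df["stay_id"], df[label_col])}


def read_method_labels(path: str | Path) -> list[MethodLabels]:
    """Read long-format method labels (columns stay_id, method, label)."""
    df = pd.read_csv(Path(path), dtype={"stay_id": str, "method": str})
    for col in ("stay_id", "method", "label"):
        if col not in df.columns:
            raise CorpusLoadError(f"{Path(path).name}: missing column {col!r}")
    return [
        MethodLabels(method=method,
                     labels={s: int(v) for s, v in
                             zip(sub["stay_id"], sub["label"])})
        for method, sub in df.groupby("method", sort=True)
    ]


def read_overrides(path: str | Path) -> dict[str, int]:
    """Read adjudication overrides (columns stay_id, adjudicated_label)."""
    df = pd.read_csv(Path(path), dtype={"stay_id": str})
    for col in ("stay_id", "adjudicated_label"):
        if col not in df.columns:
            raise CorpusLoadError(f"{Path(path).name}: missing column {col!r}")
    return {s: int(v) for s, v in zip(df["stay_id"], df["adjudicated_label"])}
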