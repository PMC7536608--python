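"""Synthetic German note corpora with planted ground truth.

No de-identified corpus of hospital notes exists for this problem, so the
pipeline is exercised on generated stays. Each synthetic stay draws
demographics and a length of stay from distributions matching a mixed
internal-medicine/orthopaedics inpatient population (age ≈ 65 ± 18 years,
length of stay lognormal with mean ≈ 11.5 days, longer for fall stays,
mean ≈ 22.6 days), then receives template-built notes:

* *in-hospital fall* stays get a progress note on day ≥ 2 describing the fall
  with standard lexicon terms ("Pat. im Badezimmer ausgerutscht …");
* *present-on-admission* stays get an admission anamnesis combining a fall
  term with emergency-context wording ("Sturz zu Hause, notfallmässig
  eingeliefert");
* negative stays may receive a decoy compound ("Bodenbett installiert") that
  contains a fall term as a substring without describing a fall.

Filler sentences use ordinary ward vocabulary free of lexicon terms, so
planted truth is exactly recoverable: the generator reproduces the structural
challenge of the detection problem (compound decoys, pre-admission mentions),
not the full variability of clinical German. An adversarial mode additionally
plants fall terms inside novel, unlisted compounds to probe suppression gaps.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .detection import ClinicalNote, HospitalStay

__all__ = ["SynthConfig", "generate_corpus", "describe_sample", "DIAGNOSES"]

#: Table-style primary-diagnosis categories used for descriptive summaries.
DIAGNOSES = (
    "cardiac", "musculoskeletal", "endocrinologic", "gastrointestinal",
    "pulmonary", "infectious", "neurological", "psychiatric", "cancer",
    "dementia",
)

TruthLabel = Literal["in_hospital_fall", "poa_fall", "none"]


class SynthConfig(BaseModel):
    """Generator settings; defaults mirror a validation-study-sized sample.

    ``los_mean``/``los_sd`` parameterize the non-fall length-of-stay
    lognormal in days; fall stays draw from ``fall_los_mean``/``fall_los_sd``
    (falls both prolong stays and are likelier in long stays, and the
    generator encodes that association directly).
    """

    n_stays: int = Field(default=300, ge=1)
    p_inhospital_fall: float = Field(default=0.05, ge=0, le=1)
    p_poa_fall: float = Field(default=0.05, ge=0, le=1)
    p_decoy: float = Field(default=0.20, ge=0, le=1)
    notes_per_stay: tuple[int, int] = (3, 10)
    los_mean: float = Field(default=11.5, gt=0)
    los_sd: float = Field(default=12.6, gt=0)
    fall_los_mean: float = Field(default=22.6, gt=0)
    fall_los_sd: float = Field(default=19.0, gt=0)
    age_mean: float = 65.3
    age_sd: float = Field(default=18.0, gt=0)
    p_female: float = Field(default=0.51, ge=0, le=1)
    adversarial: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        if self.p_inhospital_fall + self.p_poa_fall > 1:
            raise ValueError("p_inhospital_fall + p_poa_fall must not exceed 1")
        lo, hi = self.notes_per_stay
        if not 0 <= lo <= hi:
            raise ValueError("notes_per_stay must be a non-decreasing pair of "
                             "non-negative counts")
        return self


# ---------------------------------------------------------------------------
# Templates. Filler text must contain no lexicon term (inclusion, exclusion
# or admission-context), so that planted truth is the only signal.
# ---------------------------------------------------------------------------

_FILLER = (
    "Vitalzeichen stabil, RR {rr} mmHg, Puls {puls}/min.",
    "Patient{fem} klagt über leichte Kopfschmerzen, Analgesie nach Schema verabreicht.",
    "Mobilisation mit Physiotherapie im Gang, gut toleriert.",
    "Wundverband gewechselt, Wundverhältnisse reizlos.",
    "Appetit mässig, Flüssigkeitsbilanz ausgeglichen.",
    "Nacht ruhig verlaufen, Patient{fem} hat gut geschlafen.",
    "Laborkontrolle angemeldet, Elektrolyte im Normbereich.",
    "Visite erfolgt, Therapie unverändert weitergeführt.",
    "Atemtherapie durchgeführt, Sättigung {spo2}% unter Raumluft.",
    "Angehörigengespräch geführt, Fragen zur Entlassungsplanung besprochen.",
)

_FALL_TEMPLATES = (
    "Patient{fem} wurde um {uhr} Uhr am Boden liegend vorgefunden, "
    "keine Kopfverletzung ersichtlich, Arzt informiert.",
    "Pat. ist im Badezimmer ausgerutscht und gestürzt, RR stabil, "
    "Röntgen angemeldet.",
    "Sturz beim Aufstehen vom Nachtstuhl beobachtet, Patient{fem} "
    "klagt über Schmerzen in der Hüfte.",
    "Pat. synkopiert, am Boden gefunden, EKG abgeleitet, engmaschige "
    "Überwachung.",
)

_POA_TEMPLATES = (
    "Sturz zu Hause, notfallmässig eingeliefert, Schmerzen im Becken.",
    "Patient{fem} zu Hause gestürzt, mit der Ambulanz auf die "
    "Notfallstation gebracht.",
    "Synkope zu Hause, durch Angehörige gefunden, via Ambulanz eingeliefert.",
    "Pat. auf vereister Strasse ausgerutscht, Zuweisung über den Notfall.",
)

_DECOY_TEMPLATES = (
    "Bodenbett zur Nacht installiert, Klingel in Reichweite.",
    "Bodenbett weitergeführt, Patient{fem} einverstanden.",
)

#: Novel compounds embedding a fall term without an exclusion-list entry;
#: generated only in adversarial mode, to probe suppression gaps.
_ADVERSARIAL_TEMPLATES = (
    "Sturzprophylaxe-Massnahmen gemäss Standard weitergeführt.",
    "Sturzrisikoassessment durchgeführt, Score unauffällig.",
)

_ANAMNESIS_NEUTRAL = (
    "Elektive Aufnahme zur weiteren Abklärung bei bekannter Grunderkrankung.",
    "Aufnahme bei zunehmender Dyspnoe, Übernahme von der Tagesklinik.",
    "Zuweisung durch den Hausarzt bei unklaren Abdominalschmerzen.",
)

_DISCHARGE_NEUTRAL = (
    "Austritt in gutem Allgemeinzustand, Nachkontrolle beim Hausarzt empfohlen.",
    "Verlegung in die Rehabilitation, Medikation gemäss Austrittsbericht.",
)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a lognormal with given mean/SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _fill(template: str, rng: np.random.Generator, female: bool) -> str:
    return template.format(
        fem="in" if female else "",
        rr=f"{rng.integers(100, 160)}/{rng.integers(60, 95)}",
        puls=rng.integers(55, 100),
        spo2=rng.integers(92, 100),
        uhr=f"{rng.integers(0, 24):02d}:{rng.integers(0, 60):02d}",
    )


def _truncated_age(rng: np.random.Generator, cfg: SynthConfig) -> float:
    while True:  # rejection sampling, ≥18 years
        age = rng.normal(cfg.age_mean, cfg.age_sd)
        if 18.0 <= age <= 103.0:
            return round(age, 1)


def generate_corpus(
    config: SynthConfig | None = None, **overrides
) -> tuple[list[HospitalStay], dict[str, TruthLabel]]:
    """Generate a stay corpus with notes and the planted per-stay truth.

    Deterministic given ``config.seed`` (every draw flows from one
    ``numpy.random.default_rng``). Returns ``(stays, truth)`` where truth maps
    stay_id to ``in_hospital_fall`` / ``poa_fall`` / ``none``.
    """
    cfg = config or SynthConfig(**overrides)
    if config is not None and overrides:
        cfg = config.model_copy(update=overrides)
    rng = np.random.default_rng(cfg.seed)

    mu0, s0 = _lognormal_params(cfg.los_mean, cfg.los_sd)
    mu1, s1 = _lognormal_params(cfg.fall_los_mean, cfg.fall_los_sd)
    base = datetime(2016, 1, 1)

    stays: list[HospitalStay] = []
    truth: dict[str, TruthLabel] = {}
    for i in range(cfg.n_stays):
        stay_id = f"S{i + 1:04d}"
        u = rng.random()
        if u < cfg.p_inhospital_fall:
            label: TruthLabel = "in_hospital_fall"
        elif u < cfg.p_inhospital_fall + cfg.p_poa_fall:
            label = "poa_fall"
        else:
            label = "none"
        truth[stay_id] = label

        is_fall_stay = label != "none"
        mu, sg = (mu1, s1) if is_fall_stay else (mu0, s0)
        los = float(rng.lognormal(mu, sg))
        # floors: ≥ 1.1 d (eligibility) and, for in-hospital falls, room for a
        # fall note on day ≥ 2
        los = max(los, 3.0 if label == "in_hospital_fall" else 1.1)
        female = rng.random() < cfg.p_female

        admission = base + timedelta(days=float(rng.uniform(0, 700)),
                                     hours=float(rng.uniform(7, 19)))
        discharge = admission + timedelta(days=los)

        notes: list[ClinicalNote] = []
        seq = 0

        def add(note_type: str, role: str, ts: datetime, text: str) -> None:
            nonlocal seq
            seq += 1
            notes.append(ClinicalNote(
                note_id=f"{stay_id}-N{seq:03d}", stay_id=stay_id,
                author_role=role, note_type=note_type, timestamp=ts, text=text,
            ))

        anamnesis = (str(rng.choice(_POA_TEMPLATES)) if label == "poa_fall"
                     else str(rng.choice(_ANAMNESIS_NEUTRAL)))
        add("admission_anamnesis", "nurse",
            admission + timedelta(hours=1), _fill(anamnesis, rng, female))

        n_progress = int(rng.integers(cfg.notes_per_stay[0],
                                      cfg.notes_per_stay[1] + 1))
        day_span = max(los - 0.5, 0.25)
        progress_days = sorted(float(d) for d in rng.uniform(0.2, day_span,
                                                             n_progress))
        fall_day: float | None = None
        if label == "in_hospital_fall":
            fall_day = float(rng.uniform(2.0, max(2.25, los - 0.25)))

        for d in progress_days:
            sentences = [
                _fill(str(t), rng, female)
                for t in rng.choice(_FILLER, size=int(rng.integers(1, 4)),
                                    replace=False)
            ]
            if label == "none" and rng.random() < cfg.p_decoy:
                sentences.append(_fill(str(rng.choice(_DECOY_TEMPLATES)),
                                       rng, female))
            if cfg.adversarial and label == "none" and rng.random() < 0.5:
                sentences.append(str(rng.choice(_ADVERSARIAL_TEMPLATES)))
            role = "nurse" if rng.random() < 0.6 else "physician"
            add("progress", role, admission + timedelta(days=d),
                " ".join(sentences))

        if fall_day is not None:
            role = "nurse" if rng.random() < 0.7 else "physician"
            add("progress", role, admission + timedelta(days=fall_day),
                _fill(str(rng.choice(_FALL_TEMPLATES)), rng, female))

        add("discharge_summary", "physician", discharge,
            _fill(str(rng.choice(_DISCHARGE_NEUTRAL)), rng, female))

        notes.sort(key=lambda n: (n.timestamp, n.note_id))
        stays.append(HospitalStay(
            stay_id=stay_id,
            age=_truncated_age(rng, cfg),
            sex="female" if female else "male",
            admission=admission,
            discharge=discharge,
            primary_diagnosis=str(rng.choice(DIAGNOSES)),
            notes=notes,
        ))
    return stays, truth


def describe_sample(stays: list[HospitalStay]) -> dict:
    """Descriptive summary: age, length of stay, sex, diagnosis frequencies.

    SDs are ``None`` (not available) when fewer than two stays are given.
    """
    if not stays:
        raise ValueError("describe_sample needs at least one stay")
    df = pd.DataFrame({
        "age": [s.age for s in stays],
        "los_days": [s.length_of_stay_days for s in stays],
        "female": [s.sex == "female" for s in stays],
        "diagnosis": [s.primary_diagnosis for s in stays],
    })
    n = len(df)
    return {
        "n": n,
        "age_mean": float(df["age"].mean()),
        "age_sd": float(df["age"].std(ddof=1)) if n > 1 else None,
        "los_mean_days": float(df["los_days"].mean()),
        "los_sd_days": float(df["los_days"].std(ddof=1)) if n > 1 else None,
        "percent_female": 100.0 * float(df["female"].mean()),
        "diagnosis_counts": df["diagnosis"].value_counts().to_dict(),
    }
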