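from datetime import datetime, timedelta

import pytest

from fallscreen.detection import ClinicalNote, HospitalStay
from fallscreen.lexicon import load_lexicon

ADMISSION = datetime(2017, 3, 1, 10, 0)


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


def make_note(stay_id="S1", text="", day=5.0, note_type="progress",
              role="nurse", note_id=None):
    """A clinical note `day` days after the canonical admission time."""
    return ClinicalNote(
        note_id=note_id or f"{stay_id}-d{day:g}",
        stay_id=stay_id,
        author_role=role,
        note_type=note_type,
        timestamp=ADMISSION + timedelta(days=day),
        text=text,
    )


def make_stay(stay_id="S1", age=70, sex="female", los_days=10.0,
              diagnosis="cardiac", notes=()):
    return HospitalStay(
        stay_id=stay_id, age=age, sex=sex,
        admission=ADMISSION,
        discharge=ADMISSION + timedelta(days=los_days),
        primary_diagnosis=diagnosis,
        notes=list(notes),
    )
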