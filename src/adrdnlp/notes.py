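"""The note container shared by every pipeline stage."""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class NoteDocument:
    """One clinician note: opaque ids plus raw free text.

    ``text`` may be empty (such a note simply yields no mentions);
    ``note_date`` is carried for provenance but plays no role in
    severity resolution.
    """

    patient_id: str
    note_id: str
    text: str
    note_date: Optional[datetime.date] = None

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")
        if not self.note_id:
            raise ValueError("note_id must be nonempty")
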