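"""Patient-level severity resolution.

Two precedence rules, applied over all of a patient's notes regardless of
date: (1) textual severity keywords outrank cognitive scores — when both
exist, the label comes from the keywords even if discordant, because
providers stage the disease on more than the test result; (2) within the
winning source the more severe class wins (``mild < moderate_severe``),
on the rationale that dementia progresses and the worse finding is the
more current one.  A patient with no textual mention and no valid score
is ``undocumented``; invalid (out-of-bounds) scores alone never count as
severity information.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .lexicon import CutoffTable, TermLexicon
from .mentions import SeverityMention, extract_severity_mentions
from .notes import NoteDocument
from .scores import ScoreMention, extract_score_mentions
from .textproc import tokenize

UNDOCUMENTED = "undocumented"
_RANK = {"mild": 0, "moderate_severe": 1}


class ConsistencyError(ValueError):
    """Evidence attributed to the wrong patient."""


@dataclass(frozen=True)
class PatientSeverity:
    """Resolved patient-level label with its evidence trail."""

    patient_id: str
    severity: str  # mild | moderate_severe | undocumented
    source: str  # text | score | none
    evidence: tuple = ()

    @property
    def has_severity_info(self) -> bool:
        return self.source != "none"

    @property
    def n_text_evidence(self) -> int:
        return sum(isinstance(e, SeverityMention) for e in self.evidence)

    @property
    def n_score_evidence(self) -> int:
        return sum(isinstance(e, ScoreMention) for e in self.evidence)


def _max_class(classes: Iterable[str]) -> str:
    return max(classes, key=_RANK.__getitem__)


def resolve_patient(
    patient_id: str,
    mentions: Sequence[SeverityMention],
    scores: Sequence[ScoreMention],
    note_owner: Optional[Mapping[str, str]] = None,
) -> PatientSeverity:
    """Apply text-over-score precedence and max-severity-wins.

    ``note_owner`` (note_id -> patient_id), when given, is used to verify
    that every evidence item belongs to ``patient_id``.
    """
    if note_owner is not None:
        for ev in list(mentions) + list(scores):
            owner = note_owner.get(ev.note_id)
            if owner != patient_id:
                raise ConsistencyError(
                    f"evidence from note {ev.note_id!r} (patient {owner!r}) "
                    f"passed to patient {patient_id!r}"
                )
    valid_scores = [s for s in scores if s.valid and s.severity is not None]
    if mentions:
        return PatientSeverity(
            patient_id=patient_id,
            severity=_max_class(m.severity for m in mentions),
            source="text",
            evidence=tuple(mentions) + tuple(scores),
        )
    if valid_scores:
        return PatientSeverity(
            patient_id=patient_id,
            severity=_max_class(s.severity for s in valid_scores),
            source="score",
            evidence=tuple(scores),
        )
    return PatientSeverity(
        patient_id=patient_id,
        severity=UNDOCUMENTED,
        source="none",
        evidence=tuple(scores),
    )


def _pct(count: int, total: int) -> Optional[float]:
    if total == 0:
        return None
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def resolve_cohort(
    notes: Iterable[NoteDocument],
    lexicon: TermLexicon,
    cutoffs: CutoffTable,
    *,
    handle_negation: bool = False,
    extended_delimiters: bool = False,
    audit: Optional[list] = None,
) -> Tuple[List[PatientSeverity], dict]:
    """Run both extraction branches on every note and resolve per patient.

    Returns one :class:`PatientSeverity` per distinct patient (sorted by
    id) plus a cohort summary with counts and percentages (2 decimals)
    per severity class and per evidence source.
    """
    by_patient: Dict[str, List[NoteDocument]] = {}
    for note in notes:
        by_patient.setdefault(note.patient_id, []).append(note)

    results: List[PatientSeverity] = []
    for patient_id in sorted(by_patient):
        mentions: List[SeverityMention] = []
        scores: List[ScoreMention] = []
        for note in by_patient[patient_id]:
            seq = tokenize(note.text, extended_delimiters)
            mentions.extend(
                extract_severity_mentions(
                    note,
                    lexicon,
                    handle_negation=handle_negation,
                    seq=seq,
                )
            )
            scores.extend(
                extract_score_mentions(note, lexicon, cutoffs, audit=audit, seq=seq)
            )
        results.append(resolve_patient(patient_id, mentions, scores))

    n = len(results)
    counts = {"mild": 0, "moderate_severe": 0, UNDOCUMENTED: 0}
    by_source = {"text": 0, "score": 0, "none": 0}
    for r in results:
        counts[r.severity] += 1
        by_source[r.source] += 1
    summary = {
        "n_patients": n,
        "counts": counts,
        "percentages": {k: _pct(v, n) for k, v in counts.items()},
        "by_source": by_source,
        "source_percentages": {k: _pct(v, n) for k, v in by_source.items()},
        "zero_denominator": n == 0,
    }
    return results, summary
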