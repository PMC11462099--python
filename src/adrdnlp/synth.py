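"""Labeled synthetic clinician notes for end-to-end testing.

Real dementia notes cannot be redistributed, so this module fabricates
template-based notes that exercise every extraction rule: severity
keywords planted within 5 tokens of an ADRD trigger, MMSE/MoCA scores in
the three documented shapes (``N/30`` fractions, bare integers, itemized
MoCA listings ending in "total score N"), trigger-word distractors with
no severity context, and six optional noise modes reproducing documented
failure causes (date-like slash tokens, out-of-bounds scores, negated
mentions, "mild cognitive disorder" confusables, ``\\r\\n`` artifacts,
fused tokens from missing delimiters).

Every note carries gold annotations (offsets into the generated text)
and a gold patient-level label; with all noise rates at zero the gold
label equals what the pipeline resolves, which is the core round-trip
property the test suite relies on.  Generation is deterministic: one
seed drives everything, with per-patient and per-note substreams keyed
by counters so a corpus is byte-identical across runs and noise
injections for one note never perturb another.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .notes import NoteDocument
from .resolve import UNDOCUMENTED

NOISE_MODES = (
    "date_like_tokens",
    "out_of_bounds_scores",
    "negated_mentions",
    "mci_distractors",
    "crlf_artifacts",
    "missing_delimiters",
)

_SEVERITIES = ("mild", "moderate_severe", UNDOCUMENTED)
_EVIDENCE_KINDS = ("text_only", "score_only", "both")
_FORMATS = ("fraction_of_30", "bare_integer", "itemized_total")


@dataclass(frozen=True)
class NoiseRates:
    """Per-note injection probability of each noise mode."""

    date_like_tokens: float = 0.05
    out_of_bounds_scores: float = 0.05
    negated_mentions: float = 0.05
    mci_distractors: float = 0.05
    crlf_artifacts: float = 0.05
    missing_delimiters: float = 0.05

    def as_dict(self) -> Dict[str, float]:
        return {m: getattr(self, m) for m in NOISE_MODES}

    @classmethod
    def zero(cls) -> "NoiseRates":
        return cls(**{m: 0.0 for m in NOISE_MODES})


@dataclass(frozen=True)
class GenerationConfig:
    """Study conditions for a synthetic cohort.

    Default prevalences mirror the documented cohort mix (22.93% mild,
    20.87% moderate-to-severe, 56.20% undocumented); the evidence mix
    reflects that among documented patients roughly a quarter carry only
    text evidence, a quarter only scores, and half both.
    """

    n_patients: int = 200
    notes_per_patient: Tuple[int, int] = (1, 3)
    prevalence: Tuple[float, float, float] = (0.2293, 0.2087, 0.5620)
    evidence_mix: Tuple[float, float, float] = (0.25, 0.23, 0.52)
    score_format_mix: Tuple[float, float, float] = (0.5, 0.3, 0.2)
    noise: NoiseRates = field(default_factory=NoiseRates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        lo, hi = self.notes_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("notes_per_patient range must satisfy 1 <= lo <= hi")
        for name, probs in (
            ("prevalence", self.prevalence),
            ("evidence_mix", self.evidence_mix),
            ("score_format_mix", self.score_format_mix),
        ):
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be three nonnegative proportions")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(probs)})")
        for mode, rate in self.noise.as_dict().items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"noise rate {mode} outside [0, 1]")


@dataclass(frozen=True)
class GoldAnnotation:
    """A planted artifact with offsets into the final note text."""

    kind: str  # severity_text | score | noise
    start: int
    end: int
    text: str
    severity: Optional[str] = None
    test: Optional[str] = None
    value: Optional[int] = None
    valid: bool = True
    intent: Optional[str] = None  # noise mode or "fused"
    extractable: bool = True

    def shifted(self, offset: int) -> "GoldAnnotation":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class LabeledNote:
    """A generated note plus its gold annotations and patient label."""

    note: NoteDocument
    annotations: Tuple[GoldAnnotation, ...]
    patient_severity: str  # gold patient-level label
    patient_source: str  # text | score | none (gold evidence source)


# ---------------------------------------------------------------------------
# Sentence banks.  Fillers contain no trigger words, severity keywords or
# digits; distractors contain ADRD triggers with no severity context.
# ---------------------------------------------------------------------------

_HEADERS = (
    "progress note",
    "clinic visit note",
    "geriatric medicine follow-up note",
    "inpatient daily note",
)

_FILLERS = (
    "patient resting comfortably in room at time of visit",
    "vital signs reviewed and stable per nursing documentation",
    "medication list reconciled with pharmacy records today",
    "family present at bedside and updated on the plan of care",
    "follow up arranged with primary care in several weeks",
    "diet tolerated well and hydration encouraged throughout the day",
    "patient ambulating in hallway with walker and standby assistance",
    "sleep reported as fair with occasional nighttime awakening",
    "labs reviewed and unremarkable per most recent results",
    "skin intact without areas of concern on examination",
)

_DISTRACTORS = (
    "indication: dementia follow-up and medication review",
    "history of vascular dementia noted in the problem list",
    "chronic cognitive impairment discussed with family at length",
    "alzheimer disease managed by outside neurology clinic",
    "counseling provided regarding dementia safety and supervision at home",
)

# (sentence, severity phrase, trigger phrase) — phrase within 5 tokens of
# trigger, each phrase appearing exactly once in its sentence.
_TEXT_EVIDENCE = {
    "mild": (
        ("patient seen today with mild dementia and stable mood", "mild", "dementia"),
        (
            "impression is early stage alzheimer disease per neurology",
            "early stage",
            "alzheimer disease",
        ),
        (
            "exam findings consistent with mild cognitive decline overall",
            "mild",
            "cognitive decline",
        ),
        (
            "assessment documents early alzheimer dementia this visit",
            "early",
            "alzheimer dementia",
        ),
    ),
    "moderate_severe": (
        (
            "patient with advanced dementia requiring assistance for all care",
            "advanced",
            "dementia",
        ),
        (
            "impression is severe alzheimer disease with behavioral disturbance",
            "severe",
            "alzheimer disease",
        ),
        (
            "assessment documents moderate vascular dementia per chart review",
            "moderate",
            "vascular dementia",
        ),
        (
            "longstanding late-stage dementia with gradual functional loss",
            "late-stage",
            "dementia",
        ),
    ),
}

_ITEMIZED_PREFIX = (
    "moca administered with trails 1 cube 0 clock 2 naming 3 attention 4 "
    "language 1 abstraction 1 delayed recall 2 orientation 5 total score "
)

_NEGATED_SENTENCES = (
    ("no evidence of advanced dementia on examination today", "moderate_severe"),
    ("screening negative for severe cognitive impairment this visit", "moderate_severe"),
)

_MCI_SENTENCE = (
    "neuropsychological testing concluded a mild cognitive disorder nos"
)


# ---------------------------------------------------------------------------
# Sentence construction helpers.  Each builder returns (sentence text,
# sentence-local annotations).
# ---------------------------------------------------------------------------


def _text_evidence_sentence(severity: str, rng) -> Tuple[str, List[GoldAnnotation]]:
    sentence, phrase, trigger = _TEXT_EVIDENCE[severity][
        int(rng.integers(len(_TEXT_EVIDENCE[severity])))
    ]
    s = sentence.find(phrase)
    return sentence, [
        GoldAnnotation(
            kind="severity_text",
            start=s,
            end=s + len(phrase),
            text=phrase,
            severity=severity,
        )
    ]


_SCORE_RANGES = {
    # value ranges consistent with the default cutoff bands, per class
    ("MMSE", "mild"): (21, 30),
    ("MMSE", "moderate_severe"): (5, 20),
    ("MoCA", "mild"): (18, 30),
    ("MoCA", "moderate_severe"): (4, 17),
}


def _score_sentence(
    severity: str, variant: str, rng
) -> Tuple[str, List[GoldAnnotation]]:
    test = "MoCA" if variant == "itemized_total" else (
        "MMSE" if rng.random() < 0.5 else "MoCA"
    )
    lo, hi = _SCORE_RANGES[(test, severity)]
    value = int(rng.integers(lo, hi + 1))
    if variant == "fraction_of_30":
        raw = f"{value}/30"
        templates = {
            "MMSE": f"mmse today scored {raw} per bedside testing",
            "MoCA": f"moca completed in clinic with result {raw} documented",
        }
        sentence = templates[test]
    elif variant == "bare_integer":
        raw = str(value)
        templates = {
            "MMSE": f"mmse was {raw} when repeated at this visit",
            "MoCA": f"moca was {raw} per occupational therapy note",
        }
        sentence = templates[test]
    else:
        raw = str(value)
        sentence = _ITEMIZED_PREFIX + raw
    s = sentence.rindex(raw)
    return sentence, [
        GoldAnnotation(
            kind="score",
            start=s,
            end=s + len(raw),
            text=raw,
            severity=severity,
            test=test,
            value=value,
        )
    ]


def _compose(
    pieces: Sequence[Tuple[str, List[GoldAnnotation]]], rng
) -> Tuple[str, List[GoldAnnotation]]:
    """Join sentences with ". ", random first-letter capitalization."""
    parts: List[str] = []
    annots: List[GoldAnnotation] = []
    offset = 0
    for i, (sentence, local) in enumerate(pieces):
        if rng.random() < 0.5:
            sentence = sentence[0].upper() + sentence[1:]
            local = [
                replace(a, text=sentence[a.start : a.end]) for a in local
            ]
        parts.append(sentence)
        annots.extend(a.shifted(offset) for a in local)
        offset += len(sentence)
        if i < len(pieces) - 1:
            parts.append(". ")
            offset += 2
    text = "".join(parts) + "."
    return text, annots


# ---------------------------------------------------------------------------
# Noise injection.
# ---------------------------------------------------------------------------


def _insert_sentence(
    note: LabeledNote, sentence: str, local: List[GoldAnnotation], rng
) -> LabeledNote:
    """Insert a sentence at a random sentence boundary, shifting offsets."""
    text = note.note.text
    boundaries = [i + 2 for i in range(len(text) - 1) if text[i : i + 2] == ". "]
    if boundaries:
        at = int(boundaries[int(rng.integers(len(boundaries)))])
        inserted = sentence + ". "
    else:
        at = len(text)
        inserted = " " + sentence + "."
        local = [a.shifted(1) for a in local]
    new_text = text[:at] + inserted + text[at:]
    shift = len(inserted)
    new_annots = [
        a.shifted(shift) if a.start >= at else a for a in note.annotations
    ]
    new_annots.extend(a.shifted(at) for a in local)
    return replace(
        note,
        note=replace(note.note, text=new_text),
        annotations=tuple(new_annots),
    )


def _delete_char(note: LabeledNote, at: int, mark: Sequence[int] = ()) -> LabeledNote:
    """Remove one character, shifting annotations; ``mark`` indices get
    ``intent='fused'`` and ``extractable=False``."""
    text = note.note.text
    new_text = text[:at] + text[at + 1 :]
    new_annots = []
    for i, a in enumerate(note.annotations):
        if a.start > at:
            a = a.shifted(-1)
        elif a.end > at:
            a = replace(a, end=a.end - 1, text=new_text[a.start : a.end - 1])
        if i in mark:
            a = replace(a, intent="fused", extractable=False)
        new_annots.append(a)
    return replace(
        note,
        note=replace(note.note, text=new_text),
        annotations=tuple(new_annots),
    )


def inject_noise(note: LabeledNote, mode: str, rng) -> LabeledNote:
    """Apply one noise mode to a note, recording the artifact in gold.

    Gold patient labels never change: noise models documentation
    artifacts, not clinical reality, so any downstream misclassification
    is a (deliberately reproducible) algorithm failure.
    """
    if mode not in NOISE_MODES:
        raise ValueError(f"unknown noise mode {mode!r}")
    if mode == "date_like_tokens":
        d = f"{int(rng.integers(1, 13))}/{int(rng.integers(1, 29))}"
        sentence = f"moca review planned on {d} at the next visit"
        s = sentence.index(d)
        ann = GoldAnnotation(
            kind="noise", start=s, end=s + len(d), text=d, intent=mode
        )
        return _insert_sentence(note, sentence, [ann], rng)
    if mode == "out_of_bounds_scores":
        v = int(rng.integers(31, 46))
        raw = f"{v}/50"
        sentence = f"mmse {raw} recorded per outside facility report"
        s = sentence.index(raw)
        ann = GoldAnnotation(
            kind="score",
            start=s,
            end=s + len(raw),
            text=raw,
            test="MMSE",
            value=v,
            valid=False,
            intent=mode,
        )
        return _insert_sentence(note, sentence, [ann], rng)
    if mode == "negated_mentions":
        sentence, implied = _NEGATED_SENTENCES[
            int(rng.integers(len(_NEGATED_SENTENCES)))
        ]
        ann = GoldAnnotation(
            kind="noise",
            start=0,
            end=len(sentence),
            text=sentence,
            severity=implied,
            intent=mode,
        )
        return _insert_sentence(note, sentence, [ann], rng)
    if mode == "mci_distractors":
        sentence = _MCI_SENTENCE
        ann = GoldAnnotation(
            kind="noise",
            start=0,
            end=len(sentence),
            text=sentence,
            severity="mild",
            intent=mode,
        )
        return _insert_sentence(note, sentence, [ann], rng)
    if mode == "crlf_artifacts":
        text = note.note.text
        boundaries = [i for i in range(len(text) - 1) if text[i : i + 2] == ". "]
        at = (
            boundaries[int(rng.integers(len(boundaries)))] + 1
            if boundaries
            else len(text)
        )
        insert = "\r\n\r\n"
        new_text = text[:at] + insert + text[at:]
        new_annots = tuple(
            a.shifted(len(insert)) if a.start >= at else a
            for a in note.annotations
        )
        return replace(
            note,
            note=replace(note.note, text=new_text),
            annotations=new_annots,
        )
    # missing_delimiters: fuse the space right after a planted finding so
    # the trigger/severity tokens merge and the rule set misses them.
    for i, a in enumerate(note.annotations):
        if a.kind == "severity_text" and a.extractable:
            text = note.note.text
            if a.end < len(text) and text[a.end] == " ":
                return _delete_char(note, a.end, mark=[i])
    for i, a in enumerate(note.annotations):
        if a.kind == "score" and a.extractable and a.start > 0:
            text = note.note.text
            if text[a.start - 1] == " ":
                return _delete_char(note, a.start - 1, mark=[i])
    text = note.note.text
    sp = text.find(" ")
    if sp >= 0:
        return _delete_char(note, sp)
    return note


# ---------------------------------------------------------------------------
# Corpus generation.
# ---------------------------------------------------------------------------


def _patient_notes(config: GenerationConfig, idx: int) -> List[LabeledNote]:
    rng = np.random.default_rng([config.seed, idx])
    severity = _SEVERITIES[
        int(rng.choice(3, p=np.asarray(config.prevalence) / sum(config.prevalence)))
    ]
    lo, hi = config.notes_per_patient
    n_notes = int(rng.integers(lo, hi + 1))
    documented = severity != UNDOCUMENTED
    kind = (
        _EVIDENCE_KINDS[int(rng.choice(3, p=config.evidence_mix))]
        if documented
        else None
    )
    text_note = int(rng.integers(n_notes)) if documented else -1
    score_note = int(rng.integers(n_notes)) if documented else -1
    variant = _FORMATS[int(rng.choice(3, p=config.score_format_mix))]
    patient_id = f"p{idx:05d}"
    source = {
        "text_only": "text",
        "both": "text",
        "score_only": "score",
        None: "none",
    }[kind]

    notes: List[LabeledNote] = []
    for j in range(n_notes):
        note_rng = np.random.default_rng([config.seed, idx, j])
        pieces: List[Tuple[str, List[GoldAnnotation]]] = []
        pieces.append((_HEADERS[int(note_rng.integers(len(_HEADERS)))], []))
        n_fill = int(note_rng.integers(3, 7))
        for _ in range(n_fill):
            pieces.append(
                (_FILLERS[int(note_rng.integers(len(_FILLERS)))], [])
            )
        n_distract = int(note_rng.integers(1, 3))
        for _ in range(n_distract):
            pieces.append(
                (_DISTRACTORS[int(note_rng.integers(len(_DISTRACTORS)))], [])
            )
        if documented and j == text_note and kind in ("text_only", "both"):
            pieces.append(_text_evidence_sentence(severity, note_rng))
        if documented and j == score_note and kind in ("score_only", "both"):
            pieces.append(_score_sentence(severity, variant, note_rng))
        order = note_rng.permutation(len(pieces) - 1) + 1
        pieces = [pieces[0]] + [pieces[k] for k in order]
        text, annots = _compose(pieces, note_rng)

        date = datetime.date(2014, 1, 1) + datetime.timedelta(
            days=int(note_rng.integers(0, 2191))
        )
        note = LabeledNote(
            note=NoteDocument(
                patient_id=patient_id,
                note_id=f"{patient_id}-n{j}",
                text=text,
                note_date=date,
            ),
            annotations=tuple(annots),
            patient_severity=severity,
            patient_source=source,
        )

        # Noise decisions are drawn in a fixed order before any injection
        # so that raising one rate enlarges (never reshuffles) the set of
        # injected notes; injection randomness uses a separate substream.
        draws = note_rng.random(len(NOISE_MODES))
        inj_rng = np.random.default_rng([config.seed, idx, j, 7])
        rates = config.noise.as_dict()
        for mode, u in zip(NOISE_MODES, draws):
            if u < rates[mode]:
                note = inject_noise(note, mode, inj_rng)
        notes.append(note)
    return notes


def generate_corpus(config: GenerationConfig) -> List[LabeledNote]:
    """Generate a deterministic labeled corpus under the given conditions."""
    config.validate()
    out: List[LabeledNote] = []
    for idx in range(config.n_patients):
        out.extend(_patient_notes(config, idx))
    return out


def corpus_gold(notes: Sequence[LabeledNote]):
    """Patient-level gold labels of a corpus (one per patient, sorted).

    Returned as :class:`adrdnlp.evaluate.GoldLabel` records suitable for
    ``build_confusion``.
    """
    from .evaluate import GoldLabel

    seen: Dict[str, Tuple[str, str]] = {}
    for ln in notes:
        pid = ln.note.patient_id
        if pid in seen and seen[pid] != (ln.patient_severity, ln.patient_source):
            raise ValueError(f"conflicting gold labels for patient {pid}")
        seen[pid] = (ln.patient_severity, ln.patient_source)
    return [
        GoldLabel(
            record_id=pid,
            has_severity_info=sev != UNDOCUMENTED,
            severity=None if sev == UNDOCUMENTED else sev,
        )
        for pid, (sev, _src) in sorted(seen.items())
    ]
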