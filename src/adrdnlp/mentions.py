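"""The severity-text branch: ADRD triggers plus nearby severity keywords.

For every occurrence of an ADRD trigger phrase a (-5, 5) token window is
formed (the trigger at relative position 0); every severity keyword found
inside that window yields one :class:`SeverityMention`.  Negation is NOT
handled by default — "negative for cognitive impairment" style text will
produce a mention, a documented failure mode of pure keyword matching —
but an opt-in mode suppresses mentions whose trigger or severity phrase
is preceded within 3 tokens by a negation cue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .lexicon import TermLexicon
from .notes import NoteDocument
from .textproc import (
    TokenSequence,
    TokenWindow,
    TriggerMatch,
    find_triggers,
    tokenize,
    window_around_match,
)

#: Tokens before and after the ADRD trigger in the severity-text window.
TEXT_WINDOW = (5, 5)

#: Cue phrases for the opt-in negation mode.
NEGATION_CUES = ("no", "not", "denies", "without", "negative for", "no evidence of")

#: Max tokens allowed between the end of a cue and the negated target.
NEGATION_REACH = 3


@dataclass(frozen=True)
class SeverityMention:
    """One textual severity finding inside a trigger window."""

    note_id: str
    trigger: str
    severity_term: str
    severity: str
    trigger_start: int  # character offsets into the note text
    trigger_end: int
    severity_start: int
    severity_end: int
    trigger_index: int  # token index of the trigger's first token
    severity_index: int  # token index of the severity phrase's first token
    window: TokenWindow


def _char_span(seq: TokenSequence, m: TriggerMatch):
    return seq.tokens[m.start].start, seq.tokens[m.end - 1].end


def _negated(target: TriggerMatch, cues: List[TriggerMatch]) -> bool:
    for c in cues:
        gap = target.start - c.end
        if 0 <= gap < NEGATION_REACH:
            return True
    return False


def note_has_adrd_flag(
    note: NoteDocument,
    lexicon: TermLexicon,
    extended_delimiters: bool = False,
) -> bool:
    """True iff any ADRD trigger phrase occurs in the note text."""
    seq = tokenize(note.text, extended_delimiters)
    return bool(find_triggers(seq, lexicon.adrd_triggers))


def extract_severity_mentions(
    note: NoteDocument,
    lexicon: TermLexicon,
    *,
    handle_negation: bool = False,
    extended_delimiters: bool = False,
    seq: Optional[TokenSequence] = None,
) -> List[SeverityMention]:
    """All severity keywords found within (-5, 5) tokens of an ADRD trigger.

    One mention per (trigger occurrence, severity occurrence) pair, with
    duplicate character-offset pairs emitted once; a severity phrase in
    the overlap of two trigger windows is reported once per trigger.
    """
    if seq is None:
        seq = tokenize(note.text, extended_delimiters)
    triggers = find_triggers(seq, lexicon.adrd_triggers)
    if not triggers:
        return []
    severities = find_triggers(seq, lexicon.all_severity_phrases)
    if not severities:
        return []
    exclusions = (
        find_triggers(seq, lexicon.exclusion_phrases)
        if lexicon.exclusion_phrases
        else []
    )
    cues = find_triggers(seq, NEGATION_CUES) if handle_negation else []

    def excluded(m: TriggerMatch) -> bool:
        return any(e.start <= m.start and m.end <= e.end for e in exclusions)

    out: List[SeverityMention] = []
    seen = set()
    for trig in triggers:
        win = window_around_match(seq, trig, *TEXT_WINDOW)
        if excluded(trig) or (handle_negation and _negated(trig, cues)):
            continue
        for sev in severities:
            if sev.start < win.start or sev.end > win.stop:
                continue
            if excluded(sev) or (handle_negation and _negated(sev, cues)):
                continue
            t0, t1 = _char_span(seq, trig)
            s0, s1 = _char_span(seq, sev)
            key = (t0, s0)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                SeverityMention(
                    note_id=note.note_id,
                    trigger=trig.phrase,
                    severity_term=sev.phrase,
                    severity=lexicon.severity_class_of(sev.phrase),
                    trigger_start=t0,
                    trigger_end=t1,
                    severity_start=s0,
                    severity_end=s1,
                    trigger_index=trig.start,
                    severity_index=sev.start,
                    window=win,
                )
            )
    return out
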