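"""The cognitive-score branch: MMSE/MoCA triggers and score regexes.

Each MMSE/MoCA trigger occurrence anchors a (-10, 10) token window that
is scanned for score candidates in three documented shapes:

``fraction_of_30``
    an integer written over a denominator of exactly 30 (``24/30``,
    ``scored 19/30``, the range form ``26-30/30`` contributing only the
    ``/30``-anchored integer).  ``N/M`` with another denominator is never
    a score: if both parts are calendar-plausible (each <= 31) the token
    is rejected as date-like (``8/22``), otherwise it is surfaced as an
    out-of-bounds candidate so that human-error reports such as
    ``MMSE 36/50`` are flagged invalid rather than silently dropped.
``itemized_total``
    MoCA only — the integer following the literal bigram "total score",
    searched up to 50 tokens after the trigger because itemized listings
    push the total far beyond the base window.
``bare_integer``
    a standalone integer 0-30 anywhere in the window.

Priority is fraction_of_30 > itemized_total > bare_integer (least
ambiguous first); within a tier the candidate nearest the trigger wins,
leftmost on ties.  A selected value outside [0, 30] yields a mention
with ``valid=False`` and no severity class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional

from .lexicon import CutoffTable, TermLexicon, SCORE_CEILING, SCORE_FLOOR
from .notes import NoteDocument
from .textproc import (
    TokenSequence,
    TokenWindow,
    TriggerMatch,
    find_triggers,
    tokenize,
    window_around_match,
)

#: Tokens before and after the test trigger in the score window.
SCORE_WINDOW = (10, 10)

#: Itemized-total search reach (tokens after the trigger), MoCA only.
ITEMIZED_REACH = 50

#: Largest day-of-month; an N/M token with both parts <= this is date-like.
CALENDAR_MAX = 31

FORMAT_VARIANTS = ("fraction_of_30", "bare_integer", "itemized_total")
_TIER = {"fraction_of_30": 0, "itemized_total": 1, "bare_integer": 2}

_FRACTION_30 = re.compile(r"(?:\d{1,3}[-–])?(\d{1,3})/30")
_FRACTION_ANY = re.compile(r"(\d{1,3})/(\d{1,3})")
_DATE_FULL = re.compile(r"\d{1,4}(?:/\d{1,4}){2,}")
_INT = re.compile(r"\d{1,3}")
_NUM_OPEN = re.compile(r"(?:\d{1,3}[-–])?(\d{1,3})/?")


@dataclass(frozen=True)
class ScoreCandidate:
    """A numeric token considered as a test score."""

    value: int
    variant: str
    token_start: int  # token index of the first token of the match
    token_stop: int  # exclusive
    distance: int  # token distance to the trigger span

    @property
    def tier(self) -> int:
        return _TIER[self.variant]


@dataclass(frozen=True)
class ScoreMention:
    """The score selected for one MMSE/MoCA trigger occurrence."""

    note_id: str
    test_name: str
    raw: str
    value: int
    format_variant: str
    valid: bool
    severity: Optional[str]
    start: int  # character offsets of the matched score text
    end: int
    trigger_start: int
    trigger_end: int


def _distance(i: int, j: int, a0: int, a1: int) -> int:
    """Token distance of span [i, j) from the trigger span [a0, a1)."""
    if j <= a0:
        return a0 - (j - 1)
    if i >= a1:
        return i - (a1 - 1)
    return 0


def _fraction_at(lowers, i: int):
    """A ``/30`` fraction starting at token ``i`` -> (value, span_len).

    Handles the atomic token ``N/30`` plus split variants ``N / 30``,
    ``N/ 30`` and ``N /30`` produced by stray whitespace around the slash.
    """
    t = lowers[i]
    m = _FRACTION_30.fullmatch(t)
    if m:
        return int(m.group(1)), 1
    m = _NUM_OPEN.fullmatch(t)
    if m:
        rest = lowers[i + 1 : i + 3]
        if t.endswith("/") and rest[:1] == ("30",):
            return int(m.group(1)), 2
        if not t.endswith("/") and rest[:1] == ("/30",):
            return int(m.group(1)), 2
        if not t.endswith("/") and tuple(rest) == ("/", "30"):
            return int(m.group(1)), 3
    return None


def parse_score_window(
    window: TokenWindow,
    test_name: str,
    trigger: Optional[TriggerMatch] = None,
    audit: Optional[list] = None,
) -> List[ScoreCandidate]:
    """All score candidates of a trigger window, best first.

    Returns candidates ordered by (priority tier, distance to trigger,
    position); rejected numeric tokens (date-like fractions, full dates,
    out-of-range bare integers) are appended to ``audit`` when given.
    """
    seq = window.seq
    lowers = seq.lowers
    if trigger is None:
        trigger = TriggerMatch(window.anchor, 1, lowers[window.anchor])
    a0, a1 = trigger.start, trigger.end
    trig_tokens = set(range(a0, a1))

    def log(reason, i, j):
        if audit is not None:
            audit.append(
                {
                    "reason": reason,
                    "test": test_name,
                    "token": seq.text[seq.tokens[i].start : seq.tokens[j - 1].end],
                    "char_start": seq.tokens[i].start,
                }
            )

    candidates: List[ScoreCandidate] = []
    claimed: set = set()

    # Itemized total: "total score N", MoCA only, widened search span.
    if test_name == "MoCA":
        stop = min(len(seq), a1 + ITEMIZED_REACH + 1)
        for i in range(window.start, stop - 2):
            if (
                lowers[i] == "total"
                and lowers[i + 1] == "score"
                and _INT.fullmatch(lowers[i + 2])
            ):
                candidates.append(
                    ScoreCandidate(
                        value=int(lowers[i + 2]),
                        variant="itemized_total",
                        token_start=i + 2,
                        token_stop=i + 3,
                        distance=_distance(i + 2, i + 3, a0, a1),
                    )
                )
                claimed.add(i + 2)

    i = window.start
    while i < window.stop:
        if i in trig_tokens or i in claimed:
            i += 1
            continue
        t = lowers[i]
        frac = _fraction_at(lowers, i)
        if frac is not None:
            value, span = frac
            candidates.append(
                ScoreCandidate(
                    value=value,
                    variant="fraction_of_30",
                    token_start=i,
                    token_stop=i + span,
                    distance=_distance(i, i + span, a0, a1),
                )
            )
            i += span
            continue
        if _DATE_FULL.fullmatch(t):
            log("date_like", i, i + 1)
            i += 1
            continue
        m = _FRACTION_ANY.fullmatch(t)
        if m:
            n, d = int(m.group(1)), int(m.group(2))
            if n <= CALENDAR_MAX and d <= CALENDAR_MAX:
                log("date_like", i, i + 1)
            else:
                # Calendar-impossible fraction: surface as out-of-bounds.
                candidates.append(
                    ScoreCandidate(
                        value=n,
                        variant="fraction_of_30",
                        token_start=i,
                        token_stop=i + 1,
                        distance=_distance(i, i + 1, a0, a1),
                    )
                )
                log("malformed_fraction", i, i + 1)
            i += 1
            continue
        if _INT.fullmatch(t):
            v = int(t)
            if SCORE_FLOOR <= v <= SCORE_CEILING:
                candidates.append(
                    ScoreCandidate(
                        value=v,
                        variant="bare_integer",
                        token_start=i,
                        token_stop=i + 1,
                        distance=_distance(i, i + 1, a0, a1),
                    )
                )
            else:
                log("bare_out_of_range", i, i + 1)
        i += 1

    candidates.sort(key=lambda c: (c.tier, c.distance, c.token_start))
    return candidates


def score_to_severity(test_name: str, value: int, cutoffs: CutoffTable) -> str:
    """Severity class of an in-range score per the cutoff bands."""
    return cutoffs.classify(test_name, value)


def extract_score_mentions(
    note: NoteDocument,
    lexicon: TermLexicon,
    cutoffs: CutoffTable,
    *,
    extended_delimiters: bool = False,
    audit: Optional[list] = None,
    seq: Optional[TokenSequence] = None,
) -> List[ScoreMention]:
    """At most one :class:`ScoreMention` per MMSE/MoCA trigger occurrence.

    The best candidate of each trigger window is selected; out-of-bounds
    values yield ``valid=False`` mentions with no severity class and an
    audit entry.  Windows with several same-tier candidates are logged as
    ambiguous.
    """
    if seq is None:
        seq = tokenize(note.text, extended_delimiters)
    out: List[ScoreMention] = []
    for test_name in sorted(lexicon.test_triggers):
        for trig in find_triggers(seq, lexicon.test_triggers[test_name]):
            win = window_around_match(seq, trig, *SCORE_WINDOW)
            cands = parse_score_window(win, test_name, trigger=trig, audit=audit)
            if not cands:
                continue
            top = cands[0]
            if audit is not None and sum(c.tier == top.tier for c in cands) > 1:
                audit.append(
                    {
                        "reason": "ambiguous_candidates",
                        "test": test_name,
                        "note_id": note.note_id,
                        "values": [c.value for c in cands if c.tier == top.tier],
                    }
                )
            valid = SCORE_FLOOR <= top.value <= SCORE_CEILING
            if not valid and audit is not None:
                audit.append(
                    {
                        "reason": "score_out_of_bounds",
                        "test": test_name,
                        "note_id": note.note_id,
                        "value": top.value,
                    }
                )
            c0 = seq.tokens[top.token_start].start
            c1 = seq.tokens[top.token_stop - 1].end
            t0 = seq.tokens[trig.start].start
            t1 = seq.tokens[trig.end - 1].end
            out.append(
                ScoreMention(
                    note_id=note.note_id,
                    test_name=test_name,
                    raw=seq.text[c0:c1],
                    value=top.value,
                    format_variant=top.variant,
                    valid=valid,
                    severity=(
                        score_to_severity(test_name, top.value, cutoffs)
                        if valid
                        else None
                    ),
                    start=c0,
                    end=c1,
                    trigger_start=t0,
                    trigger_end=t1,
                )
            )
    return out
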