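"""Cognitive-score branch: regex formats, candidate priority, validity."""

import re

import numpy as np
import pytest

from adrdnlp import (
    NoteDocument,
    extract_score_mentions,
    parse_score_window,
    score_to_severity,
    tokenize,
)
from adrdnlp.scores import SCORE_WINDOW
from adrdnlp.textproc import TriggerMatch, window_around_match

ITEMIZED = (
    "MoCA XX/XX/20XX trails 1 cube 1 clock 2 naming 3 digit span 1 letter a 1 "
    "serial 7s 3 sentence repetition 2 fluency 1 abstraction 2 orientation 6 "
    "memory 0 education level 0 total score 23"
)


def note(text):
    return NoteDocument(patient_id="p1", note_id="n1", text=text)


def mentions(text, lexicon, cutoffs, **kw):
    return extract_score_mentions(note(text), lexicon, cutoffs, **kw)


def test_canonical_fraction(lexicon, cutoffs):
    (m,) = mentions("mmse was 24/30 today", lexicon, cutoffs)
    assert (m.test_name, m.value, m.format_variant, m.valid) == (
        "MMSE",
        24,
        "fraction_of_30",
        True,
    )
    assert m.severity == "mild"
    assert m.raw == "24/30"


def test_itemized_moca_total_beyond_base_window(lexicon, cutoffs):
    (m,) = mentions(ITEMIZED, lexicon, cutoffs)
    assert (m.test_name, m.value, m.format_variant, m.valid) == (
        "MoCA",
        23,
        "itemized_total",
        True,
    )


def test_out_of_bounds_fraction_flagged_invalid(lexicon, cutoffs):
    (m,) = mentions("MMSE 36/50", lexicon, cutoffs)
    assert m.valid is False
    assert m.value == 36
    assert m.severity is None


def test_date_tokens_are_never_candidates(lexicon, cutoffs):
    text = "Montreal Cognitive Assessment by on 8/22 (scored 19/30, normal is 26-30/30)"
    audit = []
    (m,) = mentions(text, lexicon, cutoffs, audit=audit)
    assert (m.value, m.format_variant, m.valid) == (19, "fraction_of_30", True)
    assert any(a["reason"] == "date_like" and a["token"] == "8/22" for a in audit)
    assert any(a["reason"] == "ambiguous_candidates" for a in audit)


def test_range_fraction_contributes_only_the_anchored_integer(lexicon, cutoffs):
    (m,) = mentions("moca scored 26-30/30 today", lexicon, cutoffs)
    assert m.value == 30


def test_fraction_with_whitespace_around_slash(lexicon, cutoffs):
    for text in ("mmse 24 / 30", "mmse 24/ 30", "mmse 24 /30"):
        (m,) = mentions(text, lexicon, cutoffs)
        assert (m.value, m.format_variant) == (24, "fraction_of_30"), text


def test_bare_integer_and_empty_windows(lexicon, cutoffs):
    (m,) = mentions("moca was 22 per therapy note", lexicon, cutoffs)
    assert (m.value, m.format_variant, m.severity) == (22, "bare_integer", "mild")
    assert mentions("mmse deferred due to acuity", lexicon, cutoffs) == []


def test_full_dates_with_year_rejected(lexicon, cutoffs):
    audit = []
    assert mentions("moca on 10/12/2019 deferred", lexicon, cutoffs, audit=audit) == []
    assert any(a["reason"] == "date_like" for a in audit)


def test_one_mention_per_trigger_occurrence(lexicon, cutoffs):
    got = mentions("mmse 24/30 repeated later mmse 22/30", lexicon, cutoffs)
    assert [m.value for m in got] == [24, 22]


@pytest.mark.parametrize(
    "test, value, expected",
    [
        ("MMSE", 15, "moderate_severe"),
        ("MoCA", 23, "mild"),
        ("MMSE", 21, "mild"),
        ("MoCA", 17, "moderate_severe"),
    ],
)
def test_score_to_severity_bands(cutoffs, test, value, expected):
    assert score_to_severity(test, value, cutoffs) == expected


def test_score_to_severity_bounds_error(cutoffs):
    with pytest.raises(ValueError):
        score_to_severity("MMSE", 36, cutoffs)


def test_valid_mentions_reproduce_cutoff_class(lexicon, cutoffs):
    rng = np.random.default_rng(3)
    for _ in range(100):
        v = int(rng.integers(0, 31))
        test = "mmse" if rng.random() < 0.5 else "moca"
        (m,) = mentions(f"{test} score {v}/30 today", lexicon, cutoffs)
        assert m.valid
        assert m.severity == cutoffs.classify(m.test_name, m.value)


def date_fuzz_strings(rng, k):
    for _ in range(k):
        yield f"{rng.integers(1, 13)}/{rng.integers(1, 29)}"


def test_random_dates_never_become_candidates(lexicon, cutoffs):
    rng = np.random.default_rng(11)
    for d in date_fuzz_strings(rng, 300):
        if d.endswith("/30"):
            continue  # a /30 denominator IS the score format
        got = mentions(f"moca follow-up on {d} next visit", lexicon, cutoffs)
        assert got == [], d


def oracle_candidates(words, anchor_span, test):
    """Independent re-statement of the tier/nearest/leftmost rules."""
    a0, a1 = anchor_span
    cands = []
    claimed = set()
    if test == "MoCA":
        for i in range(max(0, a0 - 10), len(words) - 2):
            if (
                words[i] == "total"
                and words[i + 1] == "score"
                and re.fullmatch(r"\d{1,3}", words[i + 2])
                and i + 2 <= a1 + 50
            ):
                cands.append((1, i + 2, int(words[i + 2]), "itemized_total"))
                claimed.add(i + 2)
    lo, hi = max(0, a0 - 10), min(len(words), a1 + 10)
    for i in range(lo, hi):
        if i in claimed or a0 <= i < a1:
            continue
        w = words[i]
        m = re.fullmatch(r"(?:\d{1,3}-)?(\d{1,3})/30", w)
        if m:
            cands.append((0, i, int(m.group(1)), "fraction_of_30"))
            continue
        m = re.fullmatch(r"(\d{1,3})/(\d{1,3})", w)
        if m:
            n, d = int(m.group(1)), int(m.group(2))
            if n > 31 or d > 31:
                cands.append((0, i, n, "fraction_of_30"))
            continue
        if re.fullmatch(r"\d{1,3}", w) and 0 <= int(w) <= 30:
            cands.append((2, i, int(w), "bare_integer"))

    def dist(i):
        return a0 - i if i < a0 else (i - (a1 - 1) if i >= a1 else 0)

    cands.sort(key=lambda c: (c[0], dist(c[1]), c[1]))
    return [(v, var, i) for _, i, v, var in cands]


def test_candidate_selection_matches_brute_force_oracle():
    rng = np.random.default_rng(23)
    vocab = ["clinic", "19/30", "24/30", "8/22", "36/50", "12", "7", "45",
             "total", "score", "23", "note", "26-30/30", "stable"]
    for _ in range(400):
        words = ["moca"] + list(rng.choice(vocab, size=rng.integers(0, 20)))
        rng.shuffle(words)
        anchor = words.index("moca")
        seq = tokenize(" ".join(words))
        trig = TriggerMatch(anchor, 1, "moca")
        win = window_around_match(seq, trig, *SCORE_WINDOW)
        got = [
            (c.value, c.variant, c.token_start)
            for c in parse_score_window(win, "MoCA", trigger=trig)
        ]
        assert got == oracle_candidates(words, (anchor, anchor + 1), "MoCA"), words
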