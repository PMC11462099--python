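"""Tokenization, trigger-phrase matching, and token windows.

The whole pipeline operates on whitespace-delimited tokens of the raw
note text.  ``\\r\\n`` runs and all other whitespace act as delimiters;
punctuation hugging a word is peeled off into its own token so that
``dementia.`` still matches the trigger ``dementia``, while slash
patterns such as ``24/30`` or ``8/22`` stay atomic for the score regex.
Matching is case-insensitive via a lowercased shadow of each token;
character offsets always refer to the original text (0-based,
end-exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, NamedTuple

import re

#: Characters peeled off token edges into standalone punctuation tokens.
PUNCT_CHARS = ".,;:!?()[]{}<>\"'“”‘’"

#: Extra in-token delimiters honoured in extended-delimiter mode.
EXTENDED_DELIMS = ";,:"

_NONSPACE = re.compile(r"\S+")


class Token(NamedTuple):
    surface: str
    start: int
    end: int

    @property
    def lower(self) -> str:
        return self.surface.lower()


@dataclass(frozen=True)
class TokenSequence:
    """Ordered tokens of one note with offsets into the source text."""

    text: str
    tokens: tuple

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    def __iter__(self):
        return iter(self.tokens)

    @property
    def lowers(self) -> tuple:
        return tuple(t.lower for t in self.tokens)


class TriggerMatch(NamedTuple):
    """A phrase occurrence: ``length`` consecutive tokens from ``start``."""

    start: int
    length: int
    phrase: str

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class TokenWindow:
    """A contiguous token span around an anchor token.

    ``start``/``stop`` are indices into the parent sequence; the anchor
    sits at relative position 0 and truncation happens only at the
    sequence boundaries.
    """

    seq: TokenSequence
    start: int
    stop: int
    anchor: int

    def __post_init__(self):
        if not (0 <= self.start <= self.anchor < self.stop <= len(self.seq)):
            raise IndexError(
                f"window [{self.start}, {self.stop}) with anchor "
                f"{self.anchor} invalid for sequence of {len(self.seq)} tokens"
            )

    @property
    def tokens(self) -> tuple:
        return self.seq.tokens[self.start : self.stop]

    @property
    def relative_span(self):
        return (self.anchor - self.start, self.stop - 1 - self.anchor)

    def __len__(self) -> int:
        return self.stop - self.start


def _emit_core(text: str, i: int, j: int, out: list, extended: bool) -> None:
    if not extended:
        out.append(Token(text[i:j], i, j))
        return
    k = i
    for m in re.finditer(f"[{EXTENDED_DELIMS}]", text[i:j]):
        d = i + m.start()
        if k < d:
            out.append(Token(text[k:d], k, d))
        out.append(Token(text[d : d + 1], d, d + 1))
        k = d + 1
    if k < j:
        out.append(Token(text[k:j], k, j))


def tokenize(text: str, extended_delimiters: bool = False) -> TokenSequence:
    """Split note text into tokens on whitespace runs.

    Leading/trailing punctuation of each chunk becomes separate one-char
    tokens; the chunk core is kept whole (slash patterns stay atomic).
    In extended-delimiter mode ``;`` ``,`` ``:`` inside a core also split.
    """
    out: List[Token] = []
    for m in _NONSPACE.finditer(text):
        i, j = m.start(), m.end()
        lead = []
        while i < j and text[i] in PUNCT_CHARS:
            lead.append(Token(text[i], i, i + 1))
            i += 1
        trail = []
        while j > i and text[j - 1] in PUNCT_CHARS:
            trail.append(Token(text[j - 1], j - 1, j))
            j -= 1
        out.extend(lead)
        if i < j:
            _emit_core(text, i, j, out, extended_delimiters)
        out.extend(reversed(trail))
    return TokenSequence(text=text, tokens=tuple(out))


def phrase_tokens(phrase: str) -> tuple:
    """Lowercased token surfaces of a lexicon phrase (same tokenizer)."""
    return tuple(t.lower for t in tokenize(phrase).tokens)


def find_triggers(seq: TokenSequence, phrases: Iterable[str]) -> List[TriggerMatch]:
    """Every case-insensitive occurrence of every phrase, in document order.

    Multi-token phrases must appear as consecutive tokens.  Overlapping
    occurrences of distinct phrases are all reported; ties at the same
    start position list the longer phrase first.
    """
    lowers = list(seq.lowers)
    by_first: dict = {}
    for p in phrases:
        toks = phrase_tokens(p)
        if toks:
            by_first.setdefault(toks[0], []).append((toks, p))
    matches: List[TriggerMatch] = []
    for i, w in enumerate(lowers):
        for toks, p in by_first.get(w, ()):
            if lowers[i : i + len(toks)] == list(toks):
                matches.append(TriggerMatch(i, len(toks), p))
    matches.sort(key=lambda m: (m.start, -m.length, m.phrase))
    return matches


def extract_window(
    seq: TokenSequence, anchor: int, before: int, after: int
) -> TokenWindow:
    """Up to ``before + after + 1`` tokens centred on ``anchor``.

    Truncated at the sequence boundaries; the anchor token is always
    contained.  Raises ``IndexError`` for an out-of-range anchor.
    """
    if not 0 <= anchor < len(seq):
        raise IndexError(f"anchor {anchor} out of range for {len(seq)} tokens")
    return TokenWindow(
        seq=seq,
        start=max(0, anchor - before),
        stop=min(len(seq), anchor + after + 1),
        anchor=anchor,
    )


def window_around_match(
    seq: TokenSequence, match: TriggerMatch, before: int, after: int
) -> TokenWindow:
    """Window spanning ``before`` tokens left of a (possibly multi-token)
    phrase match and ``after`` tokens right of it."""
    return extract_window(
        seq, match.start, before, after + match.length - 1
    )
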