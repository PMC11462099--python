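"""Term lists and score-cutoff tables driving the extraction rules.

Three vocabularies steer the pipeline: ADRD trigger phrases (anchor the
severity-text search), severity keywords grouped into the two documented
classes (``mild`` and ``moderate_severe``), and cognitive-test trigger
phrases for MMSE and MoCA.  A cutoff table maps a valid test score
(0-30 points) to a severity class.  All four are plain YAML files so a
health system can swap in its own vocabulary without touching code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

SEVERITY_CLASSES = ("mild", "moderate_severe")
TEST_NAMES = ("MMSE", "MoCA")
SCORE_FLOOR = 0
SCORE_CEILING = 30


class LexiconError(ValueError):
    """A lexicon or cutoff file violates its schema or an invariant."""


def normalize_phrase(phrase: str) -> str:
    """Lowercase and collapse internal whitespace of a lexicon phrase."""
    return re.sub(r"\s+", " ", phrase.strip().lower())


def _norm_set(items, where: str) -> frozenset:
    out = set()
    for p in items or []:
        if not isinstance(p, str) or not p.strip():
            raise LexiconError(f"{where}: empty or non-string phrase {p!r}")
        out.add(normalize_phrase(p))
    return frozenset(out)


@dataclass(frozen=True)
class TermLexicon:
    """The three term lists plus optional exclusion phrases.

    All phrases are stored lowercase with collapsed whitespace.  A phrase
    may appear in at most one severity class.
    """

    adrd_triggers: frozenset
    severity_terms: Mapping[str, frozenset]
    test_triggers: Mapping[str, frozenset]
    exclusion_phrases: frozenset = frozenset()

    def __post_init__(self):
        if not self.adrd_triggers:
            raise LexiconError("adrd_triggers is empty")
        bad = set(self.severity_terms) - set(SEVERITY_CLASSES)
        if bad:
            raise LexiconError(f"unknown severity class(es): {sorted(bad)}")
        seen: dict = {}
        for cls in SEVERITY_CLASSES:
            for p in self.severity_terms.get(cls, ()):  # pragma: no branch
                if p in seen and seen[p] != cls:
                    raise LexiconError(
                        f"severity phrase {p!r} listed under both "
                        f"{seen[p]!r} and {cls!r}"
                    )
                seen[p] = cls
        for t in TEST_NAMES:
            if not self.test_triggers.get(t):
                raise LexiconError(f"test_triggers missing entries for {t}")
        for group in (
            self.adrd_triggers,
            *self.severity_terms.values(),
            *self.test_triggers.values(),
            self.exclusion_phrases,
        ):
            for p in group:
                if not p or p != normalize_phrase(p):
                    raise LexiconError(f"phrase {p!r} is not normalized")

    def severity_class_of(self, phrase: str) -> str:
        for cls in SEVERITY_CLASSES:
            if phrase in self.severity_terms.get(cls, ()):
                return cls
        raise KeyError(phrase)

    @property
    def all_severity_phrases(self) -> frozenset:
        out: set = set()
        for terms in self.severity_terms.values():
            out |= terms
        return frozenset(out)

    def to_dict(self) -> dict:
        return {
            "adrd_triggers": sorted(self.adrd_triggers),
            "severity_terms": {
                cls: sorted(self.severity_terms.get(cls, ()))
                for cls in SEVERITY_CLASSES
            },
            "test_triggers": {
                t: sorted(self.test_triggers.get(t, ())) for t in TEST_NAMES
            },
            "exclusion_phrases": sorted(self.exclusion_phrases),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "TermLexicon":
        if not isinstance(data, Mapping):
            raise LexiconError("lexicon file must contain a mapping")
        sev = data.get("severity_terms") or {}
        if not isinstance(sev, Mapping):
            raise LexiconError("severity_terms must be a mapping")
        tests = data.get("test_triggers") or {}
        if not isinstance(tests, Mapping):
            raise LexiconError("test_triggers must be a mapping")
        return cls(
            adrd_triggers=_norm_set(data.get("adrd_triggers"), "adrd_triggers"),
            severity_terms={
                k: _norm_set(v, f"severity_terms[{k}]") for k, v in sev.items()
            },
            test_triggers={
                k: _norm_set(v, f"test_triggers[{k}]") for k, v in tests.items()
            },
            exclusion_phrases=_norm_set(
                data.get("exclusion_phrases"), "exclusion_phrases"
            ),
        )


@dataclass(frozen=True)
class CutoffTable:
    """Per-test severity bands tiling the integer score range [0, 30].

    ``bands`` maps a test name to a tuple of ``(min, max, class)`` triples
    with inclusive bounds; the bands of a test must be disjoint and cover
    every integer score exactly once.
    """

    bands: Mapping[str, tuple]
    score_floor: int = SCORE_FLOOR
    score_ceiling: int = SCORE_CEILING

    def __post_init__(self):
        for test in TEST_NAMES:
            if test not in self.bands:
                raise LexiconError(f"cutoff table missing test {test}")
        for test, bands in self.bands.items():
            owners: dict = {}
            for lo, hi, cls in bands:
                if cls not in SEVERITY_CLASSES:
                    raise LexiconError(
                        f"{test}: unknown severity class {cls!r}"
                    )
                if not (isinstance(lo, int) and isinstance(hi, int)) or lo > hi:
                    raise LexiconError(f"{test}: malformed band [{lo}, {hi}]")
                for s in range(lo, hi + 1):
                    if s in owners:
                        raise LexiconError(
                            f"{test}: score {s} covered by more than one band"
                        )
                    owners[s] = cls
            for s in range(self.score_floor, self.score_ceiling + 1):
                if s not in owners:
                    raise LexiconError(f"{test}: score {s} not covered by any band")
            extra = set(owners) - set(
                range(self.score_floor, self.score_ceiling + 1)
            )
            if extra:
                raise LexiconError(
                    f"{test}: band extends outside the score range "
                    f"(score {min(extra)})"
                )

    def classify(self, test_name: str, value: int) -> str:
        """Severity class of an in-range score; raises on out-of-range input."""
        if test_name not in self.bands:
            raise KeyError(test_name)
        if not self.score_floor <= value <= self.score_ceiling:
            raise ValueError(
                f"{test_name} score {value} outside "
                f"[{self.score_floor}, {self.score_ceiling}]"
            )
        for lo, hi, cls in self.bands[test_name]:
            if lo <= value <= hi:
                return cls
        raise AssertionError("unreachable: bands tile the range")  # pragma: no cover

    def to_dict(self) -> dict:
        return {
            test: [[lo, hi, cls] for lo, hi, cls in bands]
            for test, bands in sorted(self.bands.items())
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CutoffTable":
        if not isinstance(data, Mapping):
            raise LexiconError("cutoff file must contain a mapping")
        bands = {}
        for test, entries in data.items():
            parsed = []
            for entry in entries or []:
                if not isinstance(entry, (list, tuple)) or len(entry) != 3:
                    raise LexiconError(
                        f"{test}: band {entry!r} is not a [min, max, class] triple"
                    )
                lo, hi, c = entry
                parsed.append((lo, hi, str(c)))
            bands[str(test)] = tuple(parsed)
        return cls(bands=bands)


def _load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        try:
            return yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise LexiconError(f"{path}: invalid YAML: {exc}") from exc


def load_lexicon(path) -> TermLexicon:
    """Load and validate a term lexicon from a YAML file."""
    return TermLexicon.from_dict(_load_yaml(path))


def load_cutoffs(path) -> CutoffTable:
    """Load and validate a score cutoff table from a YAML file."""
    return CutoffTable.from_dict(_load_yaml(path))


def save_lexicon(lexicon: TermLexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(lexicon.to_dict(), fh, sort_keys=False)


def save_cutoffs(cutoffs: CutoffTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cutoffs.to_dict(), fh, sort_keys=False)


def load_default_lexicon() -> TermLexicon:
    """The bundled default term lists (site-replaceable stand-ins)."""
    ref = resources.files("adrdnlp.data").joinpath("default_lexicon.yaml")
    return TermLexicon.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


def load_default_cutoffs() -> CutoffTable:
    """The bundled default MMSE/MoCA staging bands."""
    ref = resources.files("adrdnlp.data").joinpath("default_cutoffs.yaml")
    return CutoffTable.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
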