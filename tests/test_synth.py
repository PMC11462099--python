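"""Synthetic corpus generator: determinism, gold integrity, noise modes."""

import dataclasses
import json

import numpy as np
import pytest

from adrdnlp import (
    GenerationConfig,
    NoiseRates,
    NoteDocument,
    corpus_gold,
    extract_score_mentions,
    extract_severity_mentions,
    generate_corpus,
    inject_noise,
    resolve_cohort,
)
from adrdnlp.synth import NOISE_MODES, LabeledNote


def quiet(n_patients=30, seed=3, **kw):
    return GenerationConfig(
        n_patients=n_patients, seed=seed, noise=NoiseRates.zero(), **kw
    )


def serialize(notes):
    return json.dumps(
        [[ln.note.note_id, ln.note.text, ln.patient_severity] for ln in notes]
    )


def test_same_seed_gives_byte_identical_corpora():
    a = generate_corpus(quiet())
    b = generate_corpus(quiet())
    assert serialize(a) == serialize(b)
    c = generate_corpus(quiet(seed=4))
    assert serialize(a) != serialize(c)


def test_gold_offsets_index_generated_substrings():
    cfg = GenerationConfig(n_patients=40, seed=9)  # default (nonzero) noise
    for ln in generate_corpus(cfg):
        for ann in ln.annotations:
            assert ln.note.text[ann.start : ann.end] == ann.text


def test_gold_label_equals_resolver_output_when_noise_free(lexicon, cutoffs):
    notes = generate_corpus(quiet(n_patients=40, seed=21))
    results, _ = resolve_cohort([ln.note for ln in notes], lexicon, cutoffs)
    gold = {g.record_id: g for g in corpus_gold(notes)}
    for r in results:
        g = gold[r.patient_id]
        want = g.severity if g.has_severity_info else "undocumented"
        assert r.severity == want, r.patient_id


def test_documented_patients_get_plantable_evidence():
    notes = generate_corpus(quiet(n_patients=60, seed=2))
    by_patient = {}
    for ln in notes:
        by_patient.setdefault(ln.note.patient_id, []).append(ln)
    for pid, lns in by_patient.items():
        kinds = {a.kind for ln in lns for a in ln.annotations}
        if lns[0].patient_severity == "undocumented":
            assert kinds == set()
        else:
            assert kinds & {"severity_text", "score"}


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="prevalence"):
        GenerationConfig(prevalence=(0.5, 0.2, 0.2)).validate()
    with pytest.raises(ValueError, match="noise"):
        GenerationConfig(noise=NoiseRates(date_like_tokens=1.5)).validate()
    with pytest.raises(ValueError, match="notes_per_patient"):
        GenerationConfig(notes_per_patient=(0, 2)).validate()


def base_note(text="patient stable today. plan unchanged going forward"):
    return LabeledNote(
        note=NoteDocument("p0", "p0-n0", text),
        annotations=(),
        patient_severity="undocumented",
        patient_source="none",
    )


def test_unknown_noise_mode_rejected():
    with pytest.raises(ValueError, match="unknown noise mode"):
        inject_noise(base_note(), "typos", np.random.default_rng(0))


def test_out_of_bounds_noise_plants_invalid_score(lexicon, cutoffs):
    noisy = inject_noise(base_note(), "out_of_bounds_scores", np.random.default_rng(1))
    (ann,) = [a for a in noisy.annotations if a.kind == "score"]
    assert ann.value > 30 and ann.valid is False
    got = extract_score_mentions(noisy.note, lexicon, cutoffs)
    assert [m.valid for m in got] == [False]
    assert noisy.patient_severity == "undocumented"  # gold label unchanged


def test_negated_noise_creates_false_mention_by_default(lexicon):
    noisy = inject_noise(base_note(), "negated_mentions", np.random.default_rng(2))
    assert noisy.patient_severity == "undocumented"
    assert extract_severity_mentions(noisy.note, lexicon)  # the documented failure
    assert (
        extract_severity_mentions(noisy.note, lexicon, handle_negation=True) == []
    )


def test_mci_distractor_reads_as_mild_unless_excluded(lexicon):
    noisy = inject_noise(base_note(), "mci_distractors", np.random.default_rng(3))
    got = extract_severity_mentions(noisy.note, lexicon)
    assert got and all(m.severity == "mild" for m in got)
    excluding = dataclasses.replace(
        lexicon, exclusion_phrases=frozenset({"mild cognitive disorder"})
    )
    assert extract_severity_mentions(noisy.note, excluding) == []


def test_crlf_noise_inserts_carriage_returns_harmlessly(lexicon, cutoffs):
    src = generate_corpus(quiet(n_patients=4, seed=5))
    before = [ln.note for ln in src]
    after = []
    for ln in src:
        noisy = inject_noise(ln, "crlf_artifacts", np.random.default_rng(4))
        assert "\r\n\r\n" in noisy.note.text
        for ann in noisy.annotations:
            assert noisy.note.text[ann.start : ann.end] == ann.text
        after.append(noisy.note)
    res_a, _ = resolve_cohort(before, lexicon, cutoffs)
    res_b, _ = resolve_cohort(after, lexicon, cutoffs)
    assert [(r.patient_id, r.severity) for r in res_a] == [
        (r.patient_id, r.severity) for r in res_b
    ]


def test_missing_delimiter_noise_hides_planted_evidence(lexicon):
    notes = generate_corpus(quiet(n_patients=40, seed=13))
    fused = 0
    for ln in notes:
        if not any(a.kind == "severity_text" for a in ln.annotations):
            continue
        noisy = inject_noise(ln, "missing_delimiters", np.random.default_rng(6))
        (ann,) = [a for a in noisy.annotations if a.intent == "fused"]
        assert ann.extractable is False
        assert noisy.note.text[ann.start : ann.end] == ann.text
        before = extract_severity_mentions(ln.note, lexicon)
        after = extract_severity_mentions(noisy.note, lexicon)
        assert len(after) < len(before)
        fused += 1
    assert fused > 0


def test_zero_rate_modes_leave_notes_unchanged():
    a = generate_corpus(quiet(n_patients=25, seed=8))
    b = generate_corpus(
        GenerationConfig(n_patients=25, seed=8, noise=NoiseRates.zero())
    )
    assert serialize(a) == serialize(b)


def test_prevalence_within_three_binomial_se():
    cfg = quiet(n_patients=2000, seed=1, prevalence=(0.2293, 0.2087, 0.5620))
    gold = corpus_gold(generate_corpus(cfg))
    n = len(gold)
    observed = {
        "mild": sum(g.severity == "mild" for g in gold) / n,
        "moderate_severe": sum(g.severity == "moderate_severe" for g in gold) / n,
        "undocumented": sum(not g.has_severity_info for g in gold) / n,
    }
    for cls, p in zip(observed, cfg.prevalence):
        se = (p * (1 - p) / n) ** 0.5
        assert abs(observed[cls] - p) <= 3 * se, (cls, observed[cls])
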