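# Methods

## Problem and approach

Dementia severity ("mild" vs "moderate-to-severe") is clinically decisive —
current disease-modifying treatments target early-stage disease — yet it is
usually documented only in free-text clinician notes. `adrdnlp` stages
patients from those notes with deterministic, auditable rules rather than a
learned model: every label can be traced to a specific trigger word, window
and matched phrase. The package follows a two-branch design: severity
keywords near ADRD trigger terms, and MMSE/MoCA scores parsed from trigger
windows, combined by explicit precedence rules.

## Tokenization

Notes are split on runs of whitespace; `\r\n` artifacts act as ordinary
delimiters. Punctuation hugging a word (`dementia.`, `(scored`) is peeled
off the edges into standalone one-character tokens so trigger phrases still
match, while token cores are never split internally — this keeps `24/30`,
`8/22` and `26-30/30` atomic for the score regexes. Matching is
case-insensitive through a lowercased shadow; all reported offsets are
0-based, end-exclusive positions in the original text. An optional
extended-delimiter mode additionally splits cores on `;` `,` `:` for notes
that drop spaces (`indication:dementia`); it is off by default because
space-delimited text is the documented norm and the aggressive mode invites
false splits (e.g. numbers with thousands separators).

Because punctuation becomes tokens, windows measured in tokens "spend"
positions on punctuation. This is intentional: it makes the window a purely
mechanical contract, with no hidden linguistic judgment.

## Severity-text branch

Every occurrence of an ADRD trigger phrase anchors a window of 5 tokens on
each side (11 tokens for a one-token trigger; multi-token triggers keep 5
tokens of context on each side of the phrase). Every severity keyword whose
tokens lie wholly inside the window produces one mention; a keyword in the
overlap of two trigger windows is reported once per trigger (provenance is
preserved; patient-level resolution deduplicates). Windows are applied per
occurrence, not per unique term.

Two documented failure modes are reproduced on purpose:

- **No negation handling by default.** "negative for cognitive impairment"
  produces a mention. The opt-in negation mode suppresses a mention when a
  cue (`no`, `not`, `denies`, `without`, `negative for`, `no evidence of`)
  ends within 3 tokens before the trigger or the severity phrase.
- **MCI confusables.** "mild cognitive disorder" matches as a mild mention
  (the keyword matcher cannot distinguish mild *dementia* from the distinct
  MCI diagnosis). Listing the phrase under `exclusion_phrases` suppresses
  any mention whose trigger or severity phrase lies inside an occurrence of
  the excluded phrase.

## Cognitive-score branch

Each MMSE/MoCA trigger occurrence anchors a (−10, 10) token window. Score
candidates are collected in three tiers:

1. `fraction_of_30` — an integer over a denominator of exactly 30. Accepted
   variations: whitespace around the slash (`24 / 30`), and hyphenated
   ranges (`26-30/30`) contributing only the `/30`-anchored integer. A
   fraction `N/M` with `M ≠ 30` is *date-like* and rejected when both parts
   are calendar-plausible (≤ 31, e.g. `8/22`); when either part is
   calendar-impossible (`36/50`) the numerator is surfaced as an
   out-of-bounds candidate so data-entry errors are flagged rather than
   silently dropped. Full dates (`10/12/2019`) are always rejected.
2. `itemized_total` — MoCA only: the integer after the literal bigram
   "total score", searched from the window start up to 50 tokens after the
   trigger, because itemized subscore listings push the total far beyond
   the base window.
3. `bare_integer` — a standalone integer 0–30 in the window. Bare integers
   near date context words remain candidates (no reliable exclusion exists
   at the token level); ambiguity is logged for audit.

The best candidate wins by (tier, distance to trigger, leftmost). The
least-ambiguous-first tier order is a design choice: an explicit `/30` is
the strongest signal, a "total score" bigram the next, a bare integer the
weakest. Exactly one mention is emitted per trigger occurrence; a selected
value outside [0, 30] gives `valid=False` and no severity class. Valid
values map to classes through the cutoff table; any valid score counts as
documented severity (the default bands cover all of 0–30, so "normal-range"
scores land in the mild band — the bands are configuration, so a site can
carve out an "undocumented" policy by editing them).

Default bands (standard clinical staging, moderate and severe collapsed):
MMSE 21–30 mild, 0–20 moderate-severe; MoCA 18–30 mild, 0–17
moderate-severe. The bundled trigger/severity/test term lists are
documented defaults assembled from common ADRD terminology and ICD-9/10
synonyms — deliberately replaceable YAML, not a claim about any particular
health system's vocabulary.

## Patient-level resolution

All of a patient's notes contribute evidence regardless of date. Textual
mentions outrank scores even when discordant (providers stage severity on
more than the test result); within the winning source the more severe class
wins, on the progression rationale that the worse finding is the more
recent state. Invalid scores never count as severity information. Labels
are therefore one of `mild`, `moderate_severe`, `undocumented` with source
`text`, `score` or `none`.

## Evaluation harness

Two binary tasks: *info-presence* (positive = any severity documented) and
*severity* (restricted to records whose **gold** label is documented;
moderate-to-severe positive, mild negative; a gold-documented record the
pipeline leaves undocumented counts on the negative side). Metrics are exact
rationals internally — accuracy (TP+TN)/total, sensitivity TP/(TP+FN),
specificity TN/(TN+FP), F1 2·TP/(2·TP+FP+FN) — displayed with decimal
half-up rounding to 2 places; zero-denominator metrics are reported as
undefined, never 0, and values landing exactly on a rounding boundary are
flagged as borderline. `compare_with_reported` recomputes metrics from the
counts they accompany and flags disagreements, so internally inconsistent
published tables are surfaced rather than echoed. The evaluation unit is
whatever identifier the files carry (patient or visit record); the harness
is agnostic and says so in its report.

## Synthetic corpus generator

No real dementia notes can ship with the package, so the generator
fabricates template-based notes with exact gold annotations. Defaults are
fixed study conditions, not tuning knobs:

- cohort mix 22.93% mild / 20.87% moderate-severe / 56.20% undocumented;
- among documented patients, evidence mix 25% text-only / 23% score-only /
  52% both (derived from the documented counts of patients with explicit
  terms, with scores, and with only scores);
- score formats 50% fraction / 30% bare integer / 20% itemized (a chosen
  mix; the source material names the formats but not their frequencies);
- 1–3 notes per patient; six noise modes at rate 0.05 each by default.

Notes are assembled from sentence banks: header, fillers (no triggers,
severity words or digits), distractors (ADRD triggers with no severity
context — so undocumented patients are still *about* dementia), and planted
evidence sentences whose severity phrase sits within 5 tokens of a trigger
or whose score sits within 10 tokens of a test trigger in the configured
format. Evidence always carries the patient's gold class, so with all noise
rates at zero the resolver provably reproduces every gold label — the
round-trip property the acceptance tests assert.

The six noise modes replicate documented misclassification causes:
date-like slash tokens near a test trigger, out-of-bounds scores
(`mmse 36/50`), negated severity phrasing ("no evidence of advanced
dementia"), "mild cognitive disorder" confusables, `\r\n\r\n` runs, and
missing delimiters (the space after a planted finding is removed, fusing
tokens so the rules miss it; the gold annotation is marked fused). Gold
patient labels never change under noise — noise models documentation
artifacts, so every resulting misclassification is a reproducible algorithm
failure, which is what makes the modes useful.

Determinism: one integer seed; per-patient and per-note substreams are
derived by counter (`[seed, patient, note]`), so corpora are byte-identical
across runs and machines. Per-note noise decisions are drawn in a fixed
order *before* any injection, and injection randomness uses a separate
substream, so raising one noise rate enlarges the set of affected notes
without reshuffling anything else — this makes the monotone
specificity-loss property exact rather than statistical.

What the generator does **not** emulate: real discourse structure and
length (real records average ~900 words; generated notes are short),
misspellings, template boilerplate, medication lists, or cross-note
temporal structure. Passing tests therefore demonstrate rule correctness
and failure-mode behavior, not field performance on any health system's
notes.

## Numerical and scale choices

Problem sizes in the test suite were chosen to exercise every rule while
keeping the default run quick: round-trip cohorts of 40–50 patients,
prevalence recovery at 2,000 patients (3 binomial standard errors ≈ ±2.8
points for the mild class), and 1,000 randomized instances per brute-force
oracle comparison (windows, trigger matching, candidate selection, metric
identities). Rounding is decimal half-up on exact rationals, avoiding both
float representation artifacts and banker's-rounding surprises.

## Known limitations

Pure lexical matching: no coreference, no temporality ("dementia two years
ago"), no hypothetical contexts, no family-history filtering, no subscore
arithmetic for itemized MoCA components, no instruments beyond MMSE/MoCA.
The bundled vocabularies and cutoff bands are defaults to be reviewed
against local documentation practice before any substantive use.
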