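# Default term lists for ADRD severity extraction.
# Replace any section with site-specific vocabulary; phrases are matched
# case-insensitively on whitespace-delimited tokens.
adrd_triggers:
  - dementia
  - progressive dementia
  - dementia nos
  - senile dementia
  - presenile dementia
  - mixed dementia
  - alzheimer
  - alzheimers
  - alzheimer disease
  - alzheimer's disease
  - alzheimer dementia
  - alzheimer's dementia
  - alzheimer type dementia
  - vascular dementia
  - multi-infarct dementia
  - lewy body dementia
  - dementia with lewy bodies
  - lewy body disease
  - frontotemporal dementia
  - frontotemporal degeneration
  - pick disease
  - pick's disease
  - parkinson disease dementia
  - major neurocognitive disorder
  - neurocognitive disorder
  - cognitive impairment
  - cognitive impairments
  - cognitive deficit
  - cognitive deficits
  - cognitive decline
  - cognitive disorder
  - cognitive dysfunction
  - memory loss
  - memory impairment
  - memory deficit
  - amnestic disorder
  - cerebral degeneration
  - senile degeneration of brain
severity_terms:
  mild:
    - mild
    - early
    - early-stage
    - early stage
  moderate_severe:
    - moderate
    - severe
    - advanced
    - late-stage
    - end-stage
    - end stage
test_triggers:
  MMSE:
    - mmse
    - mini mental state examination
    - mini-mental state examination
    - mini mental state exam
    - mini mental status examination
    - mini-mental status exam
  MoCA:
    - moca
    - montreal cognitive assessment
exclusion_phrases: []
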