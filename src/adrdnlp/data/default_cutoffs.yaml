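# Default score-to-severity bands (points on the 0-30 scale of each test).
# Standard clinical staging bands with moderate and severe collapsed into a
# single moderate_severe class; swap in site-specific bands as needed.
# Bands are [min, max, class] with inclusive bounds and must tile 0..30.
MMSE:
  - [21, 30, mild]
  - [10, 20, moderate_severe]
  - [0, 9, moderate_severe]
MoCA:
  - [18, 30, mild]
  - [10, 17, moderate_severe]
  - [0, 9, moderate_severe]
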