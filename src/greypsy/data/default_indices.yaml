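version: 1
description: >
  Default six-index psychological evaluation system.  Full scores sum to
  200 so that the 100-point overall-score threshold is the midpoint of the
  measurement range.  Higher observations indicate a worse state; the three
  grey classes per index are good / ordinary / morbid.  Boundaries are at
  20/40/60/80 percent of each index's full score, placing the
  ordinary-class center at exactly half the full score.
indices:
  - name: anxiety
    full_score: 40
    boundaries: [8, 16, 24, 32]
  - name: depression
    full_score: 40
    boundaries: [8, 16, 24, 32]
  - name: sleep_quality
    full_score: 30
    boundaries: [6, 12, 18, 24]
  - name: disease_cognition
    full_score: 30
    boundaries: [6, 12, 18, 24]
  - name: social_support
    full_score: 30
    boundaries: [6, 12, 18, 24]
  - name: somatic_symptoms
    full_score: 30
    boundaries: [6, 12, 18, 24]
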