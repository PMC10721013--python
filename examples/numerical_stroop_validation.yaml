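# Unimpaired (low math-anxiety) model on the 144-pair numerical Stroop design.
parameters:
  seed: 2023
design:
  task: numerical
  stimulus_set: validation-144
  n_participants: 30
  conditions:
    - label: LMA
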