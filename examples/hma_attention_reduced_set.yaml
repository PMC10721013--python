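# Matched LMA / HMA attention study on the reduced 16-combination set.
# HMA scales the numerical task-demand activation to 95%.
parameters:
  seed: 2023
design:
  task: numerical
  stimulus_set: reduced-16
  n_participants: 30
  conditions:
    - label: LMA
    - label: HMA
      attention: {numerical: 0.95}
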