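# Physical Stroop: physical size is the relevant dimension, numerical size
# irrelevant; weights at the 17,000-trial checkpoint.
parameters:
  seed: 2023
design:
  task: physical
  stimulus_set: validation-144
  n_participants: 30
  conditions:
    - label: trained-17k
      checkpoint: 17000
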