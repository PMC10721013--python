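# Symbolic number comparison with reduced learning: the LMA model uses the
# 20,000-trial checkpoint, the HMA model the 18,000-trial checkpoint with
# attention to the numerical dimension reduced to 95%.
parameters:
  seed: 2023
design:
  task: comparison
  stimulus_set: pairs-72
  n_participants: 30
  conditions:
    - label: LMA-20k
      checkpoint: 20000
    - label: HMA-18k-attention
      checkpoint: 18000
      attention: {numerical: 0.95}
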