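# Census on the intact network, then attractor survival under silencing.
task: silence
connectome: {reference: true}
network: {mode: custom, G: 0.15, J_max: 0.42}
census:
  n_samples: 1000
  relax_time: 10.0
  dt: 0.001
  silenced_sets:
    - [24c]
    - [V2]
    - [STPr, 24c]
numerics: {seed: 0, noise: false}
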