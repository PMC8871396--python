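# One point of the counterstream-inhibitory-bias sweep; vary cib_scale
# (0 disables feedback inhibition entirely).
task: simulate
connectome: {reference: true}
network: {mode: distributed, cib_scale: 1.0}
protocol:
  events:
    - {area: V1, population: A, onset: 0.5, duration: 0.5, amplitude: 0.3}
numerics: {duration: 8.0, dt: 0.0005, seed: 0, noise: true}
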