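# Transient inactivation during the delay: 1 s inhibitory drive to the
# top area of a strongly distributed network.
task: simulate
connectome: {reference: true}
network: {mode: strongly-distributed}
protocol:
  events:
    - {area: V1, population: A, onset: 0.5, duration: 0.5, amplitude: 0.3}
    - {area: STPr, population: inhibitory, onset: 4.0, duration: 1.0, amplitude: 0.3}
numerics: {duration: 9.0, dt: 0.0005, seed: 0, noise: true}
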