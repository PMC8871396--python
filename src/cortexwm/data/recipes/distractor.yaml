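# Cue then equal-strength distractor four seconds later.
task: distractor
connectome: {reference: true}
network: {mode: strongly-distributed}
numerics: {dt: 0.0005, seed: 0, noise: true}
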