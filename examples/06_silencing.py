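"""Which lesions destroy distributed memories?

Re-relaxes every attractor of the intact network with selected areas
clamped off and reports the percentage that survive.
"""
import numpy as np
from cortexwm import (reference_connectome, build_network,
                      enumerate_attractors, silencing_survival)

bundle = reference_connectome()
net = build_network(bundle, mode="custom", G=0.03, J_max=0.47)
census = enumerate_attractors(net, n_samples=512, relax_time=10.0,
                              seed=0, dt=1e-3)
print(f"census: {census.n_attractors} attractors on the intact network")

top = net.areas[int(np.argmax(net.J_s))]
bottom = net.areas[int(np.argmin(net.J_s))]
sets = [[bottom], [top], [top, "8B"]]
surv = silencing_survival(net, census, sets)
for areas, pct in zip(sets, surv):
    print(f"silencing {', '.join(areas):14s}: {pct:5.1f}% of attractors survive")
print("\nsilencing the top of the hierarchy costs far more memories than "
      "silencing the bottom.")
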