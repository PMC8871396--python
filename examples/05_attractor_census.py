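"""Counting the network's distributed memory states.

Relaxes hundreds of random initial conditions (noise off), binarizes the
settled patterns and deduplicates them; repeated for several global
couplings G.
"""
import numpy as np
from cortexwm import (reference_connectome, build_network,
                      enumerate_attractors, participation_index,
                      size_rate_correlation)

bundle = reference_connectome()
print("G     attractors (J_max = 0.47)")
counts = []
for G in [0.0, 0.02, 0.03, 0.06, 0.10, 0.22]:
    net = build_network(bundle, mode="custom", G=G, J_max=0.47)
    c = enumerate_attractors(net, n_samples=256, relax_time=10.0,
                             seed=0, dt=1e-3)
    counts.append(c.n_attractors)
    print(f"{G:4.2f}  {c.n_attractors}")
print("-> an inverted-U: too little coupling sustains nothing, too much "
      "collapses everything onto one global pattern.\n")

net = build_network(bundle, mode="custom", G=0.03, J_max=0.47)
c = enumerate_attractors(net, n_samples=512, relax_time=10.0, seed=0, dt=1e-3)
pi = participation_index(c)
top = np.argsort(-pi)[:5]
print("areas most often part of an attractor:",
      ", ".join(f"{c.areas[i]} ({pi[i]:.2f})" for i in top))
print(f"size-rate correlation across {c.n_attractors} attractors: "
      f"{size_rate_correlation(c):.2f} (bigger attractors fire faster)")
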