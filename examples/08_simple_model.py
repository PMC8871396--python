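"""The minimal model: excitatory nodes on a coupling gradient.

Shows the first-order mean field R = phi((J+G)R + I), and how a
feedforward/feedback asymmetry lets only part of the gradient hold
memory.
"""
import numpy as np
from cortexwm import SimpleNetSpec, meanfield_solutions, count_bistable_areas
from cortexwm.simple import saturating_gradient

spec = SimpleNetSpec(J=np.full(30, 0.2))
for G in [0.1, 0.4]:
    sols = meanfield_solutions(spec.replace(G=G))
    desc = ", ".join(f"R = {r:.3f} ({'stable' if ok else 'unstable'})"
                     for r, ok in sols)
    print(f"G = {G}: {desc}")

Gs = np.linspace(0.0, 0.4, 9)
J = saturating_gradient(30, 0.21, 0.42)
sym = count_bistable_areas(SimpleNetSpec(J=J), Gs, relax_time=2.0, dt=1e-3)
asym = count_bistable_areas(SimpleNetSpec(J=J, ff_factor=1.15, fb_factor=0.6),
                            Gs, relax_time=2.0, dt=1e-3)
print("\nG grid:          ", np.round(Gs, 2).tolist())
print("bistable (sym):  ", sym.tolist())
print("bistable (asym): ", asym.tolist())
print("\nweakening feedback (asym) recruits the gradient gradually instead "
      "of all at once - the simple-model analogue of the counterstream bias.")
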