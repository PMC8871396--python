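"""Bifurcation structure of one isolated cortical area.

Scans the local self-coupling J_s (with the excitatory-to-inhibitory
coupling re-balanced at each value so the resting state never moves) and
reports where stimulus-selective memory states appear.
"""
import numpy as np
from cortexwm import (LocalCircuitParams, find_fixed_points,
                      critical_coupling_scan, compute_balance_constants,
                      balance_jie)

params = LocalCircuitParams()
constants = compute_balance_constants(params)
print(f"balance constants: J0 = {constants.J0:.4f} nA, "
      f"zeta = {constants.zeta:.4f} /nA, Z = {constants.Z:.4f}")

for J_s in [0.3213, 0.42, 0.48]:
    p = params.replace(J_s=J_s, J_IE=balance_jie(J_s, constants, params))
    stable = [fp for fp in find_fixed_points(p) if fp.stable]
    rates = ", ".join(f"({fp.r_A:.2f}, {fp.r_B:.2f})" for fp in stable)
    print(f"J_s = {J_s:.4f} nA: {len(stable)} stable fixed point(s) "
          f"with (r_A, r_B) = {rates} Hz")

jc = critical_coupling_scan(params)
print(f"\nbistability threshold: J_s = {jc:.4f} nA")
print("below it an area holds no memory on its own; the default gradient "
      "tops out at 0.42 nA, so every area needs the network to remember.")
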