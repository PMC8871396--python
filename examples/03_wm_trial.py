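"""A visual working-memory trial on the 30-area network.

A 0.5 s selective pulse to V1 leaves a distributed, stimulus-selective
delay pattern confined to association areas.
"""
import numpy as np
from cortexwm import (reference_connectome, build_network, run_wm_trial,
                      summarize_delay_activity)

net = build_network(reference_connectome(), mode="distributed")
res = run_wm_trial(net, duration=8.0, noise=False)
summ = summarize_delay_activity(res)

print(f"delay-active areas ({summ.n_active} of 30, threshold "
      f"{summ.threshold:.1f} Hz):")
for a in summ.rate_order[:summ.n_active]:
    i = summ.areas.index(a)
    print(f"  {a:7s} cued pool {summ.mean_rates[i]:6.1f} Hz   "
          f"selectivity {summ.selectivity[i]:6.1f} Hz")
iv1 = summ.areas.index("V1")
print(f"\nV1 (the cued area) falls back to {summ.mean_rates[iv1]:.2f} Hz: "
      "the memory lives in the association cortex, not where the cue arrived.")
ranked = np.sort(summ.mean_rates)[::-1]
print(f"rate gap between active and inactive areas: "
      f"{ranked[summ.n_active-1]:.1f} vs {ranked[summ.n_active]:.1f} Hz")
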