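# cortexwm

Distributed working memory in a large-scale model of macaque neocortex.

Working memory — holding information over seconds without external input
— has classically been modelled as attractor dynamics inside a single
strongly recurrent area such as dorsolateral prefrontal cortex.
`cortexwm` implements the competing hypothesis: none of the 30 modelled
cortical areas is capable of sustaining memory on its own, and
stimulus-selective delay activity instead emerges from long-range
excitatory loops spanning temporal, parietal and frontal cortex. The
package is aimed at computational neuroscientists who want to simulate,
perturb and enumerate these distributed memory states.

## Model

Each area is a reduced three-population circuit: two stimulus-selective
excitatory pools with slow NMDA gating,

    dS/dt = -S/τ_N + γ (1 - S) r,        r → φ_E(I),

one inhibitory pool with fast GABA kinetics and a threshold-linear
transfer, and Ornstein-Uhlenbeck noise currents. An area is bistable
(spontaneous + memory state) only when its local coupling exceeds
J_s = 0.4655 nA. Three ingredients turn 30 sub-bistable areas into a
working-memory system:

1. **A macroscopic gradient.** J_s^i = J_min + (J_max − J_min) h_i
   follows each area's dendritic spine count (packaged, age-corrected),
   with J_IE co-varied so that the invariant drive
   J_s + J_c + 2 J_EI J_IE ζ = J_0 = 0.2112 nA keeps the resting state
   identical everywhere.
2. **Connectome-constrained loops.** Long-range weights are
   W = k₁ FLN^k₂ from (real or surrogate) retrograde-tracing data;
   like-selective pools receive G·W·SLN·S from each source.
3. **Counterstream inhibitory bias.** Feedback projections (low SLN)
   target the inhibitory pool with weight G·Z·W·(1−SLN), confining the
   memory pattern to the top of the hierarchy.

The anatomical hierarchy is itself fitted from the data: a binomial GLM
in which SLN(j→i) ≈ logistic(H_i − H_j). The package also contains the
experiment protocols built on this model (cue/delay trials, distractors,
permanent and transient silencing, targeted shutdown, input gating), a
numerical attractor census with lesion-survival analysis, a simplified
fully connected model for mean-field analysis, and a synthetic-connectome
generator emulating the statistical structure of the macaque data (the
real matrices, available from the authors of the tracing studies, drop
in as two CSV files).

## Worked example

```python
from cortexwm import (reference_connectome, build_network, run_wm_trial,
                      summarize_delay_activity)

net = build_network(reference_connectome(), mode="distributed")
res = run_wm_trial(net, duration=8.0, noise=False)   # 0.5 s cue to V1
summ = summarize_delay_activity(res)
```

With the packaged reference connectome this prints (see
`examples/03_wm_trial.py`):

```
delay-active areas (14 of 30, threshold 5.7 Hz):
  STPr    cued pool   95.2 Hz   selectivity   95.2 Hz
  8B      cued pool   81.8 Hz   selectivity   81.8 Hz
  24c     cued pool   81.3 Hz   selectivity   81.3 Hz
  ...
  9/46d   cued pool   22.0 Hz   selectivity   22.0 Hz

V1 (the cued area) falls back to 0.07 Hz
rate gap between active and inactive areas: 22.0 vs 0.2 Hz
```

Fourteen association areas hold the cue selectively through the delay
while every early sensory area — including V1, where the cue arrived —
returns to baseline; the 22-vs-0.2 Hz gap is the transition-in-space
between the memory-engaged and disengaged parts of cortex. Each script
in `examples/` demonstrates one capability the same way: the isolated
bifurcation diagram, the hierarchy fit and gradient, the
feedback-inhibition sweep, the attractor census and its inverted-U
dependence on global coupling, lesion survival, distractor resistance of
localized versus distributed memory, and the simplified mean-field
model. A thin CLI wraps the same machinery
(`cortexwm simulate --recipe wm_trial --out results`).

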