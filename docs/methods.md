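# Methods

`cortexwm` simulates distributed working memory in a 30-area model of
macaque neocortex: local mean-field circuits placed on a gradient of
recurrent excitation, coupled through tract-tracing-style connectivity in
which feedback projections preferentially recruit inhibition. This note
records the model equations as implemented, the choices made where the
design was open, and what the synthetic substrate does and does not show.

## Local circuit

Each area contains two stimulus-selective excitatory pools (A, B) and one
inhibitory pool. The slow variable of an excitatory pool is its NMDA
gating fraction,

    dS/dt = -S / tau_N + gamma (1 - S) r,        tau_N = 60 ms, gamma = 1.282,

the inhibitory pool carries a fast GABA conductance

    dS_C/dt = -S_C / tau_G + gamma_I r_C,        tau_G = 5 ms, gamma_I = 2.

Input currents combine local coupling (self J_s, cross J_c = 0.0107 nA,
inhibitory-to-excitatory J_EI = -0.31 nA, excitatory-to-inhibitory J_IE,
inhibitory self J_II = -0.12 nA), backgrounds (0.3294 nA excitatory,
0.26 nA inhibitory), long-range input, stimulation, and an
Ornstein-Uhlenbeck current (tau = 2 ms, sigma = 0.005 nA for excitatory
pools; stationary std sigma * sqrt(tau/2) ~ 1.6e-4 nA). Rates relax with
tau_r = 2 ms toward the transfer functions

    phi_E(I) = (a I - b) / (1 - exp(-d (a I - b))),   a = 135 Hz/nA, b = 54 Hz, d = 0.308 s,
    phi_C(I) = [ (c1 I - c0) / g_I + r0 ]_+,          c1 = 615 Hz/nA, c0 = 177 Hz, g_I = 4, r0 = 5.5 Hz.

The placement of the inhibitory baseline r0 *outside* the gain division
(equivalently, a rectified argument c1 I - c0 + g_I r0) deserves a note:
it is the only reading consistent with the closed-form balance offset
beta = tau_G gamma_I (c1 I0_C + g_I r0 - c0) / (g_I - J_II tau_G gamma_I c1),
and it is what places the isolated-area bifurcation at J_s = 0.4655 nA
(the package's scan returns 0.4655 +- 0.0005). With r0 divided by g_I the
bifurcation would sit near 0.416 nA and the standard gradient endpoint
J_max = 0.42 would already be bistable in isolation, contradicting the
model's premise.

Integration is fixed-step Euler-Maruyama, default dt = 0.5 ms (1 ms for
the deterministic census relaxations; a convergence test in the suite
compares the two). NMDA gating is clipped defensively to [0, 1]; rates
are rectified at zero; a step-size detector aborts when any relative
conductance step exceeds 20%.

## Gradient and balance

The local self-coupling interpolates J_s^i = J_min + (J_max - J_min) h_i
with J_min = 0.21 nA and J_max = 0.42 nA by default, where h_i in [0, 1]
is the area's excitability: for real data, age-corrected spine counts of
layer 2/3 basal dendrites (packaged as `data/spine_counts.csv`; missing
areas are filled by regressing counts on the fitted hierarchy); for
synthetic data, the generator's excitability proxy.

Raising J_s alone would raise an area's resting rate. Adiabatic
elimination of the fast GABA variables shows the resting state is
preserved exactly if J_s + J_c + 2 J_EI J_IE zeta = J_0 stays constant,
with zeta = tau_G gamma_I c1 / (g_I - J_II tau_G gamma_I c1) = 1.2980 /nA
and J_0 = 0.2112 nA at baseline. The package therefore co-varies
J_IE = (J_0 - J_s - J_c) / (2 J_EI zeta), which is exact at the fixed
point because the inhibitory transfer is linear above threshold. All 30
areas then share one resting state (0.655 Hz for the excitatory pools) to
numerical precision — a property the test suite asserts.

The anatomical hierarchy itself is estimated by a binomial GLM with logit
link: the SLN of projection j -> i is modelled as
logistic(H_i - H_j), the gauge fixed by anchoring the minimum to zero,
and h = H / H_max. FLN weighting of the regression is available but off
by default.

## Long-range coupling and counterstream inhibitory bias

FLN values are row-normalized (each target's incoming weights sum to
one), compressed as W = k1 FLN^k2 with k1 = 1.2 and k2 = 0.3, and scaled
on the target side by J_s^x / J_max so long-range input follows the same
macroscopic gradient as local recurrence. Like-selective excitatory pools
receive G W SLN S; inhibitory pools receive G Z W (1 - SLN)(S_A + S_B),
with G = 0.48 and the balancing factor
Z = 2 c1 tau_G gamma_I J_EI / (c1 tau_G gamma_I J_II - g_I) = 0.8048.
The inhibitory fraction min(cib_scale (1 - SLN), cap) is capped at 0.4
for projections onto the frontal-eye-field areas 8l and 8m and at 1
elsewhere; `cib_scale` is the sweep parameter of the feedback-inhibition
analyses, with 0 disabling the counterstream inhibitory bias entirely.

Named regimes: `distributed` (J_max 0.42, G 0.48), `strongly-distributed`
(J_max 0.26, G 0.48), and `localized` (J_max 0.468, G 0.21, feedback
projections removed: the inhibitory pathway zeroed and excitatory entries
of SLN < 0.5 projections dropped).

## Synthetic connectome

The generator emulates three regularities of the macaque retrograde
tracing data, all of which turn out to be load-bearing for the dynamics:

1. **Hierarchy compression.** The latent hierarchy is H = x^0.45 on
   equally spaced x: sensory areas are separated by large steps while
   association areas cluster. Projections within the association cluster
   then have SLN near 0.5, which keeps their net long-range drive small
   (the balance factor Z nearly cancels excitation against
   feedback-routed inhibition at SLN just below 0.4) — without this, the
   strongly coupled top areas rest far above the isolated fixed point and
   the selective mode destabilizes.
2. **Exponential-distance-rule dominance.** Each target draws two
   dominant sources from its hierarchical neighborhood
   (log10 FLN ~ N(-1.2, 0.3)) and a trace-level tail from everywhere
   else (log10 ~ U(-6, -3)); positive weights span more than four orders
   of magnitude. Edges exist with probability 0.66, the empirical
   density of the 30-area graph.
3. **Laminar polarization.** SLN = logistic(12 (H_x - H_y)): long
   ascending paths are almost purely feedforward, long descending ones
   almost purely feedback.

The excitability proxy (the synthetic stand-in for spine counts) is a
noisy saturating function of hierarchical rank, x / (x + 0.25) plus
N(0, 0.06), min-max rescaled with the bottom sensory area anchored at
zero — it rises quickly and plateaus, as measured spine counts do, so
the most excitable areas sit in the upper half of the hierarchy rather
than exactly at its top.

Analyses that depend on a particular substrate run on the **reference
connectome**, the generator's output at a fixed seed, mirroring how the
original analyses use one fixed tracing dataset; trial noise and census
sampling stay under the caller's seed.

### What the surrogate does not show

The surrogate supports the mechanism claims (distributed delay activity
from sub-bistable areas, confinement by feedback inhibition, the
attractor repertoire and its lesion sensitivity, distractor filtering),
but it is not the real connectome, and three departures matter:

- The coupled resting state of the `distributed` and
  `strongly-distributed` regimes is metastable rather than stable: a
  selective perturbation of order 1e-2 nA, or OU noise integrated over
  ten-plus seconds, can ignite a memory pattern without a cue. Protocol
  outcomes are therefore evaluated on deterministic (noise-free) runs or
  on cue-dominated epochs.
- Delay rates run higher (tens of Hz, up to ~95 Hz at the top of the
  pattern) than typical cortical delay activity, i.e. the surrogate's
  attractors are deeper than the real-data model's. One consequence:
  a 1 s, 0.3 nA excitatory pulse to the inhibitory pools of a few top
  areas suppresses them while it lasts but does not deactivate the whole
  pattern — the targeted-shutdown operation is provided and
  mechanically tested, but the network-wide shutdown result does not
  reproduce on this substrate.
- The localized regime's permanent-loss result holds on the reference
  substrate with the cue delivered directly to the memory-holding area;
  on other generator draws, neighbouring areas can co-latch and re-seed
  the silenced area.

## Attractor census

Noise-free relaxation from random initial conditions: each sample
elevates the pool-A gating of a random subset of areas (subset size
uniform on [1, N]) to S = 0.3, relaxes for 20 s by default (10 s in the
reduced analyses, which the settling check validates), binarizes by
"dominant-pool rate above resting + 5 Hz", and deduplicates on the
binary spatial pattern only. Samples still moving in the last second are
discarded and counted. The all-inactive pattern is not a memory state
and is excluded. The seed value S = 0.3 sits near the basin boundary of
a barely supercritical isolated area, so at G = 0 the census
deliberately undercounts isolated-area attractors; with any coupling the
seeded subsets support each other and the census is reproducible by
configuration. Census counts are reported raw; the inverted-U analyses
use a G grid from 0 to 0.30 at 512 samples per point, which resolves the
rise, the peak ordering across J_max cases, and the decline, while
staying below the strong-coupling regime where one or two global
patterns persist at any G.

Survival under silencing re-relaxes every attractor with the silenced
areas clamped (rates and outgoing conductances zero; they remain current
sinks) and counts the patterns whose active set stays nonempty. Both the
census and the survival computation are checked exactly against
brute-force relaxation from all binary seed patterns on 2- and 3-area
toy networks, through the plain numpy integrator rather than the census
kernel.

## Protocols

Stimuli are rectangular current pulses (default 0.3 nA for 0.5 s). The
delay summary takes the last 2 s of a trial and counts areas whose
cued-pool rate exceeds resting + 5 Hz; the wide gap in ranked delay
rates makes the active set insensitive to this threshold over roughly
1-20 Hz. Decisions about *memory content* (distractor outcome, encoding
success in threshold searches, shutdown success) use selectivity — the
cued-minus-anticued pool rate, majority over the five most excitable
areas with a 5 Hz margin — because strongly coupled areas can carry an
unselective baseline shift that raw-rate thresholds misread. Distractor
trials present the cue to the bottom area's pool A and, four seconds
after cue offset, an equal pulse to pool B; minimal-strength searches
bisect the pulse amplitude to 0.01 nA on noise-free trials, verifying
the bracket at both ends (a distractor threshold beyond the bracket is
reported as right-censored). Gating multiplies the long-range incoming
weights of "open" areas by 1 + g_s (a flag extends this to the local
couplings).

## Simplified model

The minimal model is a fully connected network of N = 30 excitatory
nodes, tau dr_i/dt = -r_i + phi(J_i r_i + G/(N-1) sum a_ij r_j + I),
with a logistic phi (threshold 0.5, width 0.07, unit ceiling), I = 0.25
and J_i on a linear gradient from 0 to 0.42 — just below the isolated
bifurcation near 0.45, mirroring the full model's construction. The
asymmetry factors a_ij multiply links running up (ff) or down (fb) the
gradient. The first-order mean field R = phi((J_mean + G) R + I) matches
simulated homogeneous networks within 5%. The qualitative results that
survive any reasonable parameter choice, and which the tests assert, are
the orderings: no bistability at G = 0, full recruitment at strong G,
partial recruitment windows for linear gradients, and a widening of the
partial window when feedback is weakened — the simple-model analogue of
the counterstream inhibitory bias. Exact transition couplings depend on
the sigmoid and are not asserted.

## Numerical notes

- The census relaxation runs through a numba kernel whose arithmetic
  matches the numpy stepper exactly (asserted in the suite).
- Fixed points of one area solve the rate self-consistency on a grid of
  initial guesses with the inhibitory branch eliminated in closed form;
  roots deduplicate at 1e-6 in S-space and stability is read from the
  eigenvalues of the 9-variable Jacobian (threshold -1e-8 on real
  parts). The bifurcation scan bisects the J_s at which a second stable
  fixed point appears, to 1e-4 nA.
- Deterministic runs are bit-reproducible; stochastic runs are
  reproducible given a seed. One master seed derives all per-area noise
  streams.
- Problem sizes in the shipped analyses (512 census samples per grid
  point, 8-10 s relaxations, 8-9 s trials) were chosen so the full
  acceptance computation completes in a few minutes; all scale linearly
  if more precision is wanted.
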