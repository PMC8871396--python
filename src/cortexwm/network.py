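"""Large-scale network assembly, integration, and experiment protocols.

The 30-area model couples local three-population circuits through the
rescaled connectome: like-selective excitatory pools receive
SLN-weighted long-range input, inhibitory pools receive
(1 - SLN)-weighted input scaled by the balancing factor Z (counterstream
inhibitory bias).  Protocols implemented here: cue/delay working-memory
trials, distractors, permanent and transient silencing, targeted
shutdown of frontal areas, and input gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .local import LocalCircuitParams, phi_excitatory, phi_inhibitory, spontaneous_state
from .gradients import (BalanceConstants, GradientSpec, HierarchyAssignment,
                        compute_balance_constants, build_gradient_spec,
                        fit_hierarchy_from_sln)
from .connectome import (ConnectomeBundle, ProjectionWeights, rescale_fln,
                         assemble_projection_weights)

__all__ = [
    "NetworkModel", "StimulusEvent", "SilencingSpec", "SimulationResult",
    "DelaySummary", "MODE_PRESETS", "build_network", "integrate",
    "relax_batch", "summarize_delay_activity", "run_wm_trial",
    "run_distractor_trial", "minimal_strength_search",
    "run_shutdown_protocol", "apply_gating",
]

#: Named parameterizations: (J_max, G, feedback_removed)
MODE_PRESETS = {
    "distributed": (0.42, 0.48, False),
    "strongly-distributed": (0.26, 0.48, False),
    "localized": (0.468, 0.21, True),
}

_POP_INDEX = {"A": 0, "B": 1, "C": 2, "inhibitory": 2, "I": 2}


@dataclass
class NetworkModel:
    """Assembled model: per-area circuit parameters plus long-range weights."""

    areas: list[str]
    params: LocalCircuitParams          # baseline (area-independent) constants
    J_s: np.ndarray                     # per-area self-coupling (nA)
    J_IE: np.ndarray                    # per-area balanced E->I coupling (nA)
    weights: ProjectionWeights
    constants: BalanceConstants
    hierarchy: np.ndarray               # normalized h per area
    mode: str = "custom"
    spontaneous: dict = field(default_factory=dict)  # per-population values

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def G(self) -> float:
        return self.weights.G

    def index(self, area: str) -> int:
        from .connectome import _norm_name
        key = _norm_name(area)
        for i, a in enumerate(self.areas):
            if _norm_name(a) == key:
                return i
        raise KeyError(f"area {area!r} not in network")

    def hierarchy_order(self) -> np.ndarray:
        """Area indices from bottom (lowest h) to top of the hierarchy."""
        return np.argsort(self.hierarchy, kind="stable")


@dataclass
class StimulusEvent:
    """A rectangular current pulse to one population of one area."""

    area: str
    population: str = "A"
    onset: float = 0.5
    duration: float = 0.5
    amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.population not in _POP_INDEX:
            raise ValueError(f"unknown population {self.population!r}")


@dataclass
class SilencingSpec:
    """Areas clamped off (rates and outgoing conductances zero).

    ``window=None`` silences for the whole simulation; otherwise a
    (start, end) pair in seconds.  Silenced areas keep receiving input
    (they are current sinks) but do not communicate.
    """

    areas: Iterable[str]
    window: tuple[float, float] | None = None


@dataclass
class SimulationResult:
    """Recorded trajectory of a network simulation."""

    time: np.ndarray                 # (T,) seconds
    rates: np.ndarray                # (T, N, 3) Hz for pools A, B, C
    areas: list[str]
    dt: float
    seed: int | None
    events: list = field(default_factory=list)
    spontaneous_rate: float = 0.0    # excitatory spontaneous rate (Hz)
    final_state: dict | None = None

    def rate(self, area: str, population: str = "A") -> np.ndarray:
        from .connectome import _norm_name
        idx = [_norm_name(a) for a in self.areas].index(_norm_name(area))
        return self.rates[:, idx, _POP_INDEX[population]]


@dataclass
class DelaySummary:
    """Delay-period activity summary of one trial."""

    areas: list[str]
    mean_rates: np.ndarray          # cued-pool mean over the window (Hz)
    anticued_rates: np.ndarray
    threshold: float
    window: tuple[float, float]
    active: list[str]
    selectivity: np.ndarray         # cued minus anticued mean rate
    rate_order: list[str]           # areas ranked by delay rate, descending

    @property
    def n_active(self) -> int:
        return len(self.active)


def build_network(bundle: ConnectomeBundle,
                  mode: str = "distributed",
                  G: float | None = None,
                  J_min: float = 0.21,
                  J_max: float | None = None,
                  cib_scale: float = 1.0,
                  fef_cap: float = 0.4,
                  k1: float = 1.2, k2: float = 0.3,
                  normalize_fln: bool = True,
                  hierarchy: HierarchyAssignment | np.ndarray | None = None,
                  params: LocalCircuitParams | None = None) -> NetworkModel:
    """Assemble a ready-to-integrate network from a connectome bundle.

    ``mode`` selects a named regime (see ``MODE_PRESETS``); explicit
    ``G``/``J_max`` override the preset.  The hierarchy defaults to the
    logistic fit on the bundle's own SLN matrix; per-area J_s follows
    the linear gradient and J_IE the spontaneous-state balance.  In
    ``localized`` mode long-range feedback is removed entirely: the
    inhibitory pathway is zeroed and excitatory entries of feedback
    projections (SLN < 0.5) are dropped.
    """
    bundle.validate()
    p = params or LocalCircuitParams()
    if mode in MODE_PRESETS:
        mJ, mG, feedback_removed = MODE_PRESETS[mode]
        J_max = mJ if J_max is None else J_max
        G = mG if G is None else G
    elif mode == "custom":
        if G is None or J_max is None:
            raise ValueError("custom mode requires explicit G and J_max")
        feedback_removed = False
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if hierarchy is None:
        hierarchy = fit_hierarchy_from_sln(bundle.SLN, bundle.FLN, bundle.areas)
    h = hierarchy.h if isinstance(hierarchy, HierarchyAssignment) else np.asarray(hierarchy)
    constants = compute_balance_constants(p)
    # local excitability (spine-count proxy) sets the J_s gradient; it
    # correlates with, but is not identical to, the laminar hierarchy h
    g = bundle.excitability if bundle.excitability is not None else h
    gradient = build_gradient_spec(g, bundle.areas, J_min, J_max, p)
    W = rescale_fln(bundle.FLN, k1=k1, k2=k2, normalize=normalize_fln)
    weights = assemble_projection_weights(bundle, W, gradient, constants,
                                          G=G, cib_scale=cib_scale,
                                          fef_cap=fef_cap)
    if feedback_removed:
        weights.W_EI = np.zeros_like(weights.W_EI)
        ff = np.nan_to_num(bundle.SLN, nan=0.5) >= 0.5
        weights.W_EE = np.where(ff, weights.W_EE, 0.0)

    sp = spontaneous_state(p)
    return NetworkModel(
        areas=list(bundle.areas), params=p, J_s=gradient.J_s,
        J_IE=np.asarray(gradient.J_IE, dtype=float), weights=weights,
        constants=constants, hierarchy=h, mode=mode,
        spontaneous={"S_A": sp.S_A, "S_B": sp.S_B, "S_C": sp.S_C,
                     "r_A": sp.r_A, "r_B": sp.r_B, "r_C": sp.r_C})


class _BatchState:
    """Stacked state arrays for B parallel copies of the network."""

    __slots__ = ("S", "x", "r")

    def __init__(self, S: np.ndarray, x: np.ndarray, r: np.ndarray):
        self.S = S  # (B, N, 3)
        self.x = x  # (B, N, 3)
        self.r = r  # (B, N, 3)

    @classmethod
    def spontaneous(cls, net: NetworkModel, batch: int = 1) -> "_BatchState":
        sp = net.spontaneous
        N = net.n_areas
        S = np.empty((batch, N, 3))
        r = np.empty((batch, N, 3))
        S[..., 0], S[..., 1], S[..., 2] = sp["S_A"], sp["S_B"], sp["S_C"]
        r[..., 0], r[..., 1], r[..., 2] = sp["r_A"], sp["r_B"], sp["r_C"]
        return cls(S, np.zeros((batch, N, 3)), r)

    def copy(self) -> "_BatchState":
        return _BatchState(self.S.copy(), self.x.copy(), self.r.copy())


def _step_batch(st: _BatchState, net: NetworkModel, dt: float,
                stim: np.ndarray | None = None,
                noise: np.ndarray | None = None,
                silenced: np.ndarray | None = None) -> None:
    """One in-place Euler-Maruyama step for a batch of network copies.

    ``stim`` is (N, 3) or (B, N, 3) in nA; ``noise`` a (B, N, 3) array of
    standard normals (None for deterministic stepping); ``silenced`` a
    boolean (N,) mask of areas clamped to zero.
    """
    p = net.params
    W_EE, W_EI = net.weights.W_EE, net.weights.W_EI
    G, Z = net.weights.G, net.constants.Z
    S_A, S_B, S_C = st.S[..., 0], st.S[..., 1], st.S[..., 2]

    I_net_A = G * (S_A @ W_EE.T)
    I_net_B = G * (S_B @ W_EE.T)
    I_net_C = G * Z * ((S_A + S_B) @ W_EI.T)

    I = np.empty_like(st.S)
    I[..., 0] = net.J_s * S_A + p.J_c * S_B + p.J_EI * S_C + p.I0_A + I_net_A + st.x[..., 0]
    I[..., 1] = p.J_c * S_A + net.J_s * S_B + p.J_EI * S_C + p.I0_B + I_net_B + st.x[..., 1]
    I[..., 2] = net.J_IE * (S_A + S_B) + p.J_II * S_C + p.I0_C + I_net_C + st.x[..., 2]
    if stim is not None:
        I += stim

    phi = np.empty_like(I)
    phi[..., :2] = phi_excitatory(I[..., :2], p)
    phi[..., 2] = phi_inhibitory(I[..., 2], p)

    dS = np.empty_like(st.S)
    dS[..., 0] = dt * (-S_A / p.tau_N + p.gamma * (1 - S_A) * st.r[..., 0])
    dS[..., 1] = dt * (-S_B / p.tau_N + p.gamma * (1 - S_B) * st.r[..., 1])
    dS[..., 2] = dt * (-S_C / p.tau_G + p.gamma_I * st.r[..., 2])
    # relative test: NMDA gating lives in [0, 1], the GABA conductance can
    # legitimately take large values (and large steps toward them)
    if np.max(np.abs(dS) / (1.0 + np.abs(st.S))) > 0.2:
        raise RuntimeError(
            f"integration unstable: relative |dS| = "
            f"{np.max(np.abs(dS) / (1.0 + np.abs(st.S))):.3f} in one step "
            f"(dt = {dt}); reduce dt")
    st.S += dS
    np.clip(st.S[..., :2], 0.0, 1.0, out=st.S[..., :2])
    np.maximum(st.S[..., 2], 0.0, out=st.S[..., 2])

    st.x += dt * (-st.x / p.tau_noise)
    if noise is not None:
        sig = np.array([p.sigma_A, p.sigma_B, p.sigma_C])
        st.x += sig * np.sqrt(dt) * noise

    st.r += dt / p.tau_r * (-st.r + phi)
    np.maximum(st.r, 0.0, out=st.r)

    if silenced is not None and silenced.any():
        st.S[:, silenced, :] = 0.0
        st.r[:, silenced, :] = 0.0


def _stim_schedule(net: NetworkModel, events: Sequence[StimulusEvent],
                   dt: float) -> list[tuple[int, int, int, int, float]]:
    sched = []
    for ev in events:
        i = net.index(ev.area)
        pop = _POP_INDEX[ev.population]
        k0 = int(round(ev.onset / dt))
        k1 = int(round((ev.onset + ev.duration) / dt))
        sched.append((k0, k1, i, pop, ev.amplitude))
    return sched


def integrate(network: NetworkModel,
              events: Sequence[StimulusEvent] = (),
              silencing: SilencingSpec | None = None,
              duration: float = 10.0,
              dt: float = 5e-4,
              seed: int | None = None,
              noise: bool = True,
              init: _BatchState | None = None,
              record_dt: float = 0.002) -> SimulationResult:
    """Run one stochastic trial and record population rates.

    Starts from the spontaneous fixed point unless ``init`` is given.
    Stimulus currents add to the targeted population's input; silenced
    areas are clamped per the spec.  With ``noise=False`` (or zero
    sigmas) the trajectory is deterministic and seed-independent.
    """
    n_steps = int(round(duration / dt))
    every = max(1, int(round(record_dt / dt)))
    rng = np.random.default_rng(seed) if noise else None

    st = init.copy() if init is not None else _BatchState.spontaneous(network)
    sched = _stim_schedule(network, events, dt)

    sil_mask = None
    sil_k = None
    if silencing is not None:
        sil_mask = np.zeros(network.n_areas, dtype=bool)
        for a in silencing.areas:
            sil_mask[network.index(a)] = True
        if silencing.window is None:
            sil_k = (0, n_steps + 1)
        else:
            sil_k = (int(round(silencing.window[0] / dt)),
                     int(round(silencing.window[1] / dt)))

    N = network.n_areas
    rec_t, rec_r = [], []
    stim = np.zeros((N, 3))
    log = [{"kind": "stimulus", "area": ev.area, "population": ev.population,
            "onset": ev.onset, "duration": ev.duration,
            "amplitude": ev.amplitude} for ev in events]
    if silencing is not None:
        log.append({"kind": "silencing", "areas": list(silencing.areas),
                    "window": silencing.window})

    for k in range(n_steps):
        stim[:] = 0.0
        for k0, k1, i, popi, amp in sched:
            if k0 <= k < k1:
                stim[i, popi] += amp
        mask = None
        if sil_mask is not None and sil_k[0] <= k < sil_k[1]:
            mask = sil_mask
        z = rng.standard_normal((1, N, 3)) if rng is not None else None
        _step_batch(st, network, dt, stim=stim, noise=z, silenced=mask)
        if (k + 1) % every == 0:
            rec_t.append((k + 1) * dt)
            rec_r.append(st.r[0].copy())

    return SimulationResult(
        time=np.asarray(rec_t), rates=np.asarray(rec_r),
        areas=list(network.areas), dt=dt, seed=seed, events=log,
        spontaneous_rate=network.spontaneous["r_A"],
        final_state={"S": st.S[0].copy(), "x": st.x[0].copy(),
                     "r": st.r[0].copy()})


def relax_batch(network: NetworkModel, S_init: np.ndarray,
                relax_time: float = 20.0, dt: float = 5e-4,
                silenced: np.ndarray | None = None,
                settle_check: float = 1.0,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministically relax a batch of initial conditions.

    ``S_init`` is (B, N, 3).  Rates start self-consistently at the
    transfer-function output for the initial conductances.  Returns
    (rates, S, converged): final (B, N, 3) arrays and a boolean mask of
    samples whose maximum rate change over the last ``settle_check``
    seconds stayed below 0.5 Hz.
    """
    B, N, _ = S_init.shape
    st = _BatchState(S_init.copy().astype(float), np.zeros((B, N, 3)),
                     np.zeros((B, N, 3)))
    # rates start at zero; tau_r (2 ms) pulls them onto phi(I) immediately
    n_steps = int(round(relax_time / dt))
    check_from = n_steps - int(round(settle_check / dt))
    sil = np.zeros(N, dtype=np.int8)
    if silenced is not None:
        sil[silenced] = 1

    from . import _kernels
    if _kernels.HAVE_NUMBA:
        p = network.params
        r_at_check = _kernels.relax_kernel(
            st.S, st.r,
            np.ascontiguousarray(network.weights.W_EE.T),
            np.ascontiguousarray(network.weights.W_EI.T),
            network.J_s.astype(float), network.J_IE.astype(float),
            p.J_c, p.J_EI, p.J_II, p.I0_A, p.I0_B, p.I0_C,
            p.a, p.b, p.d, p.g_I, p.c1, p.c0, p.r0,
            p.tau_N, p.tau_G, p.tau_r, p.gamma, p.gamma_I,
            network.weights.G, network.constants.Z, dt, n_steps,
            check_from, sil)
    else:  # pragma: no cover - numpy fallback
        mask = sil.astype(bool) if silenced is not None else None
        r_at_check = None
        for k in range(n_steps):
            _step_batch(st, network, dt, silenced=mask)
            if k == check_from:
                r_at_check = st.r.copy()
    moved = np.max(np.abs(st.r - r_at_check), axis=(1, 2))
    return st.r.copy(), st.S.copy(), moved < 0.5


def summarize_delay_activity(result: SimulationResult,
                             window: tuple[float, float] | None = None,
                             threshold: float | None = None,
                             cued: str = "A") -> DelaySummary:
    """Mean cued-pool rates over the delay window and the active-area set.

    Default window is the last 2 s of the trial; default threshold is
    the spontaneous rate + 5 Hz (the rate gap across the hierarchy makes
    the active set insensitive to this choice over a wide band).
    """
    t = result.time
    if window is None:
        window = (float(t[-1]) - 2.0, float(t[-1]))
    last_offset = max((e["onset"] + e["duration"] for e in result.events
                      if e.get("kind") == "stimulus"), default=0.0)
    if window[0] < last_offset:
        import warnings
        warnings.warn("delay window starts before the last stimulus offset")
    if threshold is None:
        threshold = result.spontaneous_rate + 5.0
    sel = (t >= window[0]) & (t <= window[1])
    cued_i = _POP_INDEX[cued]
    anti_i = 1 - cued_i
    mean_cued = result.rates[sel, :, cued_i].mean(axis=0)
    mean_anti = result.rates[sel, :, anti_i].mean(axis=0)
    active = [a for a, r in zip(result.areas, mean_cued) if r > threshold]
    order = list(np.argsort(-mean_cued, kind="stable"))
    return DelaySummary(
        areas=list(result.areas), mean_rates=mean_cued,
        anticued_rates=mean_anti, threshold=float(threshold),
        window=(float(window[0]), float(window[1])), active=active,
        selectivity=mean_cued - mean_anti,
        rate_order=[result.areas[i] for i in order])


def run_wm_trial(network: NetworkModel, cue_area: str | None = None,
                 cue_population: str = "A", amplitude: float = 0.3,
                 cue_onset: float = 0.5, cue_duration: float = 0.5,
                 duration: float = 8.0, dt: float = 5e-4,
                 seed: int | None = None, noise: bool = True,
                 **kw) -> SimulationResult:
    """Standard cue/delay trial: a 0.5 s selective pulse, then free delay.

    The cue defaults to the bottom-hierarchy area (V1 on the canonical
    connectome).
    """
    if cue_area is None:
        cue_area = network.areas[int(np.argmin(network.hierarchy))]
    ev = StimulusEvent(area=cue_area, population=cue_population,
                       onset=cue_onset, duration=cue_duration,
                       amplitude=amplitude)
    return integrate(network, events=[ev], duration=duration, dt=dt,
                     seed=seed, noise=noise, **kw)


def _top_areas(network: NetworkModel, n: int = 5) -> list[int]:
    """Indices of the n most excitable (highest J_s) areas: the memory core."""
    return list(np.argsort(network.J_s, kind="stable")[-n:])


def run_distractor_trial(network: NetworkModel,
                         cue: StimulusEvent | None = None,
                         distractor: StimulusEvent | None = None,
                         gap: float = 4.0,
                         tail: float = 4.0,
                         dt: float = 5e-4, seed: int | None = None,
                         noise: bool = True,
                         threshold: float | None = None,
                         ) -> tuple[str, SimulationResult]:
    """Cue (pool A) then distractor (pool B) after ``gap`` seconds.

    The outcome is decided from the late-delay activity of the top five
    hierarchy areas by majority: 'retained-cue' if pool A is active,
    'switched-to-distractor' if pool B is, 'lost' if neither.
    """
    bottom = network.areas[int(np.argmin(network.hierarchy))]
    if cue is None:
        cue = StimulusEvent(area=bottom, population="A", onset=0.5)
    if distractor is None:
        distractor = StimulusEvent(area=cue.area, population="B",
                                   onset=cue.onset + cue.duration + gap,
                                   duration=cue.duration,
                                   amplitude=cue.amplitude)
    else:
        distractor = replace(distractor,
                             onset=cue.onset + cue.duration + gap)
    duration = distractor.onset + distractor.duration + tail
    events = [cue] + ([distractor] if distractor.amplitude > 0 else [])
    res = integrate(network, events=events, duration=duration, dt=dt,
                    seed=seed, noise=noise)
    if threshold is None:
        threshold = 5.0  # selectivity margin (Hz)
    sel = res.time >= duration - 2.0
    top = _top_areas(network, 5)
    rA = res.rates[sel][:, top, 0].mean(axis=0)
    rB = res.rates[sel][:, top, 1].mean(axis=0)
    # memory content = selective (cued minus anticued) activity; this is
    # robust to unselective baseline shifts of strongly coupled areas
    a_votes = int(np.sum(rA - rB > threshold))
    b_votes = int(np.sum(rB - rA > threshold))
    if a_votes > b_votes:
        label = "retained-cue"
    elif b_votes > a_votes:
        label = "switched-to-distractor"
    elif a_votes > 0:
        label = "retained-cue"  # tie with votes on both sides
    else:
        label = "lost"
    return label, res


def minimal_strength_search(network: NetworkModel, role: str = "cue",
                            bracket: tuple[float, float] = (0.0, 0.6),
                            tol: float = 0.01,
                            cue_amplitude: float = 0.3,
                            gap: float = 4.0, dt: float = 5e-4,
                            noise: bool = False) -> float:
    """Bisect the minimal pulse amplitude that changes the trial outcome.

    ``role='cue'``: smallest cue amplitude that elicits a sustained
    pattern (any active area late in the delay).  ``role='distractor'``:
    smallest distractor amplitude that overwrites a cue of
    ``cue_amplitude``.  Searches run noise-free by default so the
    outcome is a deterministic function of amplitude.
    """
    bottom = network.areas[int(np.argmin(network.hierarchy))]

    def success(amp: float) -> bool:
        if role == "cue":
            res = run_wm_trial(network, amplitude=amp, duration=7.0, dt=dt,
                               noise=noise, seed=0)
            summ = summarize_delay_activity(res)
            # encoded = selective delay activity somewhere in the network
            return bool(np.max(summ.selectivity) > 5.0)
        elif role == "distractor":
            cue = StimulusEvent(area=bottom, population="A", onset=0.5,
                                amplitude=cue_amplitude)
            dis = StimulusEvent(area=bottom, population="B", onset=0.0,
                                amplitude=amp)
            label, _ = run_distractor_trial(network, cue=cue, distractor=dis,
                                            gap=gap, dt=dt, noise=noise,
                                            seed=0)
            return label != "retained-cue"
        raise ValueError(f"unknown role {role!r}")

    lo, hi = bracket
    if success(lo) or not success(hi):
        raise ValueError(
            f"bracket {bracket} does not straddle the {role} threshold: "
            f"outcome(lo)={success(lo)}, outcome(hi)={success(hi)}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if success(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def run_shutdown_protocol(network: NetworkModel,
                          targets: Sequence[str] = ("9/46v", "9/46d", "F7", "8B"),
                          amplitude: float = 0.3, duration: float = 1.0,
                          cue_area: str | None = None,
                          cue_amplitude: float = 0.3,
                          shutdown_onset: float = 6.0,
                          total: float = 14.0, dt: float = 5e-4,
                          seed: int | None = None, noise: bool = True,
                          ) -> tuple[SimulationResult, bool]:
    """Establish a distributed attractor, then excite inhibition in ``targets``.

    An excitatory pulse to the inhibitory populations of the target
    areas (default: the four top frontal areas) tests whether localized
    inhibition can deactivate the whole distributed pattern.  Returns
    the trajectory and whether every area returned to spontaneous in the
    final 1.5 s.
    """
    for t in targets:
        network.index(t)  # raises on unknown names
    if cue_area is None:
        cue_area = network.areas[int(np.argmin(network.hierarchy))]
    events = []
    if cue_amplitude > 0:
        events.append(StimulusEvent(area=cue_area, population="A", onset=0.5,
                                    amplitude=cue_amplitude))
    events += [StimulusEvent(area=t, population="inhibitory",
                             onset=shutdown_onset, duration=duration,
                             amplitude=amplitude) for t in targets]
    res = integrate(network, events=events, duration=total, dt=dt,
                    seed=seed, noise=noise)
    summ = summarize_delay_activity(res, window=(total - 1.5, total))
    # deactivated = no selective memory trace anywhere
    return res, bool(np.max(summ.selectivity) < 5.0)


def apply_gating(network: NetworkModel, open_areas: Iterable[str],
                 g_s: float, long_range_only: bool = True) -> NetworkModel:
    """Open input gates: incoming projections onto ``open_areas`` x(1+g_s).

    Models dendritic gating: an 'open' area weighs its afferents more
    strongly.  By default only long-range weights are scaled; with
    ``long_range_only=False`` the local couplings J_s, J_c of the open
    areas scale too.
    """
    if g_s < 0:
        raise ValueError("g_s must be >= 0")
    idx = [network.index(a) for a in open_areas]
    w = network.weights
    W_EE = w.W_EE.copy()
    W_EI = w.W_EI.copy()
    W_EE[idx, :] *= (1.0 + g_s)
    W_EI[idx, :] *= (1.0 + g_s)
    new_w = ProjectionWeights(areas=list(w.areas), W_EE=W_EE, W_EI=W_EI,
                              G=w.G, cib_scale=w.cib_scale, fef_cap=w.fef_cap)
    J_s = network.J_s.copy()
    if not long_range_only:
        J_s[idx] *= (1.0 + g_s)
    return NetworkModel(areas=list(network.areas), params=network.params,
                        J_s=J_s, J_IE=network.J_IE.copy(), weights=new_w,
                        constants=network.constants,
                        hierarchy=network.hierarchy.copy(),
                        mode=network.mode,
                        spontaneous=dict(network.spontaneous))
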