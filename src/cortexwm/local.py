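"""Local three-population circuit of a single cortical area.

Each area is a reduced mean-field circuit with two stimulus-selective
excitatory pools (A, B) whose slow synaptic variable is the NMDA gating
fraction, one inhibitory pool with a fast GABA conductance, and an
Ornstein-Uhlenbeck noise current per population.  Depending on the local
self-coupling ``J_s`` the isolated circuit is monostable (a single
spontaneous low-rate state) or bistable (spontaneous state coexisting
with an elevated, stimulus-selective memory state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "LocalCircuitParams",
    "AreaState",
    "FixedPoint",
    "phi_excitatory",
    "phi_inhibitory",
    "population_currents",
    "step_area",
    "find_fixed_points",
    "critical_coupling_scan",
]


@dataclass
class LocalCircuitParams:
    """Constants of one area's three-population circuit.

    Couplings are in nA (inhibitory ones carry their negative sign
    explicitly), time constants in seconds, gains in Hz/nA.
    """

    tau_N: float = 0.060      # NMDA conductance time constant (s)
    tau_G: float = 0.005      # GABA conductance time constant (s)
    gamma: float = 1.282      # NMDA coupling factor
    gamma_I: float = 2.0      # GABA coupling factor
    J_s: float = 0.3213       # local self-coupling within a pool (nA)
    J_c: float = 0.0107       # cross-coupling between pools (nA)
    J_EI: float = -0.31       # inhibitory -> excitatory coupling (nA)
    J_IE: float = 0.15        # excitatory -> inhibitory coupling (nA)
    J_II: float = -0.12       # inhibitory self-coupling (nA)
    I0_A: float = 0.3294      # background current, pool A (nA)
    I0_B: float = 0.3294      # background current, pool B (nA)
    I0_C: float = 0.26        # background current, inhibitory pool (nA)
    a: float = 135.0          # excitatory gain (Hz/nA)
    b: float = 54.0           # excitatory threshold (Hz)
    d: float = 0.308          # excitatory curvature (s)
    g_I: float = 4.0          # inhibitory gain divisor
    c1: float = 615.0         # inhibitory gain (Hz/nA)
    c0: float = 177.0         # inhibitory threshold (Hz)
    r0: float = 5.5           # inhibitory baseline rate (Hz)
    tau_r: float = 0.002      # rate relaxation time constant (s)
    tau_noise: float = 0.002  # OU noise time constant (s)
    sigma_A: float = 0.005    # OU noise amplitude, pool A (nA)
    sigma_B: float = 0.005    # OU noise amplitude, pool B (nA)
    sigma_C: float = 0.0      # OU noise amplitude, inhibitory pool (nA)

    def __post_init__(self) -> None:
        for name in ("tau_N", "tau_G", "tau_r", "tau_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be positive")
        if self.J_EI > 0 or self.J_II > 0:
            raise ValueError("inhibitory couplings J_EI, J_II must be <= 0")
        if self.J_s < 0 or self.J_c < 0 or self.J_IE < 0:
            raise ValueError("excitatory couplings J_s, J_c, J_IE must be >= 0")
        if self.a <= 0 or self.c1 <= 0 or self.g_I <= 0:
            raise ValueError("gains a, c1, g_I must be positive")

    def replace(self, **kw) -> "LocalCircuitParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LocalCircuitParams":
        return cls(**d)


@dataclass
class AreaState:
    """Dynamical state of one area.

    ``S_A``/``S_B`` are NMDA gating fractions in [0, 1], ``S_C`` the GABA
    conductance (>= 0), ``x_*`` the OU noise currents (nA) and ``r_*`` the
    population rates (Hz).
    """

    S_A: float = 0.0
    S_B: float = 0.0
    S_C: float = 0.0
    x_A: float = 0.0
    x_B: float = 0.0
    x_C: float = 0.0
    r_A: float = 0.0
    r_B: float = 0.0
    r_C: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.S_A, self.S_B, self.S_C,
                         self.x_A, self.x_B, self.x_C,
                         self.r_A, self.r_B, self.r_C])

    @classmethod
    def from_array(cls, v: np.ndarray) -> "AreaState":
        return cls(*[float(x) for x in v])


def phi_excitatory(I, params: LocalCircuitParams):
    """Excitatory transfer function (aI - b) / (1 - exp(-d (aI - b))).

    The removable singularity at a*I = b is handled analytically: the
    limit of x / (1 - exp(-d x)) as x -> 0 is 1/d.  Accepts scalars or
    arrays; rates are non-negative by construction.
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("phi_excitatory: input current must be finite")
    x = params.a * I - params.b
    # series of x/(1-e^{-dx}) around 0: 1/d + x/2 + d x^2/12 + O(x^4)
    small = np.abs(x) < 1e-6
    with np.errstate(over="ignore"):
        denom = 1.0 - np.exp(-params.d * np.where(small, 1.0, x))
    out = np.where(small,
                   1.0 / params.d + x / 2.0 + params.d * x * x / 12.0,
                   x / np.where(small, 1.0, denom))
    return out if out.ndim else float(out)


def phi_inhibitory(I, params: LocalCircuitParams):
    """Threshold-linear inhibitory transfer: [(c1*I - c0)/g_I + r0]_+.

    The baseline rate r0 is added after the gain division, i.e. the
    rectified argument is c1*I - c0 + g_I*r0.  This placement is the one
    consistent with the closed-form balance constants (the beta offset
    carries a g_I*r0 term) and it reproduces the isolated-area
    bifurcation at J_s = 0.4655 nA.
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("phi_inhibitory: input current must be finite")
    out = np.maximum(params.c1 * I - params.c0 + params.g_I * params.r0, 0.0) / params.g_I
    return out if out.ndim else float(out)


def population_currents(state: AreaState, params: LocalCircuitParams,
                        net_input: Sequence[float] = (0.0, 0.0, 0.0),
                        stim: Sequence[float] = (0.0, 0.0, 0.0)) -> tuple[float, float, float]:
    """Total input currents (I_A, I_B, I_C) in nA.

    ``net_input`` carries long-range input per population; ``stim``
    external pulse currents.  Noise currents are taken from the state.
    """
    p = params
    I_A = (p.J_s * state.S_A + p.J_c * state.S_B + p.J_EI * state.S_C
           + p.I0_A + net_input[0] + stim[0] + state.x_A)
    I_B = (p.J_c * state.S_A + p.J_s * state.S_B + p.J_EI * state.S_C
           + p.I0_B + net_input[1] + stim[1] + state.x_B)
    I_C = (p.J_IE * (state.S_A + state.S_B) + p.J_II * state.S_C
           + p.I0_C + net_input[2] + stim[2] + state.x_C)
    return I_A, I_B, I_C


def step_area(state: AreaState, params: LocalCircuitParams, dt: float,
              rng: np.random.Generator | None = None,
              net_input: Sequence[float] = (0.0, 0.0, 0.0),
              stim: Sequence[float] = (0.0, 0.0, 0.0)) -> AreaState:
    """One Euler-Maruyama step of a single isolated area.

    Synaptic variables follow dS/dt = -S/tau + gamma (1-S) r (NMDA) and
    dS_C/dt = -S_C/tau_G + gamma_I r_C (GABA); rates relax toward the
    transfer-function output with time constant tau_r; OU noise uses the
    sqrt(dt) scaling.  S_A, S_B are clipped defensively to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params
    I_A, I_B, I_C = population_currents(state, p, net_input, stim)

    S_A = state.S_A + dt * (-state.S_A / p.tau_N + p.gamma * (1 - state.S_A) * state.r_A)
    S_B = state.S_B + dt * (-state.S_B / p.tau_N + p.gamma * (1 - state.S_B) * state.r_B)
    S_C = state.S_C + dt * (-state.S_C / p.tau_G + p.gamma_I * state.r_C)

    if rng is not None:
        noise = rng.standard_normal(3)
    else:
        noise = np.zeros(3)
    sqdt = np.sqrt(dt)
    x_A = state.x_A + dt * (-state.x_A / p.tau_noise) + p.sigma_A * sqdt * noise[0]
    x_B = state.x_B + dt * (-state.x_B / p.tau_noise) + p.sigma_B * sqdt * noise[1]
    x_C = state.x_C + dt * (-state.x_C / p.tau_noise) + p.sigma_C * sqdt * noise[2]

    r_A = state.r_A + dt / p.tau_r * (-state.r_A + phi_excitatory(I_A, p))
    r_B = state.r_B + dt / p.tau_r * (-state.r_B + phi_excitatory(I_B, p))
    r_C = state.r_C + dt / p.tau_r * (-state.r_C + phi_inhibitory(I_C, p))

    return AreaState(
        S_A=float(np.clip(S_A, 0.0, 1.0)),
        S_B=float(np.clip(S_B, 0.0, 1.0)),
        S_C=float(max(S_C, 0.0)),
        x_A=float(x_A), x_B=float(x_B), x_C=float(x_C),
        r_A=float(max(r_A, 0.0)), r_B=float(max(r_B, 0.0)),
        r_C=float(max(r_C, 0.0)),
    )


@dataclass
class FixedPoint:
    """A noise-free fixed point of the isolated circuit with stability label."""

    S_A: float
    S_B: float
    S_C: float
    r_A: float
    r_B: float
    r_C: float
    stable: bool
    eigenvalues: np.ndarray = field(repr=False, default=None)


def _steady_S_exc(r: float, params: LocalCircuitParams) -> float:
    # dS/dt = 0  =>  S = gamma tau_N r / (1 + gamma tau_N r)
    g = params.gamma * params.tau_N * r
    return g / (1.0 + g)


def _fp_residual(rs: np.ndarray, params: LocalCircuitParams) -> np.ndarray:
    """Residual of the self-consistency r_i = phi_i(I_i) in (r_A, r_B)."""
    p = params
    r_A, r_B = rs
    S_A = _steady_S_exc(r_A, p)
    S_B = _steady_S_exc(r_B, p)
    # inhibitory branch is linear above threshold; solve its fixed point
    # r_C = phi_C(I_C), S_C = tau_G gamma_I r_C in closed form
    k = p.tau_G * p.gamma_I
    denom = p.g_I - p.c1 * p.J_II * k
    num = p.c1 * (p.J_IE * (S_A + S_B) + p.I0_C) - p.c0 + p.g_I * p.r0
    r_C = num / denom
    if r_C < 0:  # below rectification: S_C = 0 consistently
        r_C = 0.0
    S_C = k * r_C
    st = AreaState(S_A=S_A, S_B=S_B, S_C=S_C, r_A=r_A, r_B=r_B, r_C=r_C)
    I_A, I_B, _ = population_currents(st, p)
    return np.array([phi_excitatory(I_A, p) - r_A,
                     phi_excitatory(I_B, p) - r_B])


def _drift(v: np.ndarray, params: LocalCircuitParams) -> np.ndarray:
    """Deterministic vector field on the 9-dim state (noise off)."""
    p = params
    st = AreaState.from_array(v)
    I_A, I_B, I_C = population_currents(st, p)
    return np.array([
        -st.S_A / p.tau_N + p.gamma * (1 - st.S_A) * st.r_A,
        -st.S_B / p.tau_N + p.gamma * (1 - st.S_B) * st.r_B,
        -st.S_C / p.tau_G + p.gamma_I * st.r_C,
        -st.x_A / p.tau_noise,
        -st.x_B / p.tau_noise,
        -st.x_C / p.tau_noise,
        (-st.r_A + phi_excitatory(I_A, p)) / p.tau_r,
        (-st.r_B + phi_excitatory(I_B, p)) / p.tau_r,
        (-st.r_C + phi_inhibitory(I_C, p)) / p.tau_r,
    ])


def _jacobian(v: np.ndarray, params: LocalCircuitParams, eps: float = 1e-7) -> np.ndarray:
    n = v.size
    J = np.empty((n, n))
    f0 = _drift(v, params)
    for j in range(n):
        dv = v.copy()
        dv[j] += eps
        J[:, j] = (_drift(dv, params) - f0) / eps
    return J


def find_fixed_points(params: LocalCircuitParams,
                      rate_grid: Sequence[float] = (0.1, 2.0, 8.0, 20.0, 40.0, 70.0),
                      tol: float = 1e-6) -> list[FixedPoint]:
    """Locate noise-free fixed points of one isolated area.

    Roots of r_i = phi_i(I_i) are found from a grid of initial rate
    guesses, deduplicated within ``tol`` in S-space, and labelled stable
    when all Jacobian eigenvalue real parts are below -1e-8.
    """
    roots: list[np.ndarray] = []
    for rA0 in rate_grid:
        for rB0 in rate_grid:
            sol = optimize.root(_fp_residual, np.array([rA0, rB0]),
                                args=(params,), method="hybr")
            if not sol.success:
                continue
            r = np.maximum(sol.x, 0.0)
            if np.max(np.abs(_fp_residual(r, params))) > 1e-8:
                continue
            S = np.array([_steady_S_exc(r[0], params), _steady_S_exc(r[1], params)])
            if not any(np.max(np.abs(S - s)) < tol for s in
                       (np.array([_steady_S_exc(q[0], params),
                                  _steady_S_exc(q[1], params)]) for q in roots)):
                roots.append(r)
    if not roots:
        raise RuntimeError("fixed-point search failed from every initial guess")

    out: list[FixedPoint] = []
    p = params
    for r_A, r_B in roots:
        S_A = _steady_S_exc(r_A, p)
        S_B = _steady_S_exc(r_B, p)
        k = p.tau_G * p.gamma_I
        denom = p.g_I - p.c1 * p.J_II * k
        r_C = max((p.c1 * (p.J_IE * (S_A + S_B) + p.I0_C) - p.c0 + p.g_I * p.r0) / denom, 0.0)
        S_C = k * r_C
        v = np.array([S_A, S_B, S_C, 0, 0, 0, r_A, r_B, r_C], dtype=float)
        eig = np.linalg.eigvals(_jacobian(v, p))
        out.append(FixedPoint(S_A, S_B, S_C, float(r_A), float(r_B), float(r_C),
                              stable=bool(np.all(eig.real < -1e-8)),
                              eigenvalues=eig))
    out.sort(key=lambda fp: fp.r_A + fp.r_B)
    return out


def spontaneous_state(params: LocalCircuitParams) -> AreaState:
    """The low-rate symmetric fixed point of the isolated area."""
    fps = find_fixed_points(params)
    stable = [fp for fp in fps if fp.stable]
    fp = min(stable, key=lambda f: f.r_A + f.r_B)
    return AreaState(S_A=fp.S_A, S_B=fp.S_B, S_C=fp.S_C,
                     r_A=fp.r_A, r_B=fp.r_B, r_C=fp.r_C)


def _n_stable(params: LocalCircuitParams) -> int:
    return sum(fp.stable for fp in find_fixed_points(params))


def critical_coupling_scan(params: LocalCircuitParams,
                           Js_range: tuple[float, float] = (0.40, 0.52),
                           co_vary_JIE: bool = True,
                           tol: float = 1e-4) -> float:
    """Smallest J_s at which the isolated area becomes bistable.

    With ``co_vary_JIE`` the excitatory-to-inhibitory coupling is
    re-balanced at every probed J_s so that the spontaneous state stays
    fixed; otherwise J_IE keeps its value from ``params``.  Refined by
    bisection to within ``tol`` (nA).
    """
    from .gradients import compute_balance_constants, balance_jie

    constants = compute_balance_constants(params) if co_vary_JIE else None

    def with_js(J_s: float) -> LocalCircuitParams:
        if co_vary_JIE:
            return params.replace(J_s=J_s, J_IE=balance_jie(J_s, constants, params))
        return params.replace(J_s=J_s)

    lo, hi = Js_range
    if _n_stable(with_js(lo)) > 1 or _n_stable(with_js(hi)) < 2:
        raise ValueError(
            f"Js_range {Js_range} does not bracket the monostable->bistable transition")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _n_stable(with_js(mid)) > 1:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
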