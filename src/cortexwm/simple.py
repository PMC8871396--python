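"""Simplified fully connected excitatory network with a coupling gradient.

A minimal caricature of the full model: N excitatory nodes with
sigmoidal transfer, each with a self-coupling J_i drawn from a gradient
(linear, or saturating like the spine-count curve), all-to-all coupled
with uniform strength G.  No node is bistable in isolation; distributed
memory states appear from the collective coupling.  A feedforward /
feedback asymmetry (stronger low-to-high links, weaker high-to-low)
stands in for the counterstream inhibitory bias of the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "SimpleNetSpec", "linear_gradient", "saturating_gradient",
    "simulate_simple_network", "meanfield_solutions",
    "isolated_critical_coupling", "count_bistable_areas",
]


def linear_gradient(n: int, j_lo: float, j_hi: float) -> np.ndarray:
    """Self-couplings equally spaced from j_lo to j_hi."""
    return np.linspace(j_lo, j_hi, n)


def saturating_gradient(n: int, j_lo: float, j_hi: float,
                        half_point: float = 0.08) -> np.ndarray:
    """Gradient that rises fast then plateaus, like the spine-count curve.

    Shape x / (x + half_point), min-max rescaled to [j_lo, j_hi]; with
    ``half_point`` ~0.2 the top half of the nodes have nearly equal
    couplings, mimicking the saturation of spine counts in association
    cortex.
    """
    x = np.linspace(0.0, 1.0, n)
    s = x / (x + half_point)
    s = (s - s[0]) / (s[-1] - s[0])
    return j_lo + (j_hi - j_lo) * s


@dataclass
class SimpleNetSpec:
    """Configuration of the simplified network.

    Rates are normalized to [0, r_max]; couplings are in units of the
    sigmoid input.  ``ff_factor``/``fb_factor`` multiply links going up
    (source below target) / down the gradient.
    """

    N: int = 30
    J: np.ndarray = field(default_factory=lambda: linear_gradient(30, 0.0, 0.42))
    G: float = 0.3
    I: float = 0.25                 # background input
    r_max: float = 1.0              # sigmoid ceiling
    theta: float = 0.5              # sigmoid threshold
    beta: float = 0.07              # sigmoid width (smaller = steeper)
    ff_factor: float = 1.0
    fb_factor: float = 1.0
    tau: float = 0.01               # node time constant (s)

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.size != self.N:
            raise ValueError("J must have one entry per node")
        if self.ff_factor < 1 or self.fb_factor > 1:
            raise ValueError("expected ff_factor >= 1 and fb_factor <= 1")

    @property
    def J_eta0(self) -> float:
        """Mean self-coupling across nodes."""
        return float(self.J.mean())

    def phi(self, x):
        return self.r_max / (1.0 + np.exp(-(np.asarray(x, float) - self.theta) / self.beta))

    def coupling_matrix(self) -> np.ndarray:
        """(N, N) asymmetry multipliers a_ij; zero diagonal."""
        A = np.ones((self.N, self.N))
        iu = np.triu_indices(self.N, 1)   # [i, j] with j > i: higher -> lower
        il = np.tril_indices(self.N, -1)  # j < i: lower -> higher (feedforward)
        A[iu] = self.fb_factor
        A[il] = self.ff_factor
        np.fill_diagonal(A, 0.0)
        return A

    def replace(self, **kw) -> "SimpleNetSpec":
        return replace(self, **kw)


def simulate_simple_network(spec: SimpleNetSpec,
                            init: np.ndarray | float = 0.0,
                            duration: float = 2.0, dt: float = 5e-4,
                            stim: np.ndarray | None = None,
                            stim_window: tuple[float, float] | None = None,
                            record_dt: float = 0.01,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate tau dr_i/dt = -r_i + phi(J_i r_i + (G/(N-1)) sum a_ij r_j + I).

    Deterministic Euler integration.  ``stim`` adds per-node input
    during ``stim_window``.  Returns (time, rates) with rates (T, N).
    """
    N = spec.N
    A = spec.coupling_matrix()
    r = np.full(N, float(init)) if np.isscalar(init) else np.asarray(init, float).copy()
    n_steps = int(round(duration / dt))
    every = max(1, int(round(record_dt / dt)))
    ts, rs = [], []
    gnorm = spec.G / (N - 1)
    for k in range(n_steps):
        x = spec.J * r + gnorm * (A @ r) + spec.I
        if stim is not None and stim_window is not None:
            t = k * dt
            if stim_window[0] <= t < stim_window[1]:
                x = x + stim
        dr = dt / spec.tau * (-r + spec.phi(x))
        if np.max(np.abs(dr)) > 0.2 * spec.r_max:
            raise RuntimeError("integration unstable; reduce dt")
        r = np.clip(r + dr, 0.0, spec.r_max)
        if (k + 1) % every == 0:
            ts.append((k + 1) * dt)
            rs.append(r.copy())
    return np.asarray(ts), np.asarray(rs)


def meanfield_solutions(spec: SimpleNetSpec) -> list[tuple[float, bool]]:
    """Self-consistent network-average rates R = phi((J_eta0 + G) R + I).

    The homogeneous first-order mean field: returns all roots on
    [0, r_max] with a stability flag (slope of the map < 1).  One root
    in the monostable regime; three (two stable, one unstable) when the
    combined coupling J_eta0 + G is strong enough.
    """
    J = spec.J_eta0 + spec.G

    def f(R):
        return spec.phi(J * R + spec.I) - R

    grid = np.linspace(0.0, spec.r_max, 2001)
    vals = f(grid)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(float(optimize.brentq(f, grid[i], grid[i + 1])))
    dedup: list[float] = []
    for r in roots:
        if not any(abs(r - q) < 1e-8 for q in dedup):
            dedup.append(r)
    out = []
    eps = 1e-6
    for r in dedup:
        slope = (f(r + eps) - f(r - eps)) / (2 * eps) + 1.0  # d phi / dR
        out.append((r, bool(slope < 1.0)))
    return out


def isolated_critical_coupling(spec: SimpleNetSpec,
                               bracket: tuple[float, float] = (0.0, 1.0),
                               tol: float = 1e-4) -> float:
    """Smallest self-coupling at which an isolated node becomes bistable.

    The isolated node is monostable-low for small J, bistable in an
    intermediate window, and monostable-high for very large J; this
    returns the lower edge of the bistable window, located by a coarse
    upward scan followed by bisection.
    """

    def n_stable(J):
        s = spec.replace(J=np.full(spec.N, J), G=0.0)
        return sum(st for _, st in meanfield_solutions(s))

    lo, hi = bracket
    if n_stable(lo) > 1:
        raise ValueError("bracket low end is already bistable")
    grid = np.linspace(lo, hi, 41)
    upper = None
    for J in grid[1:]:
        if n_stable(float(J)) > 1:
            upper = float(J)
            break
        lo = float(J)
    if upper is None:
        raise ValueError(f"no bistability found in bracket {bracket}")
    hi = upper
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if n_stable(mid) > 1:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def count_bistable_areas(spec: SimpleNetSpec, G_range,
                         relax_time: float = 3.0, dt: float = 5e-4,
                         rate_gap: float = 0.2) -> np.ndarray:
    """Per-G count of nodes that are bistable in the connected network.

    For each G the network is relaxed from an all-low and an all-high
    initialization; a node counts as bistable when its two settled rates
    differ by more than ``rate_gap * r_max``.
    """
    counts = []
    for G in np.atleast_1d(G_range):
        s = spec.replace(G=float(G))
        _, lo = simulate_simple_network(s, init=0.0, duration=relax_time, dt=dt)
        _, hi = simulate_simple_network(s, init=s.r_max, duration=relax_time, dt=dt)
        gap = np.abs(hi[-1] - lo[-1])
        counts.append(int(np.sum(gap > rate_gap * s.r_max)))
    return np.asarray(counts)
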