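"""Numerical census of distributed attractors and their survival to lesions.

Attractors are sampled by relaxing the noise-free network from many
random initial conditions (random subsets of areas set to an elevated
pool-A state), binarizing the settled activity pattern by area, and
deduplicating.  Identity is the binary spatial pattern only; the
all-spontaneous pattern is not counted as a working-memory attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkModel, relax_batch

__all__ = [
    "AttractorPattern", "CensusResult", "enumerate_attractors",
    "brute_force_census", "participation_index", "size_rate_correlation",
    "silencing_survival",
]


@dataclass
class AttractorPattern:
    """One settled spatial activity pattern."""

    active: np.ndarray            # (N,) bool
    pool: np.ndarray              # (N,) int: 0 = A, 1 = B, -1 inactive
    mean_rates: np.ndarray        # (N,) Hz of the dominant pool
    S: np.ndarray = field(repr=False, default=None)  # (N, 3) conductances

    @property
    def size(self) -> int:
        return int(self.active.sum())

    @property
    def key(self) -> str:
        return "".join("1" if a else "0" for a in self.active)

    @property
    def mean_active_rate(self) -> float:
        if self.size == 0:
            return 0.0
        return float(self.mean_rates[self.active].mean())


@dataclass
class CensusResult:
    """Unique attractors plus sampling metadata."""

    patterns: list[AttractorPattern]
    areas: list[str]
    n_samples: int
    n_converged: int
    n_discarded: int
    relax_time: float
    threshold: float
    seed: int | None
    G: float
    J_max: float

    @property
    def n_attractors(self) -> int:
        return len(self.patterns)

    def sizes(self) -> np.ndarray:
        return np.array([p.size for p in self.patterns], dtype=int)


def _binarize(rates: np.ndarray, threshold: float):
    """rates (B, N, 3) -> (active, pool, dominant-rate) arrays."""
    rA, rB = rates[..., 0], rates[..., 1]
    dom = np.where(rA >= rB, rA, rB)
    pool = np.where(rA >= rB, 0, 1)
    active = dom > threshold
    pool = np.where(active, pool, -1)
    return active, pool, dom


def enumerate_attractors(network: NetworkModel, n_samples: int = 5000,
                         relax_time: float = 20.0,
                         threshold: float | None = None,
                         seed: int | None = None,
                         seed_S: float = 0.3,
                         dt: float = 5e-4,
                         batch: int = 256) -> CensusResult:
    """Sample-and-relax census of the network's stable activity patterns.

    Each sample elevates the pool-A NMDA conductance of a random subset
    of areas (subset size uniform on [1, N]) to ``seed_S`` and relaxes
    the noise-free network for ``relax_time``.  Non-settled samples are
    discarded and counted.  Deterministic given ``seed``.
    """
    N = network.n_areas
    if threshold is None:
        threshold = network.spontaneous["r_A"] + 5.0
    rng = np.random.default_rng(seed)
    sp = network.spontaneous
    base = np.array([sp["S_A"], sp["S_B"], sp["S_C"]])

    found: dict[str, AttractorPattern] = {}
    n_conv = n_disc = 0
    for start in range(0, n_samples, batch):
        B = min(batch, n_samples - start)
        S0 = np.tile(base, (B, N, 1))
        for b in range(B):
            size = rng.integers(1, N + 1)
            subset = rng.choice(N, size=size, replace=False)
            S0[b, subset, 0] = seed_S
        rates, S, ok = relax_batch(network, S0, relax_time=relax_time, dt=dt)
        n_conv += int(ok.sum())
        n_disc += int((~ok).sum())
        active, pool, dom = _binarize(rates, threshold)
        for b in range(B):
            if not ok[b]:
                continue
            if not active[b].any():
                continue  # spontaneous pattern: not a WM attractor
            key = "".join("1" if a else "0" for a in active[b])
            if key not in found:
                found[key] = AttractorPattern(
                    active=active[b].copy(), pool=pool[b].copy(),
                    mean_rates=dom[b].copy(), S=S[b].copy())
    patterns = sorted(found.values(), key=lambda p: (p.size, p.key))
    return CensusResult(patterns=patterns, areas=list(network.areas),
                        n_samples=n_samples, n_converged=n_conv,
                        n_discarded=n_disc, relax_time=relax_time,
                        threshold=float(threshold), seed=seed,
                        G=network.G, J_max=float(network.J_s.max()))


def brute_force_census(network: NetworkModel, relax_time: float = 20.0,
                       threshold: float | None = None, seed_S: float = 0.3,
                       dt: float = 5e-4) -> CensusResult:
    """Exhaustive relaxation from all 2^N binary pool-A seed patterns.

    Tractable only for toy networks (N <= ~12); serves as the oracle
    against which the sampling census is checked.
    """
    N = network.n_areas
    if N > 14:
        raise ValueError("brute force is limited to small networks")
    if threshold is None:
        threshold = network.spontaneous["r_A"] + 5.0
    sp = network.spontaneous
    base = np.array([sp["S_A"], sp["S_B"], sp["S_C"]])
    B = 2 ** N
    S0 = np.tile(base, (B, N, 1))
    for b in range(B):
        for i in range(N):
            if (b >> i) & 1:
                S0[b, i, 0] = seed_S
    rates, S, ok = _relax_all(network, S0, relax_time, dt)
    active, pool, dom = _binarize(rates, threshold)
    found: dict[str, AttractorPattern] = {}
    for b in range(B):
        if not ok[b] or not active[b].any():
            continue
        key = "".join("1" if a else "0" for a in active[b])
        if key not in found:
            found[key] = AttractorPattern(active[b].copy(), pool[b].copy(),
                                          dom[b].copy(), S[b].copy())
    patterns = sorted(found.values(), key=lambda p: (p.size, p.key))
    return CensusResult(patterns=patterns, areas=list(network.areas),
                        n_samples=B, n_converged=int(ok.sum()),
                        n_discarded=int((~ok).sum()), relax_time=relax_time,
                        threshold=float(threshold), seed=None,
                        G=network.G, J_max=float(network.J_s.max()))


def _relax_all(network, S0, relax_time, dt, silenced=None):
    return relax_batch(network, S0, relax_time=relax_time, dt=dt,
                       silenced=silenced)


def participation_index(census: CensusResult) -> np.ndarray:
    """Fraction of unique attractors in which each area is active."""
    if census.n_attractors == 0:
        import warnings
        warnings.warn("empty census: participation index undefined")
        return np.zeros(len(census.areas))
    mat = np.stack([p.active for p in census.patterns])
    return mat.mean(axis=0)


def size_rate_correlation(census: CensusResult) -> float:
    """Pearson correlation between attractor size and mean active-area rate."""
    if census.n_attractors < 3:
        raise ValueError("need at least 3 attractors for a correlation")
    sizes = census.sizes().astype(float)
    rates = np.array([p.mean_active_rate for p in census.patterns])
    if np.std(sizes) == 0 or np.std(rates) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    return float(np.corrcoef(sizes, rates)[0, 1])


def silencing_survival(network: NetworkModel, census: CensusResult,
                       silenced_sets: list[list[str]],
                       relax_time: float = 10.0, dt: float = 5e-4,
                       ) -> list[float]:
    """Percent of attractors that survive clamping each area set off.

    Every attractor of the intact census is re-relaxed with the given
    areas silenced; it survives if the settled pattern still has a
    nonempty active set.  Returns one percentage per silenced set.
    """
    out = []
    if census.n_attractors == 0:
        return [100.0 for _ in silenced_sets]
    S_all = np.stack([p.S for p in census.patterns])
    for areas in silenced_sets:
        mask = np.zeros(network.n_areas, dtype=bool)
        for a in areas:
            mask[network.index(a)] = True
        S0 = S_all.copy()
        S0[:, mask, :] = 0.0
        rates, _, ok = relax_batch(network, S0, relax_time=relax_time, dt=dt,
                                   silenced=mask)
        active, _, _ = _binarize(rates, census.threshold)
        survived = ok & active.any(axis=1)
        out.append(100.0 * float(survived.mean()))
    return out
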