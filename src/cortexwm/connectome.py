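"""Anatomical substrate: FLN/SLN matrices, weight assembly, synthetic data.

Matrix convention throughout: rows index the TARGET area and columns the
SOURCE area, so ``FLN[x, y]`` is the strength of the projection y -> x.
FLN (fraction of labelled neurons) spans roughly five orders of
magnitude and is rescaled by a power law before use; SLN (fraction of
supragranular labelled neurons) in [0, 1] encodes the feedforward (near
1) versus feedback (near 0) character of each projection and routes
feedback preferentially onto the inhibitory population (counterstream
inhibitory bias, CIB).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import BalanceConstants, GradientSpec

__all__ = [
    "CANONICAL_AREAS",
    "ConnectomeBundle",
    "ProjectionWeights",
    "load_connectome",
    "save_connectome",
    "rescale_fln",
    "assemble_projection_weights",
    "generate_synthetic_connectome",
    "shuffle_projection_weights",
]

#: The 30 modelled areas in anatomical-hierarchy order (V1 lowest).
CANONICAL_AREAS = [
    "V1", "V2", "V4", "DP", "MT", "8m", "5", "8l", "2", "TEO",
    "F1", "STPc", "7A", "46d", "10", "9/46v", "9/46d", "F5", "TEpd", "PBr",
    "7m", "LIP", "F2", "7B", "ProM", "STPi", "F7", "8B", "STPr", "24c",
]


def _norm_name(name: str) -> str:
    """Case/whitespace/punctuation-insensitive key for area-name matching."""
    return re.sub(r"[\s.\-_]+", "", str(name)).lower()


_CANON_BY_KEY = {_norm_name(a): a for a in CANONICAL_AREAS}


def canonical_area_name(name: str) -> str:
    """Map a loosely written area name ('9/46 v', '7a') to its canonical form."""
    key = _norm_name(name)
    if key not in _CANON_BY_KEY:
        raise KeyError(f"unknown area name: {name!r}")
    return _CANON_BY_KEY[key]


@dataclass
class ConnectomeBundle:
    """Area names plus FLN/SLN matrices (rows = target, cols = source).

    ``excitability`` is an optional per-area proxy for local recurrent
    strength on [0, 1] (the role spine counts play for the real data);
    when absent, the SLN-derived hierarchy is used in its place.
    """

    areas: list[str]
    FLN: np.ndarray
    SLN: np.ndarray
    distances: np.ndarray | None = None
    excitability: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def index(self, area: str) -> int:
        key = _norm_name(area)
        for i, a in enumerate(self.areas):
            if _norm_name(a) == key:
                return i
        raise KeyError(f"area {area!r} not in bundle")

    def validate(self) -> "ConnectomeBundle":
        n = self.n_areas
        for name, M in (("FLN", self.FLN), ("SLN", self.SLN)):
            if M.shape != (n, n):
                raise ValueError(f"{name} shape {M.shape} != ({n}, {n})")
        if np.any(np.diag(self.FLN) != 0):
            i = int(np.nonzero(np.diag(self.FLN))[0][0])
            raise ValueError(f"FLN diagonal must be zero (area {self.areas[i]})")
        if np.any(self.FLN < 0):
            x, y = np.argwhere(self.FLN < 0)[0]
            raise ValueError(
                f"negative FLN at [{self.areas[x]}, {self.areas[y]}]")
        bad = (self.SLN < 0) | (self.SLN > 1)
        if np.any(bad):
            x, y = np.argwhere(bad)[0]
            raise ValueError(
                f"SLN out of [0, 1] at [{self.areas[x]}, {self.areas[y]}] "
                f"= {self.SLN[x, y]}")
        if np.any((self.FLN > 0) & ~np.isfinite(self.SLN)):
            raise ValueError("SLN must be defined wherever FLN > 0")
        return self


def load_connectome(path: str | Path) -> ConnectomeBundle:
    """Read a bundle from ``<path>/fln.csv`` and ``<path>/sln.csv``.

    Each CSV has a header row and an index column of area names.  A
    ``meta.json`` sidecar, if present, is attached verbatim.  Area names
    are matched case/punctuation-insensitively against the canonical
    list when the bundle has 30 areas.
    """
    path = Path(path)
    fln = pd.read_csv(path / "fln.csv", index_col=0)
    sln = pd.read_csv(path / "sln.csv", index_col=0)
    if list(fln.index) != list(fln.columns):
        raise ValueError("fln.csv row and column names differ")
    if list(sln.index) != list(fln.index):
        raise ValueError("sln.csv area names differ from fln.csv")
    areas = [str(a) for a in fln.index]
    if len(areas) == len(CANONICAL_AREAS):
        try:
            areas = [canonical_area_name(a) for a in areas]
        except KeyError:
            pass  # synthetic bundles may use their own names
    meta = {}
    mp = path / "meta.json"
    if mp.exists():
        meta = json.loads(mp.read_text())
    bundle = ConnectomeBundle(areas, fln.to_numpy(dtype=float),
                              sln.to_numpy(dtype=float), meta=meta)
    return bundle.validate()


def save_connectome(bundle: ConnectomeBundle, path: str | Path) -> None:
    """Write ``fln.csv``, ``sln.csv`` and ``meta.json`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = "# rows = target area, columns = source area\n"
    for name, M in (("fln", bundle.FLN), ("sln", bundle.SLN)):
        df = pd.DataFrame(M, index=bundle.areas, columns=bundle.areas)
        with open(path / f"{name}.csv", "w") as f:
            df.to_csv(f)
    (path / "meta.json").write_text(json.dumps(bundle.meta, indent=1))


def rescale_fln(FLN: np.ndarray, k1: float = 1.2, k2: float = 0.3,
                normalize: bool = True) -> np.ndarray:
    """Compress the FLN dynamic range: W = k1 * FLN**k2 elementwise.

    With ``normalize`` each target row is first scaled so its incoming
    FLN sums to one (controls in-degree heterogeneity); zeros stay zero.
    """
    if k2 <= 0:
        raise ValueError("power-law exponent k2 must be positive")
    FLN = np.asarray(FLN, dtype=float)
    if np.any(FLN < 0):
        raise ValueError("FLN must be non-negative")
    M = FLN.copy()
    if normalize:
        row = M.sum(axis=1, keepdims=True)
        row[row == 0] = 1.0
        M = M / row
    W = np.zeros_like(M)
    pos = M > 0
    W[pos] = k1 * M[pos] ** k2
    return W


@dataclass
class ProjectionWeights:
    """Long-range weight matrices after gradient scaling and CIB routing.

    ``W_EE[x, y]`` drives the like-selective excitatory pools of target
    x from source y (feedforward-weighted by SLN); ``W_EI`` drives the
    inhibitory pool (feedback-weighted by 1 - SLN, multiplied by the
    balancing factor Z and the global coupling G at simulation time).
    """

    areas: list[str]
    W_EE: np.ndarray
    W_EI: np.ndarray
    G: float = 0.48
    cib_scale: float = 1.0
    fef_cap: float = 0.4


def assemble_projection_weights(bundle: ConnectomeBundle, W: np.ndarray,
                                gradient: GradientSpec,
                                constants: BalanceConstants,
                                G: float = 0.48, cib_scale: float = 1.0,
                                fef_cap: float = 0.4,
                                fef_targets: tuple[str, ...] = ("8l", "8m"),
                                fef_sources: list[str] | None = None,
                                ) -> ProjectionWeights:
    """Split rescaled weights into excitatory and inhibitory pathways.

    The target-side gradient multiplies each row by J_s^x / J_max so
    long-range input follows the same macroscopic gradient as local
    recurrence.  The inhibitory fraction min(cib_scale * (1 - SLN), cap)
    is capped at ``fef_cap`` for projections onto the frontal eye field
    areas (optionally only from ``fef_sources``) and at 1 elsewhere.
    """
    n = bundle.n_areas
    if len(gradient.J_s) != n:
        raise ValueError("gradient does not cover all areas")
    Wg = (gradient.J_s / gradient.J_max)[:, None] * np.asarray(W, dtype=float)
    SLN = np.nan_to_num(bundle.SLN, nan=0.5)
    cap = np.ones((n, 1))
    for t in fef_targets:
        try:
            cap[bundle.index(t), 0] = fef_cap
        except KeyError:
            if bundle.n_areas == len(CANONICAL_AREAS):
                raise
            # synthetic bundles without FEF areas: cap is a no-op
    cap_mat = np.broadcast_to(cap, (n, n)).copy()
    if fef_sources is not None:
        src = np.array([any(_norm_name(a) == _norm_name(s) for s in fef_sources)
                        for a in bundle.areas])
        cap_mat[:, ~src] = 1.0
        for t in fef_targets:
            cap_mat[bundle.index(t), ~src] = 1.0
    inh_frac = np.minimum(cib_scale * (1.0 - SLN), cap_mat)
    W_EE = Wg * SLN
    W_EI = Wg * inh_frac
    return ProjectionWeights(areas=list(bundle.areas), W_EE=W_EE, W_EI=W_EI,
                             G=G, cib_scale=cib_scale, fef_cap=fef_cap)


#: Generator seed of the packaged reference surrogate connectome.
REFERENCE_SEED = 1


def generate_synthetic_connectome(n_areas: int = 30, density: float = 0.66,
                                  seed: int | None = None,
                                  sln_slope: float = 12.0,
                                  hierarchy_compression: float = 0.45,
                                  n_strong: int = 2,
                                  strong_log10: tuple[float, float] = (-1.2, 0.3),
                                  weak_log10: tuple[float, float] = (-6.0, -3.0),
                                  excitability_half: float = 0.25,
                                  excitability_noise: float = 0.06,
                                  ) -> ConnectomeBundle:
    """Surrogate connectome with the statistical structure of the real one.

    Three empirical regularities of the macaque tracing data are
    emulated.  (1) The latent anatomical hierarchy compresses toward its
    top: H_i = (i/(n-1))**hierarchy_compression, so sensory areas are
    separated by large hierarchical steps while association areas
    cluster.  (2) Weights follow the exponential distance rule: each
    target's ``n_strong`` hierarchically nearest sources carry dominant
    FLN (log10 ~ N(strong_log10)), all other existing projections carry
    trace weights (log10 ~ U(weak_log10)); positive entries span more
    than four orders of magnitude.  (3) SLN of a projection y -> x is
    logistic(sln_slope * (H_x - H_y)): long ascending projections are
    almost purely feedforward (SLN near 1), long descending ones almost
    purely feedback, and projections within the association cluster stay
    near 0.5 — which is what keeps the counterstream inhibitory bias
    from destabilizing the resting state of strongly coupled areas.

    The per-area excitability proxy (the role spine counts play for the
    real data) is a noisy saturating function of hierarchical rank,
    x / (x + half), min-max rescaled: it rises quickly and plateaus, as
    measured spine counts do.  Directed edges exist with probability
    ``density``; everything is reproducible from ``seed``.
    """
    if n_areas < 2:
        raise ValueError("need at least two areas")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if n_areas == len(CANONICAL_AREAS):
        areas = list(CANONICAL_AREAS)
    else:
        areas = [f"A{i:02d}" for i in range(n_areas)]
    x = np.linspace(0.0, 1.0, n_areas)
    H = x ** hierarchy_compression
    exists = rng.random((n_areas, n_areas)) < density
    np.fill_diagonal(exists, False)
    dH = np.abs(H[:, None] - H[None, :])
    FLN = np.zeros((n_areas, n_areas))
    mu, msig = strong_log10
    for t in range(n_areas):
        src = np.nonzero(exists[t])[0]
        if src.size == 0:
            continue
        order = src[np.argsort(dH[t, src], kind="stable")]
        ns = min(n_strong, src.size)
        FLN[t, order[:ns]] = 10.0 ** rng.normal(mu, msig, ns)
        if src.size > ns:
            FLN[t, order[ns:]] = 10.0 ** rng.uniform(*weak_log10, src.size - ns)
    FLN = np.clip(FLN, 0.0, 0.95)
    dHs = H[:, None] - H[None, :]  # target minus source
    SLN = np.where(exists, 1.0 / (1.0 + np.exp(-sln_slope * dHs)), 0.0)
    g = x / (x + excitability_half)
    g = g + rng.normal(0.0, excitability_noise, n_areas)
    g[0] = 0.0  # the bottom sensory area anchors the gradient
    g = np.clip(g, 0.0, None)
    g = (g - g.min()) / (g.max() - g.min())
    bundle = ConnectomeBundle(
        areas, FLN, SLN, excitability=g,
        meta={"synthetic": True, "seed": seed, "density": density,
              "sln_slope": sln_slope,
              "hierarchy_compression": hierarchy_compression,
              "latent_hierarchy": H.tolist()})
    return bundle.validate()


def reference_connectome() -> ConnectomeBundle:
    """The packaged reference surrogate: one fixed synthetic connectome.

    The study conditions use a single anatomical substrate, exactly as
    the original analyses use a single tracing dataset; this returns the
    generator's output for the fixed ``REFERENCE_SEED``.
    """
    return generate_synthetic_connectome(seed=REFERENCE_SEED)


def shuffle_projection_weights(W: np.ndarray, seed: int | None = None) -> np.ndarray:
    """Permute the positive off-diagonal entries of W among themselves.

    The multiset of positive weights is preserved; absent projections
    (zeros) stay absent.  Used to test whether results depend on which
    projection carries which strength.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    out = W.copy()
    mask = (W > 0) & ~np.eye(W.shape[0], dtype=bool)
    vals = out[mask]
    rng = np.random.default_rng(seed)
    out[mask] = rng.permutation(vals)
    return out
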