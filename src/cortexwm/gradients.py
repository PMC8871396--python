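"""Macroscopic gradient of synaptic excitation across the cortical hierarchy.

Sensory areas have sparse dendritic spines (weak local recurrence) and
association areas dense ones; the model captures this with a per-area
self-coupling J_s^i interpolated between J_min and J_max by a normalized
hierarchy value h_i in [0, 1].  The hierarchy itself is estimated from
laminar projection data: the fraction of supragranular labelled neurons
(SLN) of a projection is modelled as a logistic function of the
difference in hierarchical value between target and source.

To keep the spontaneous state identical across areas despite the J_s
gradient, the excitatory-to-inhibitory coupling J_IE is co-varied so the
invariant drive J_0 = J_s + J_c + 2 J_EI J_IE zeta stays constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .local import LocalCircuitParams

__all__ = [
    "SpineRecord",
    "HierarchyAssignment",
    "BalanceConstants",
    "GradientSpec",
    "load_spine_table",
    "correct_spine_counts",
    "fit_hierarchy_from_sln",
    "spine_based_hierarchy",
    "build_js_gradient",
    "compute_balance_constants",
    "balance_jie",
]


@dataclass
class SpineRecord:
    """Spine count of layer 2/3 basal dendrites for one area.

    ``age_factor`` corrects counts measured in aged animals upward
    (spine density declines roughly 30% per decade); missing counts stay
    missing and are later filled from the hierarchy.
    """

    area: str
    measured_count: float | None
    age_factor: float | None
    corrected_count: float | None = None


@dataclass
class HierarchyAssignment:
    """Raw (H) and normalized (h = H/H_max, in [0, 1]) hierarchy values."""

    areas: list[str]
    H: np.ndarray
    h: np.ndarray
    source: list[str]  # per-area: "spine-derived" | "hierarchy-proxy" | "sln-fit"

    def value(self, area: str) -> float:
        return float(self.h[self.areas.index(area)])


@dataclass
class BalanceConstants:
    """Analytic constants of the spontaneous-state balance condition.

    zeta converts excitatory drive into inhibitory conductance (1/nA),
    beta is the residual offset conductance, J0 the invariant excitatory
    drive (nA), and Z the factor that balances long-range excitatory and
    inhibitory projections in the target area.
    """

    zeta: float
    beta: float
    J0: float
    Z: float


@dataclass
class GradientSpec:
    """Per-area self-coupling and balanced E->I coupling along the gradient."""

    areas: list[str]
    J_min: float
    J_max: float
    J_s: np.ndarray
    J_IE: np.ndarray


def load_spine_table() -> pd.DataFrame:
    """Spine-count table packaged with the model (area, count, age factor)."""
    with resources.files("cortexwm.data").joinpath("spine_counts.csv").open() as f:
        return pd.read_csv(f, comment="#")


def correct_spine_counts(records: list[SpineRecord]) -> list[SpineRecord]:
    """Apply age-correction factors: corrected = measured x factor.

    Missing measurements remain missing (they are filled later from the
    hierarchy fit).  Negative counts are rejected.
    """
    out = []
    for rec in records:
        if rec.measured_count is None or (isinstance(rec.measured_count, float)
                                          and np.isnan(rec.measured_count)):
            out.append(SpineRecord(rec.area, None, None, None))
            continue
        if rec.measured_count < 0:
            raise ValueError(f"negative spine count for area {rec.area}")
        if rec.age_factor is None or rec.age_factor < 1:
            raise ValueError(f"age factor missing or < 1 for area {rec.area}")
        out.append(SpineRecord(rec.area, rec.measured_count, rec.age_factor,
                               rec.measured_count * rec.age_factor))
    return out


def fit_hierarchy_from_sln(SLN: np.ndarray, FLN: np.ndarray,
                           areas: list[str] | None = None,
                           fln_weighted: bool = False) -> HierarchyAssignment:
    """Estimate hierarchy values from laminar projection fractions.

    For every existing projection (FLN > 0) from source j to target i the
    observed SLN is modelled as logistic(H_i - H_j); the per-area H are
    the coefficients of a binomial GLM with logit link on signed
    indicator covariates.  The gauge is fixed by anchoring the minimum H
    to zero; h = H / H_max.  With ``fln_weighted`` each projection is
    weighted by its FLN.
    """
    SLN = np.asarray(SLN, dtype=float)
    FLN = np.asarray(FLN, dtype=float)
    n = SLN.shape[0]
    if areas is None:
        areas = [f"A{i}" for i in range(n)]
    tgt, src = np.nonzero(FLN > 0)
    y = SLN[tgt, src]
    if y.size == 0:
        warnings.warn("no projections: returning a flat hierarchy")
        return HierarchyAssignment(list(areas), np.zeros(n), np.zeros(n),
                                   ["sln-fit"] * n)

    if y.size > 1 and np.allclose(y, y[0]):
        if not np.isclose(y[0], 0.5):
            warnings.warn("degenerate SLN (all equal); returning a flat hierarchy")
        H = np.zeros(n)
        return HierarchyAssignment(list(areas), H, np.zeros(n), ["sln-fit"] * n)

    # design: +1 at target, -1 at source; drop the first column as gauge
    X = np.zeros((y.size, n))
    X[np.arange(y.size), tgt] += 1.0
    X[np.arange(y.size), src] -= 1.0
    X = X[:, 1:]
    w = FLN[tgt, src] if fln_weighted else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
        res = model.fit()
    H = np.concatenate([[0.0], res.params])
    H = H - H.min()
    h = H / H.max() if H.max() > 0 else np.zeros(n)
    return HierarchyAssignment(list(areas), H, h, ["sln-fit"] * n)


def spine_based_hierarchy(records: list[SpineRecord],
                          sln_fit: HierarchyAssignment) -> HierarchyAssignment:
    """Gradient values from corrected spine counts, hierarchy as fallback.

    Areas with spine data get h proportional to the age-corrected count
    (min-max scaled).  Areas without data are filled from a linear
    regression of corrected counts on the SLN-derived hierarchy position,
    then the whole vector is re-normalized to [0, 1].
    """
    areas = [r.area for r in records]
    if areas != sln_fit.areas:
        raise ValueError("spine records and hierarchy fit must list the same areas")
    counts = np.array([np.nan if r.corrected_count is None else r.corrected_count
                       for r in records], dtype=float)
    have = ~np.isnan(counts)
    if have.sum() < 2:
        raise ValueError("need at least two areas with spine data")
    slope, intercept = np.polyfit(sln_fit.h[have], counts[have], 1)
    filled = counts.copy()
    filled[~have] = intercept + slope * sln_fit.h[~have]
    H = filled - filled.min()
    h = H / H.max()
    source = ["spine-derived" if p else "hierarchy-proxy" for p in have]
    return HierarchyAssignment(list(areas), H, h, source)


def build_js_gradient(h, J_min: float = 0.21, J_max: float = 0.42) -> np.ndarray:
    """Per-area self-coupling J_s^i = J_min + (J_max - J_min) h_i."""
    if J_max < J_min:
        raise ValueError("J_max must be >= J_min")
    h = np.asarray(getattr(h, "h", h), dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("hierarchy values must lie in [0, 1]")
    return J_min + (J_max - J_min) * h


def compute_balance_constants(params: LocalCircuitParams | None = None) -> BalanceConstants:
    """Closed-form constants of the equal-spontaneous-state condition.

    Derived by adiabatically eliminating the fast GABA variables: the
    inhibitory conductance tracks the excitatory drive linearly with
    slope 2 J_IE zeta and offset beta, giving an effective excitatory
    drive J_s + J_c + 2 J_EI J_IE zeta = J_0 that is held constant
    across areas.  Z rebalances long-range projections onto inhibition
    so that unselective long-range input cancels.
    """
    p = params or LocalCircuitParams()
    k = p.tau_G * p.gamma_I * p.c1  # conductance gain of the I pathway
    denom = p.g_I - p.J_II * k
    if abs(denom) < 1e-12:
        raise ValueError("degenerate parameters: g_I - J_II tau_G gamma_I c1 = 0")
    zeta = k / denom
    beta = p.tau_G * p.gamma_I * (p.c1 * p.I0_C + p.g_I * p.r0 - p.c0) / denom
    J0 = p.J_s + p.J_c + 2 * p.J_EI * p.J_IE * zeta
    Z = 2 * p.c1 * p.tau_G * p.gamma_I * p.J_EI / (p.c1 * p.tau_G * p.gamma_I * p.J_II - p.g_I)
    return BalanceConstants(zeta=zeta, beta=beta, J0=J0, Z=Z)


def balance_jie(J_s, constants: BalanceConstants,
                params: LocalCircuitParams | None = None):
    """Balanced E->I coupling J_IE = (J0 - J_s - J_c) / (2 J_EI zeta).

    Keeps the spontaneous fixed point identical for any J_s in the valid
    range J_s >= J0 - J_c (below it the formula would require J_IE < 0).
    """
    p = params or LocalCircuitParams()
    J_s = np.asarray(J_s, dtype=float)
    J_IE = (constants.J0 - J_s - p.J_c) / (2 * p.J_EI * constants.zeta)
    if np.any(J_IE < -1e-12):
        bad = float(np.min(J_IE))
        raise ValueError(
            f"J_s below validity bound J0 - J_c = {constants.J0 - p.J_c:.4f} nA "
            f"would need negative J_IE = {bad:.4f} nA")
    J_IE = np.maximum(J_IE, 0.0)
    return float(J_IE) if J_IE.ndim == 0 else J_IE


def build_gradient_spec(h, areas: list[str],
                        J_min: float = 0.21, J_max: float = 0.42,
                        params: LocalCircuitParams | None = None) -> GradientSpec:
    """Bundle per-area J_s (linear in h) with balanced J_IE."""
    p = params or LocalCircuitParams()
    J_s = build_js_gradient(h, J_min, J_max)
    constants = compute_balance_constants(p)
    J_IE = balance_jie(J_s, constants, p)
    return GradientSpec(areas=list(areas), J_min=J_min, J_max=J_max,
                        J_s=J_s, J_IE=np.asarray(J_IE))
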