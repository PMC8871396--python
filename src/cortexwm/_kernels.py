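"""Numba-accelerated deterministic relaxation kernel for the census.

The attractor census relaxes thousands of initial conditions; the
jitted kernel integrates a whole batch with noise off.  Results agree
with the pure-numpy stepper to floating-point roundoff (same update
order and arithmetic).  If numba is unavailable the caller falls back
to the numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep of the env
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@njit(cache=True)
def _phi_exc(x, d):
    # x = a*I - b; removable singularity at 0 handled by series
    if abs(x) < 1e-6:
        return 1.0 / d + x / 2.0 + d * x * x / 12.0
    return x / (1.0 - np.exp(-d * x))


@njit(cache=True)
def relax_kernel(S, r, W_EE_T, W_EI_T, J_s, J_IE,
                 J_c, J_EI, J_II, I0_A, I0_B, I0_C,
                 a, b, d, g_I, c1, c0, r0,
                 tau_N, tau_G, tau_r, gamma, gamma_I,
                 G, Z, dt, n_steps, check_step, silenced):
    """Integrate a (B, N, 3) batch in place; returns rates at check_step.

    ``silenced`` is an int8 mask of areas clamped to zero.  The GABA
    threshold-linear transfer adds the baseline r0 after the gain
    division (rectified argument c1*I - c0 + g_I*r0).
    """
    B, N, _ = S.shape
    r_check = np.zeros((B, N, 3))
    for k in range(n_steps):
        SA = np.ascontiguousarray(S[:, :, 0])
        SB = np.ascontiguousarray(S[:, :, 1])
        InetA = G * np.dot(SA, W_EE_T)
        InetB = G * np.dot(SB, W_EE_T)
        InetC = G * Z * np.dot(SA + SB, W_EI_T)
        for i in range(B):
            for j in range(N):
                sA = S[i, j, 0]
                sB = S[i, j, 1]
                sC = S[i, j, 2]
                I_A = J_s[j] * sA + J_c * sB + J_EI * sC + I0_A + InetA[i, j]
                I_B = J_c * sA + J_s[j] * sB + J_EI * sC + I0_B + InetB[i, j]
                I_C = (J_IE[j] * (sA + sB) + J_II * sC + I0_C + InetC[i, j])
                phiA = _phi_exc(a * I_A - b, d)
                phiB = _phi_exc(a * I_B - b, d)
                argC = c1 * I_C - c0 + g_I * r0
                phiC = argC / g_I if argC > 0.0 else 0.0

                nA = sA + dt * (-sA / tau_N + gamma * (1.0 - sA) * r[i, j, 0])
                nB = sB + dt * (-sB / tau_N + gamma * (1.0 - sB) * r[i, j, 1])
                nC = sC + dt * (-sC / tau_G + gamma_I * r[i, j, 2])
                S[i, j, 0] = min(max(nA, 0.0), 1.0)
                S[i, j, 1] = min(max(nB, 0.0), 1.0)
                S[i, j, 2] = max(nC, 0.0)

                r[i, j, 0] = max(r[i, j, 0] + dt / tau_r * (-r[i, j, 0] + phiA), 0.0)
                r[i, j, 1] = max(r[i, j, 1] + dt / tau_r * (-r[i, j, 1] + phiB), 0.0)
                r[i, j, 2] = max(r[i, j, 2] + dt / tau_r * (-r[i, j, 2] + phiC), 0.0)

                if silenced[j] == 1:
                    S[i, j, 0] = 0.0
                    S[i, j, 1] = 0.0
                    S[i, j, 2] = 0.0
                    r[i, j, 0] = 0.0
                    r[i, j, 1] = 0.0
                    r[i, j, 2] = 0.0
        if k == check_step:
            r_check[:, :, :] = r
    return r_check
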