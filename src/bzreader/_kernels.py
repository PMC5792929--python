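"""Numba-compiled right-hand sides and Jacobians for network integration.

Every node carries five state variables (x, y, z, v, ag); nodes that never
receive excitatory pulses simply keep ag = 0, which reproduces the
four-variable model exactly.  Parameters arrive as flat vectors in the order
of :data:`bzreader.kinetics.PARAM_NAMES`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the parameter vector
K1, K2, K3, K4, K9P, K10, K13, K0, Y0, C0, CMIN, KDIFF = range(12)

NVAR = 5


@njit(cache=True)
def cell_rhs(s, P, inh, exc, out):
    x, y, z, v, ag = s[0], s[1], s[2], s[3], s[4]
    D = P[C0] - z
    q = P[K4] * x * D / (D + P[CMIN])
    scav = P[KDIFF] * ag * y
    out[0] = -P[K1] * x * y + P[K2] * y - 2.0 * P[K3] * x * x + q - P[K0] * x
    out[1] = (-P[K1] * x * y - P[K2] * y + P[K9P] * v * z
              - P[K0] * (y - P[Y0]) + inh - scav)
    out[2] = 2.0 * q - P[K9P] * v * z - P[K10] * z
    out[3] = (2.0 * P[K1] * x * y + P[K2] * y + P[K3] * x * x
              - P[K9P] * v * z - P[K13] * v - P[K0] * v)
    out[4] = exc - scav


@njit(cache=True)
def cell_jac(s, P, J):
    """5x5 Jacobian block of one cell (drive terms are state-independent)."""
    x, y, z, v, ag = s[0], s[1], s[2], s[3], s[4]
    D = P[C0] - z
    S = D + P[CMIN]
    J[:, :] = 0.0
    J[0, 0] = -P[K1] * y - 4.0 * P[K3] * x + P[K4] * D / S - P[K0]
    J[0, 1] = -P[K1] * x + P[K2]
    J[0, 2] = -P[K4] * x * P[CMIN] / (S * S)
    J[1, 0] = -P[K1] * y
    J[1, 1] = -P[K1] * x - P[K2] - P[K0] - P[KDIFF] * ag
    J[1, 2] = P[K9P] * v
    J[1, 3] = P[K9P] * z
    J[1, 4] = -P[KDIFF] * y
    J[2, 0] = 2.0 * P[K4] * D / S
    J[2, 2] = -2.0 * P[K4] * x * P[CMIN] / (S * S) - P[K9P] * v - P[K10]
    J[2, 3] = -P[K9P] * z
    J[3, 0] = 2.0 * P[K1] * y + 2.0 * P[K3] * x
    J[3, 1] = 2.0 * P[K1] * x + P[K2]
    J[3, 2] = -P[K9P] * v
    J[3, 3] = -P[K9P] * z - P[K13] - P[K0]
    J[4, 1] = -P[KDIFF] * ag
    J[4, 4] = -P[KDIFF] * y


@njit(cache=True)
def network_rhs(Y, Pmat, inh, exc):
    n = Pmat.shape[0]
    out = np.empty(n * NVAR)
    for i in range(n):
        cell_rhs(Y[i * NVAR:(i + 1) * NVAR], Pmat[i], inh[i], exc[i],
                 out[i * NVAR:(i + 1) * NVAR])
    return out


@njit(cache=True)
def network_jac(Y, Pmat):
    n = Pmat.shape[0]
    J = np.zeros((n * NVAR, n * NVAR))
    for i in range(n):
        a = i * NVAR
        cell_jac(Y[a:a + NVAR], Pmat[i], J[a:a + NVAR, a:a + NVAR])
    return J
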