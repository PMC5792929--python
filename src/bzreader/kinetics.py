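"""Four-variable kinetic model of a single Belousov-Zhabotinsky (BZ) cell.

The model tracks the activator x = [HBrO2], the inhibitor y = [Br-], the
oxidised catalyst z and bromomalonic acid v = [BrMA], all in molar units with
time in seconds.  Cells that receive excitatory pulses carry a fifth variable,
the silver-ion concentration ag = [Ag+]: silver scavenges bromide at the
diffusion-limited rate ``kdiff``, which is how an excitatory pulse lowers the
inhibitor and can trigger a spike.

Two knobs tune a cell's dynamical state: the proton concentration ``h`` and
the bromide-inflow parameter ``y0``.  At ``y0 = 0`` the cell oscillates
autonomously; raising ``y0`` past the Hopf threshold turns it into an
excitable stable focus (see :mod:`bzreader.linstab`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import math

import numpy as np

__all__ = [
    "RateConstants",
    "BZParameters",
    "BZState",
    "PulseDrive",
    "derive_parameters",
    "rhs",
    "jacobian",
    "param_vector",
    "PARAM_NAMES",
]


@dataclass(frozen=True)
class RateConstants:
    """Primary rate constants and feed concentrations of the BZ recipe.

    Defaults are the standard set for the catalysed bromate / malonic acid
    system in a flow reactor; all rates are in molar-second units.
    """

    k1_prime: float = 2e6      # M^-2 s^-1
    k2_prime: float = 2.0      # M^-3 s^-1
    k3: float = 3000.0         # M^-1 s^-1
    k4_prime: float = 42.0     # M^-2 s^-1
    k9p: float = 20.0          # M^-1 s^-1
    k10_prime: float = 0.05    # M^-1 s^-1
    k13: float = 0.004         # s^-1
    k0: float = 5e-4           # flow rate, s^-1
    kr: float = 2e8            # M^-1 s^-1
    kred: float = 5e6          # M^-1 s^-1
    kdiff: float = 1e8         # M^-1 s^-1, Ag+ + Br- recombination
    A_star: float = 0.25       # [NaBrO3], M
    MA: float = 0.1            # [malonic acid], M
    c0: float = 1e-3           # total catalyst, M

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (value > 0):
                raise ValueError(f"rate constant {name} must be positive, got {value}")


@dataclass(frozen=True)
class BZParameters:
    """Derived, ready-to-integrate parameter set for one cell.

    ``k1 = k1'h``, ``k2 = k2'h^2 A*``, ``k4 = k4'h A*``, ``k10 = k10'[MA]``
    and ``cmin = sqrt(3 kr k10 c0) / kred``.  The bromate concentration in
    the autocatalysis term is identified with A* = [NaBrO3].
    """

    h: float
    y0: float
    k1: float
    k2: float
    k4: float
    k10: float
    cmin: float
    raw: RateConstants = field(default_factory=RateConstants)

    @property
    def c0(self) -> float:
        return self.raw.c0

    @property
    def k3(self) -> float:
        return self.raw.k3


def derive_parameters(
    raw: RateConstants | None = None, h: float = 0.3, y0: float = 0.0
) -> BZParameters:
    """Derive the composite rates for proton concentration ``h`` and inflow ``y0``."""
    if raw is None:
        raw = RateConstants()
    if not (h > 0):
        raise ValueError(f"proton concentration h must be positive, got {h}")
    if y0 < 0:
        raise ValueError(f"bromide inflow y0 must be non-negative, got {y0}")
    k10 = raw.k10_prime * raw.MA
    cmin = math.sqrt(3.0 * raw.kr * k10 * raw.c0) / raw.kred
    if not cmin < raw.c0 / 10.0:
        raise ValueError(
            f"cmin = {cmin:g} is not small compared with c0 = {raw.c0:g}; "
            "the reduced catalyst-recovery term is invalid in this regime"
        )
    return BZParameters(
        h=h,
        y0=y0,
        k1=raw.k1_prime * h,
        k2=raw.k2_prime * h * h * raw.A_star,
        k4=raw.k4_prime * h * raw.A_star,
        k10=k10,
        cmin=cmin,
        raw=raw,
    )


@dataclass
class BZState:
    """Concentrations of one cell at one instant (molar).

    ``ag`` is only dynamically active in excitatorily driven cells; for bare
    oscillators it stays exactly zero and the five-variable form reduces to
    the four-variable one.
    """

    x: float
    y: float
    z: float
    v: float
    ag: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.v, self.ag], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "BZState":
        arr = np.asarray(arr, dtype=float)
        ag = float(arr[4]) if arr.shape[0] > 4 else 0.0
        return cls(float(arr[0]), float(arr[1]), float(arr[2]), float(arr[3]), ag)

    def validate(self, c0: float, tol: float = 1e-12) -> None:
        arr = self.as_array()
        if np.any(arr < -tol):
            raise ValueError(f"negative concentration in state {self}")
        if self.z > c0 + tol:
            raise ValueError(f"catalyst bound violated: z = {self.z} > c0 = {c0}")


@dataclass(frozen=True)
class PulseDrive:
    """Instantaneous injection rates from all currently open pulse windows.

    ``inh`` adds bromide to dy/dt (inhibitory coupling); ``exc`` adds silver
    to d[Ag]/dt (excitatory coupling).  Both are sums over open windows and
    therefore non-negative.
    """

    inh: float = 0.0
    exc: float = 0.0

    def __post_init__(self) -> None:
        if self.inh < 0 or self.exc < 0:
            raise ValueError("pulse injection rates must be non-negative")


ZERO_DRIVE = PulseDrive()


def rhs(state: BZState, params: BZParameters, drive: PulseDrive = ZERO_DRIVE) -> BZState:
    """Time derivative of one cell, returned in the same container as the state.

    The four kinetic components are G, F, P, W (activator, inhibitor,
    catalyst, BrMA); the inhibitor additionally receives ``drive.inh`` and
    loses bromide to silver, and the silver balance closes the system.
    """
    p = params
    x, y, z, v, ag = state.x, state.y, state.z, state.v, state.ag
    k9p, k13, k0, kdiff = p.raw.k9p, p.raw.k13, p.raw.k0, p.raw.kdiff
    D = p.c0 - z
    q = p.k4 * x * D / (D + p.cmin)
    G = -p.k1 * x * y + p.k2 * y - 2.0 * p.k3 * x * x + q - k0 * x
    F = -p.k1 * x * y - p.k2 * y + k9p * v * z - k0 * (y - p.y0)
    P = 2.0 * q - k9p * v * z - p.k10 * z
    W = 2.0 * p.k1 * x * y + p.k2 * y + p.k3 * x * x - k9p * v * z - k13 * v - k0 * v
    dy = F + drive.inh - kdiff * ag * y
    dag = drive.exc - kdiff * ag * y
    return BZState(G, dy, P, W, dag)


def jacobian(
    state: BZState, params: BZParameters, include_silver: bool = False
) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` with the drive held at zero.

    Returns the 4x4 matrix over (x, y, z, v), or the 5x5 matrix including the
    silver row/column when ``include_silver`` is true.
    """
    p = params
    x, y, z, v, ag = state.x, state.y, state.z, state.v, state.ag
    k1, k2, k3, k4, k10, cmin = p.k1, p.k2, p.raw.k3, p.k4, p.k10, p.cmin
    k9p, k13, k0, kdiff, c0 = p.raw.k9p, p.raw.k13, p.raw.k0, p.raw.kdiff, p.c0
    D = c0 - z
    S = D + cmin
    J = np.zeros((5, 5))
    # G row
    J[0, 0] = -k1 * y - 4.0 * k3 * x + k4 * D / S - k0
    J[0, 1] = -k1 * x + k2
    J[0, 2] = -k4 * x * cmin / (S * S)
    # F row (with silver loss term)
    J[1, 0] = -k1 * y
    J[1, 1] = -k1 * x - k2 - k0 - kdiff * ag
    J[1, 2] = k9p * v
    J[1, 3] = k9p * z
    J[1, 4] = -kdiff * y
    # P row
    J[2, 0] = 2.0 * k4 * D / S
    J[2, 2] = -2.0 * k4 * x * cmin / (S * S) - k9p * v - k10
    J[2, 3] = -k9p * z
    # W row
    J[3, 0] = 2.0 * k1 * y + 2.0 * k3 * x
    J[3, 1] = 2.0 * k1 * x + k2
    J[3, 2] = -k9p * v
    J[3, 3] = -k9p * z - k13 - k0
    # silver row
    J[4, 1] = -kdiff * ag
    J[4, 4] = -kdiff * y
    if include_silver:
        return J
    return J[:4, :4]


# Order of the flat parameter vector consumed by the compiled kernels.
PARAM_NAMES = (
    "k1", "k2", "k3", "k4", "k9p", "k10", "k13", "k0", "y0", "c0", "cmin", "kdiff",
)


def param_vector(params: BZParameters) -> np.ndarray:
    """Flatten a parameter set into the vector layout of the integration kernels."""
    p, r = params, params.raw
    return np.array(
        [p.k1, p.k2, r.k3, p.k4, r.k9p, p.k10, r.k13, r.k0, p.y0, r.c0, p.cmin, r.kdiff],
        dtype=float,
    )
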