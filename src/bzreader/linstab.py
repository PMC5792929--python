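"""Linear-stability machinery: steady states, spectra, Hopf threshold and
excitability thresholds.

A BZ cell with large bromide inflow ``y0`` sits on a stable focus.  Lowering
``y0`` through the Hopf threshold ``y0H`` destabilises the focus and the cell
oscillates.  Just above the threshold the cell is *excitable*: a single
silver pulse that removes enough bromide — roughly the gap between the
steady-state bromide ``y_SS`` and its critical value ``y_SS^H`` — fires one
full spike.  :func:`min_pulse_amplitude` measures that threshold amplitude by
bisection on a direct simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .kinetics import (
    BZParameters,
    BZState,
    RateConstants,
    derive_parameters,
    jacobian,
    rhs,
)

__all__ = [
    "SteadyState",
    "Spectrum",
    "HopfPoint",
    "SteadyStateError",
    "find_steady_state",
    "spectrum_at",
    "hopf_threshold",
    "subthreshold_trajectory",
    "min_pulse_amplitude",
]


class SteadyStateError(RuntimeError):
    """Raised when no steady state can be located (parameters likely oscillatory)."""


@dataclass(frozen=True)
class SteadyState:
    state: BZState
    params: BZParameters
    residual: float

    @property
    def y_ss(self) -> float:
        return self.state.y


@dataclass(frozen=True)
class Spectrum:
    """Eigenvalues of the linearised four-variable model at a steady state.

    ``eigenvalues`` are sorted by descending real part.  ``re``/``im`` refer
    to the oscillatory (complex) pair with the largest real part when one
    exists — this is the pair whose frequency Im(lambda) sets the resonance
    of an excitable focus — and fall back to the leading real eigenvalue
    otherwise.  ``im`` is non-negative by convention.
    """

    eigenvalues: tuple[complex, ...]

    @property
    def leading(self) -> complex:
        return self.eigenvalues[0]

    @property
    def _focus(self) -> complex:
        for ev in self.eigenvalues:
            if abs(ev.imag) > 1e-12:
                return ev
        return self.eigenvalues[0]

    @property
    def re(self) -> float:
        return self._focus.real

    @property
    def im(self) -> float:
        return abs(self._focus.imag)

    @property
    def ratio(self) -> float:
        return self.im / self.re if self.re != 0 else np.inf


@dataclass(frozen=True)
class HopfPoint:
    y0H: float
    ySSH: float
    h: float


def _rhs4(s: np.ndarray, p: BZParameters) -> np.ndarray:
    d = rhs(BZState(s[0], s[1], s[2], s[3]), p)
    return np.array([d.x, d.y, d.z, d.v])


def _jac4(s: np.ndarray, p: BZParameters) -> np.ndarray:
    return jacobian(BZState(s[0], s[1], s[2], s[3]), p)


def find_steady_state(
    params: BZParameters, guess: BZState | None = None
) -> SteadyState:
    """Locate the (possibly unstable) steady state of the four-variable model.

    Without a guess, the root is continued from a deeply stable state at very
    large ``y0`` down to the requested one, which converges reliably on both
    sides of the Hopf threshold.  The converged root is polished with Newton
    steps using the analytic Jacobian until the residual is at round-off.
    """
    if guess is not None:
        s = guess.as_array()[:4]
        sol = root(lambda q: _rhs4(q, params), s, jac=lambda q: _jac4(q, params),
                   method="hybr", tol=1e-13)
        s = sol.x
    else:
        y0_start = max(0.2, 2.0 * params.y0)
        grid = np.geomspace(y0_start, max(params.y0, 1e-8), 30)
        grid[-1] = params.y0
        s = np.array([1e-9, grid[0], 1e-6, 1e-4])
        for y0_i in grid:
            p_i = derive_parameters(params.raw, params.h, y0_i)
            sol = root(lambda q: _rhs4(q, p_i), s, jac=lambda q: _jac4(q, p_i),
                       method="hybr", tol=1e-13)
            if not sol.success and np.abs(_rhs4(sol.x, p_i)).max() > 1e-10:
                raise SteadyStateError(
                    f"continuation stalled at y0 = {y0_i:g} (h = {params.h:g})"
                )
            s = sol.x
    # Newton polish
    for _ in range(6):
        try:
            s = s - np.linalg.solve(_jac4(s, params), _rhs4(s, params))
        except np.linalg.LinAlgError:
            break
    res = float(np.abs(_rhs4(s, params)).max())
    scale = max(1.0, float(np.abs(s).max()))
    if not res < 1e-14 * scale or np.any(s < 0):
        raise SteadyStateError(
            f"no steady state at h = {params.h:g}, y0 = {params.y0:g} "
            f"(residual {res:g}); parameters are likely oscillatory"
        )
    return SteadyState(BZState(*s), params, res)


def spectrum_at(params: BZParameters, ss: SteadyState | None = None) -> Spectrum:
    """Eigenvalue spectrum of the four-variable Jacobian at the steady state."""
    if ss is None:
        ss = find_steady_state(params)
    ev = np.linalg.eigvals(jacobian(ss.state, params))
    order = np.argsort(-ev.real)
    ev = ev[order]
    # canonical sign: list the +Im member of each conjugate pair first
    evs = tuple(sorted(ev, key=lambda e: (-e.real, -e.imag)))
    return Spectrum(eigenvalues=evs)


def hopf_threshold(
    raw: RateConstants | None = None,
    h: float = 0.3,
    bracket: tuple[float, float] = (1.0e-3, 2.0e-3),
    xtol: float = 1e-10,
) -> HopfPoint:
    """Bisect ``y0`` for the zero crossing of the leading eigenvalue's real part."""
    if raw is None:
        raw = RateConstants()

    def re_leading(y0: float) -> float:
        params = derive_parameters(raw, h, y0)
        return spectrum_at(params).leading.real

    lo, hi = bracket
    f_lo, f_hi = re_leading(lo), re_leading(hi)
    if f_lo * f_hi >= 0:
        raise ValueError(
            f"bracket ({lo:g}, {hi:g}) does not straddle the Hopf point: "
            f"Re(lambda) = ({f_lo:g}, {f_hi:g})"
        )
    y0H = float(brentq(re_leading, lo, hi, xtol=xtol))
    ss = find_steady_state(derive_parameters(raw, h, y0H))
    return HopfPoint(y0H=y0H, ySSH=ss.y_ss, h=h)


def subthreshold_trajectory(
    ss: SteadyState, spec: Spectrum, y_ini: float, times: np.ndarray
) -> np.ndarray:
    """Closed-form small-perturbation response of the bromide concentration.

    Evaluates ``y(t) = y_SS + y_ini cos(w0 t) exp(2.3 Re(lambda) t)``.
    Diagnostic only: the full ODE is authoritative.  Note the 2.3 factor in
    the exponent is kept as printed in the source model description even
    though plain linear theory would give exp(Re(lambda) t); see the methods
    note.
    """
    if spec.re >= 0:
        raise ValueError("subthreshold approximation requires a stable focus (Re < 0)")
    t = np.asarray(times, dtype=float)
    return ss.y_ss + y_ini * np.cos(spec.im * t) * np.exp(2.3 * spec.re * t)


def min_pulse_amplitude(
    params: BZParameters,
    dt_pulse: float = 5.0,
    horizon: float = 450.0,
    theta: float = 3e-6,
    c_hi: float = 1e-3,
    rel_tol: float = 1e-3,
) -> float:
    """Minimum amplitude of a single silver pulse (width ``dt_pulse``) that
    fires a spike in an excitable cell resting at its steady state.

    The activator threshold ``theta`` and the spike horizon follow the
    network spike detector; the amplitude is bisected to ``rel_tol``.
    """
    from .network_sim import PulseWindow, integrate_cell  # deferred, avoids cycle

    ss = find_steady_state(params)
    s0 = ss.state.as_array()

    def spikes(c_ex: float) -> bool:
        win = [PulseWindow(target="cell", kind="excitatory", amplitude=c_ex,
                           t_on=0.0, t_off=dt_pulse)]
        _, spike_times = integrate_cell(params, s0, win, horizon, theta=theta)
        return len(spike_times) > 0

    if spikes(0.0):
        raise SteadyStateError("cell fires without stimulus; not excitable")
    if not spikes(c_hi):
        raise SteadyStateError(
            f"no spike even at amplitude {c_hi:g} M/s; cell may not be excitable"
        )
    lo, hi = 0.0, c_hi
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi
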