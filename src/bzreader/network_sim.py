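"""Event-driven integration of pulse-coupled BZ cell networks.

Coupling between cells is purely pulsatile: a spike of the activator in a
source cell opens, after a conduction delay, a rectangular injection window
of fixed width on the target cell.  Inhibitory windows inject bromide
directly into dy/dt; excitatory windows inject silver into d[Ag]/dt.
External periodic signals open one window per forcing period.

The integrator is a stiff LSODA run that is restarted exactly at every
window boundary, so rectangular pulses are resolved without smoothing, and
terminated at every upward threshold crossing of a cell that drives others,
so delayed windows are scheduled causally from spike events located by the
solver's root finder.  Overlapping windows on one target sum additively.
The whole procedure is deterministic.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ._kernels import NVAR, network_jac, network_rhs
from .kinetics import BZParameters, BZState, param_vector

__all__ = [
    "OscillatorNode",
    "CouplingLink",
    "ExternalSignal",
    "PulseWindow",
    "NetworkSpec",
    "Trajectory",
    "SpikeTrain",
    "SimulationError",
    "signal_windows",
    "simulate",
    "integrate_cell",
    "detect_spikes",
    "natural_period",
]

DEFAULT_THETA = 3e-6       # activator spike threshold, M
DEFAULT_REFRACTORY = 20.0  # s
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12


class SimulationError(RuntimeError):
    pass


@dataclass
class OscillatorNode:
    """One cell of the network.  ``role`` is 'cpg' for oscillators and 'A'
    for excitable reader cells (which carry an active silver variable)."""

    id: str
    params: BZParameters
    initial: np.ndarray
    role: str = "cpg"

    def __post_init__(self) -> None:
        if isinstance(self.initial, BZState):
            self.initial = self.initial.as_array()
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape == (4,):
            self.initial = np.append(self.initial, 0.0)
        if self.initial.shape != (NVAR,):
            raise ValueError(f"initial state of node {self.id} must have 4 or 5 components")


@dataclass(frozen=True)
class CouplingLink:
    """Directed pulsatile link.  ``source`` is a node id or a signal id."""

    source: str
    target: str
    kind: str              # 'inhibitory' | 'excitatory'
    amplitude: float       # injection rate while the window is open, M/s
    delay: float = 0.0     # s
    width: float = 5.0     # s

    def __post_init__(self) -> None:
        if self.kind not in ("inhibitory", "excitatory"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if self.amplitude < 0 or self.delay < 0 or self.width <= 0:
            raise ValueError("link requires amplitude >= 0, delay >= 0, width > 0")


@dataclass(frozen=True)
class ExternalSignal:
    """Periodic pulse trigger S(t) = H(sin(omega t) - 0.99): one trigger per
    forcing period, at the upward crossing of sin(omega t) through 0.99."""

    id: str
    omega: float           # angular frequency, 1/s
    width: float = 5.0     # pulse width Delta t, s

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("signal frequency must be positive")


@dataclass(frozen=True)
class PulseWindow:
    target: str
    kind: str
    amplitude: float
    t_on: float
    t_off: float


@dataclass
class NetworkSpec:
    nodes: list[OscillatorNode]
    links: list[CouplingLink] = field(default_factory=list)
    signals: list[ExternalSignal] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        known = set(ids) | {s.id for s in self.signals}
        for ln in self.links:
            if ln.source not in known:
                raise ValueError(f"link source {ln.source!r} unknown")
            if ln.target not in ids:
                raise ValueError(f"link target {ln.target!r} is not a node")


@dataclass
class Trajectory:
    times: np.ndarray                 # (nt,)
    states: np.ndarray                # (n_nodes, NVAR, nt)
    node_ids: list[str]
    meta: dict = field(default_factory=dict)

    def node(self, node_id: str) -> np.ndarray:
        return self.states[self.node_ids.index(node_id)]


@dataclass
class SpikeTrain:
    trains: dict[str, np.ndarray]     # node id -> sorted spike times
    theta: float = DEFAULT_THETA
    refractory: float = DEFAULT_REFRACTORY

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self.trains[node_id]

    def n_spikes(self, node_id: str) -> int:
        return len(self.trains.get(node_id, ()))


def signal_windows(
    signal: ExternalSignal,
    t_end: float,
    target: str = "",
    kind: str = "excitatory",
    amplitude: float = 0.0,
) -> list[PulseWindow]:
    """Pulse windows of a periodic external signal up to ``t_end``.

    The window of period k opens at t_k = (arcsin(0.99) + 2 pi k) / omega,
    the first upward crossing of sin(omega t) through 0.99 in that period.
    """
    t_up = math.asin(0.99) / signal.omega
    period = 2.0 * math.pi / signal.omega
    out = []
    k = 0
    while t_up + k * period < t_end:
        t_on = t_up + k * period
        out.append(PulseWindow(target=target, kind=kind, amplitude=amplitude,
                               t_on=t_on, t_off=t_on + signal.width))
        k += 1
    return out


def _refractory_filter(times: list[float], refractory: float) -> np.ndarray:
    out: list[float] = []
    for t in sorted(times):
        if not out or t - out[-1] >= refractory:
            out.append(t)
    return np.array(out)


def simulate(
    spec: NetworkSpec,
    t_end: float,
    extra_windows: list[PulseWindow] | None = None,
    theta: float = DEFAULT_THETA,
    refractory: float = DEFAULT_REFRACTORY,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    sample_dt: float = 1.0,
    validate: bool = True,
) -> tuple[Trajectory, SpikeTrain]:
    """Integrate a pulse-coupled network and return its trajectory and spikes.

    Spikes of nodes with outgoing links are located online by terminal
    solver events (upward crossing of the activator through ``theta``) and
    immediately schedule the delayed windows of their links; spikes of sink
    nodes are recorded by non-terminal events.  ``extra_windows`` allows
    precomputed drive (e.g. from an already-simulated upstream network).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n = len(spec.nodes)
    ids = [nd.id for nd in spec.nodes]
    index = {nid: i for i, nid in enumerate(ids)}
    Pmat = np.array([param_vector(nd.params) for nd in spec.nodes])
    Y = np.concatenate([nd.initial for nd in spec.nodes])

    windows: list[PulseWindow] = list(extra_windows or [])
    boundaries: list[float] = []
    out_links: dict[int, list[CouplingLink]] = {i: [] for i in range(n)}
    sig_by_id = {s.id: s for s in spec.signals}
    for ln in spec.links:
        if ln.source in sig_by_id:
            windows.extend(
                signal_windows(sig_by_id[ln.source], t_end, target=ln.target,
                               kind=ln.kind, amplitude=ln.amplitude)
            )
        else:
            out_links[index[ln.source]].append(ln)
    for w in windows:
        if w.target not in index:
            raise ValueError(f"window target {w.target!r} is not a node")
        heapq.heappush(boundaries, w.t_on)
        heapq.heappush(boundaries, w.t_off)

    source_nodes = [i for i in range(n) if out_links[i]]
    armed = np.array([Y[i * NVAR] < theta for i in range(n)])
    last_spike = np.full(n, -np.inf)
    spike_lists: dict[int, list[float]] = {i: [] for i in range(n)}

    # event functions; closures over the mutable `armed` array
    events = []
    term_of_event: list[int | None] = []
    for i in range(n):
        xi = i * NVAR
        if i in set(source_nodes):
            def ev_spike(t, y, xi=xi, i=i):
                return (y[xi] - theta) if armed[i] else -1.0
            ev_spike.direction = 1
            ev_spike.terminal = True

            def ev_rearm(t, y, xi=xi, i=i):
                return 1.0 if armed[i] else (y[xi] - 0.5 * theta)
            ev_rearm.direction = -1
            ev_rearm.terminal = True
            events.extend([ev_spike, ev_rearm])
            term_of_event.extend([i, i])
        else:
            def ev_cross(t, y, xi=xi):
                return y[xi] - theta
            ev_cross.direction = 1
            ev_cross.terminal = False
            events.append(ev_cross)
            term_of_event.append(None)

    grid = np.arange(0.0, t_end, sample_dt)
    g_ptr = 0
    times_out: list[float] = [0.0]
    states_out: list[np.ndarray] = [Y.copy()]

    def open_drive(t_mid: float) -> tuple[np.ndarray, np.ndarray]:
        inh = np.zeros(n)
        exc = np.zeros(n)
        for w in windows:
            if w.t_on <= t_mid < w.t_off:
                if w.kind == "inhibitory":
                    inh[index[w.target]] += w.amplitude
                else:
                    exc[index[w.target]] += w.amplitude
        return inh, exc

    def handle_stop(t_now: float, y_now: np.ndarray) -> None:
        """Record spikes / rearm all source nodes that are due at a restart."""
        for i in source_nodes:
            x_i = y_now[i * NVAR]
            # accept marginally sub-threshold states as simultaneous spikes:
            # the activator rises orders of magnitude per second, so 1e-6
            # relative corresponds to a sub-microsecond timing error
            if armed[i] and x_i >= theta * (1.0 - 1e-6):
                armed[i] = False
                if t_now - last_spike[i] >= refractory:
                    last_spike[i] = t_now
                    spike_lists[i].append(t_now)
                    for ln in out_links[i]:
                        t_on = t_now + ln.delay
                        if t_on < t_end:
                            windows.append(PulseWindow(
                                target=ln.target, kind=ln.kind,
                                amplitude=ln.amplitude,
                                t_on=t_on, t_off=t_on + ln.width))
                            heapq.heappush(boundaries, t_on)
                            heapq.heappush(boundaries, t_on + ln.width)
            elif not armed[i] and x_i <= 0.75 * theta:
                # hysteresis: the rearm event roots at 0.5*theta; accept any
                # state safely below the spike threshold
                armed[i] = True

    t_cur = 0.0
    eps = 1e-9
    stall = 0
    max_iter = 500_000
    for _ in range(max_iter):
        if t_cur >= t_end - 1e-12:
            break
        while boundaries and boundaries[0] <= t_cur + eps:
            heapq.heappop(boundaries)
        t_next = min(boundaries[0], t_end) if boundaries else t_end
        inh, exc = open_drive(0.5 * (t_cur + t_next))

        t_eval = grid[g_ptr:np.searchsorted(grid, t_next, side="right")]
        t_eval = t_eval[t_eval > t_cur + 1e-13]
        sol = solve_ivp(
            lambda t, y: network_rhs(y, Pmat, inh, exc),
            (t_cur, t_next), Y,
            method="LSODA",
            jac=lambda t, y: network_jac(y, Pmat),
            rtol=rtol, atol=atol,
            events=events, dense_output=True,
            t_eval=t_eval if len(t_eval) else None,
        )
        if sol.status == -1:
            raise SimulationError(f"solver failed at t = {sol.t[-1]:g}: {sol.message}")

        if sol.status == 1:
            t_stop = min(te[0] for te, flag in zip(sol.t_events, term_of_event)
                         if flag is not None and len(te))
        else:
            t_stop = t_next
        y_stop = sol.sol(t_stop)

        # store samples up to the stop time
        sol_t = np.atleast_1d(np.asarray(sol.t, dtype=float))
        if len(t_eval) and len(sol_t):
            sol_y = np.asarray(sol.y, dtype=float).reshape(len(Y), len(sol_t))
            keep = sol_t <= t_stop + 1e-13
            for tk, yk in zip(sol_t[keep], sol_y[:, keep].T):
                times_out.append(float(tk))
                states_out.append(yk)
            g_ptr += int(np.sum(keep))
        # non-terminal crossings (sink nodes)
        sink_event_nodes = [i for i in range(n) if i not in set(source_nodes)]
        sk = 0
        for k, flag in enumerate(term_of_event):
            if flag is None:
                node_i = sink_event_nodes[sk]
                sk += 1
                for te in sol.t_events[k]:
                    if te <= t_stop + 1e-13:
                        spike_lists[node_i].append(float(te))

        if t_stop <= t_cur + 1e-13:
            stall += 1
            if stall > 50:
                raise SimulationError(f"integration stalled at t = {t_cur:g}")
            t_stop = t_cur + 1e-9
            y_stop = Y
        else:
            stall = 0
        t_cur = t_stop
        Y = np.asarray(y_stop, dtype=float)
        handle_stop(t_cur, Y)
    else:
        raise SimulationError("maximum number of integration segments exceeded")

    times_out.append(t_end)
    states_out.append(Y.copy())
    times = np.array(times_out)
    allst = np.array(states_out)                      # (nt, n*NVAR)
    states = np.transpose(allst.reshape(-1, n, NVAR), (1, 2, 0))

    traj = Trajectory(times=times, states=states, node_ids=ids,
                      meta=dict(rtol=rtol, atol=atol, theta=theta,
                                refractory=refractory, sample_dt=sample_dt))
    if validate:
        _validate_trajectory(traj, spec)

    trains = {}
    for i, nid in enumerate(ids):
        trains[nid] = _refractory_filter(spike_lists[i], refractory)
    return traj, SpikeTrain(trains=trains, theta=theta, refractory=refractory)


def _validate_trajectory(traj: Trajectory, spec: NetworkSpec, tol: float = 1e-9) -> None:
    if traj.states.min() < -tol:
        raise SimulationError(
            f"negative concentration {traj.states.min():g} in trajectory"
        )
    for i, nd in enumerate(spec.nodes):
        c0 = nd.params.c0
        if traj.states[i, 2].max() > c0 * (1 + 1e-9) + tol:
            raise SimulationError(f"catalyst bound violated on node {nd.id}")


def integrate_cell(
    params: BZParameters,
    initial: np.ndarray,
    windows: list[PulseWindow],
    t_end: float,
    theta: float = DEFAULT_THETA,
    refractory: float = DEFAULT_REFRACTORY,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    sample_dt: float = 1.0,
) -> tuple[Trajectory, np.ndarray]:
    """Integrate a single cell under a precomputed pulse-window drive.

    Fast path used for reader cells (which receive pulses but drive nobody),
    excitability-threshold bisection and resonance curves.
    """
    win = [PulseWindow(target="cell", kind=w.kind, amplitude=w.amplitude,
                       t_on=w.t_on, t_off=w.t_off) for w in windows]
    spec = NetworkSpec(nodes=[OscillatorNode(id="cell", params=params,
                                             initial=np.asarray(initial, float))])
    traj, spikes = simulate(spec, t_end, extra_windows=win, theta=theta,
                            refractory=refractory, rtol=rtol, atol=atol,
                            sample_dt=sample_dt)
    return traj, spikes["cell"]


def detect_spikes(
    trajectory: Trajectory,
    theta: float = DEFAULT_THETA,
    refractory: float = DEFAULT_REFRACTORY,
) -> SpikeTrain:
    """Post-hoc spike detection: linearly interpolated upward crossings of the
    activator through ``theta``, with crossings inside the refractory window
    of the previous spike discarded."""
    trains = {}
    t = trajectory.times
    for i, nid in enumerate(trajectory.node_ids):
        x = trajectory.states[i, 0]
        above = x >= theta
        idx = np.nonzero(~above[:-1] & above[1:])[0]
        crossings = []
        for k in idx:
            frac = (theta - x[k]) / (x[k + 1] - x[k])
            crossings.append(t[k] + frac * (t[k + 1] - t[k]))
        trains[nid] = _refractory_filter(crossings, refractory)
    return SpikeTrain(trains=trains, theta=theta, refractory=refractory)


def natural_period(
    params: BZParameters,
    n_discard: int = 20,
    n_avg: int = 5,
    theta: float = DEFAULT_THETA,
    cv_tol: float = 1e-3,
    t_end: float | None = None,
) -> float:
    """Asymptotic inter-spike interval of an isolated oscillatory cell.

    The relaxation onto the limit cycle is slow (the interval shrinks
    geometrically over ~15 cycles), hence the generous default transient.
    """
    if t_end is None:
        t_end = (n_discard + n_avg + 4) * 220.0
    initial = np.array([1e-8, max(params.y0, 1e-8), 1e-6, 1e-5, 0.0])
    spec = NetworkSpec(nodes=[OscillatorNode(id="cell", params=params, initial=initial)])
    _, spikes = simulate(spec, t_end, theta=theta, sample_dt=5.0)
    ts = spikes["cell"]
    if len(ts) < n_discard + n_avg + 1:
        raise SimulationError(
            f"only {len(ts)} spikes in {t_end:g} s; cell may not be oscillatory"
        )
    isi = np.diff(ts)[n_discard:n_discard + n_avg]
    cv = isi.std() / isi.mean()
    if cv > cv_tol:
        raise SimulationError(f"inter-spike intervals not settled (CV = {cv:g})")
    return float(isi.mean())
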