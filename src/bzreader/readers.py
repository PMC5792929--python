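"""The three mode-recognition methods.

* Delay (polychronization) reader, one excitable cell per sub-mode: each CPG
  oscillator feeds the cell through a conduction delay chosen so that the
  four pulses arrive simultaneously only when the CPG runs in that cell's
  sub-mode; the per-pulse amplitude is set so that four overlapping pulses
  fire the cell but three do not.
* Amplitude (cluster-summation) reader: banks of cells fed without delay,
  with excitability thresholds graded to fire on k or more simultaneous
  pulses; the set of active cells encodes the cluster structure.
* Resonance reader: stable-focus cells whose damped frequency Im(lambda)
  matches the pulse rate of one CPG mode; a periodic pulse train above a
  critical amplitude C_ex^cr(omega), minimal near resonance, drives a spike.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .cli_io import PRESETS, build_cpg_spec, build_fixture
from .kinetics import BZParameters, derive_parameters
from .linstab import find_steady_state, min_pulse_amplitude, spectrum_at
from .mode_analysis import (
    ModeLabel,
    all_mode_labels,
    canonical_phases,
    classify_detail,
    phase_pattern,
)
from .network_sim import (
    NetworkSpec,
    PulseWindow,
    SimulationError,
    SpikeTrain,
    integrate_cell,
    signal_windows,
    simulate,
)
from .network_sim import ExternalSignal

__all__ = [
    "DelayTable",
    "ThresholdBank",
    "ThresholdCell",
    "ResonanceCurve",
    "ReaderReport",
    "build_delay_table",
    "calibrate_mode",
    "run_delay_reader",
    "delay_reader_for_mode",
    "run_dispersion_case",
    "build_threshold_bank",
    "canonical_trains",
    "run_amplitude_reader",
    "critical_amplitude_curve",
    "tune_resonance_cell",
    "plan_resonance_amplitudes",
    "run_resonance_reader",
    "tuned_resonance_study",
    "RESONANCE_CELLS",
]

CPG_IDS = ("osc1", "osc2", "osc3", "osc4")


@dataclass(frozen=True)
class DelayTable:
    """Per-CPG-oscillator conduction delays tuning one cell to one sub-mode."""

    label: ModeLabel
    T: float
    tau_s: float
    delays: tuple[float, float, float, float]


@dataclass(frozen=True)
class ReaderReport:
    mode: ModeLabel
    activations: dict[str, bool]
    counts: dict[str, int]
    extra: dict = field(default_factory=dict)


def build_delay_table(
    label: ModeLabel,
    T: float,
    tau_s: float | None = None,
    offsets: tuple[float, ...] | None = None,
) -> DelayTable:
    """Delays such that the four pulses of sub-mode ``label`` arrive together.

    ``tau_d(i) = tau_s + ((-offset_i) mod T)``: an oscillator firing later in
    the cycle gets a correspondingly shorter extra delay, so all pulses land
    at ``tau_s`` past the cycle origin.  With no measured ``offsets`` the
    canonical pattern is used, except that the triplet-singlet mode's singlet
    is placed at ``T - T/2.2`` (the settled singlet lags slightly more than
    anti-phase, so the delay gap is T/2.2 rather than T/2).
    """
    if tau_s is None:
        tau_s = 0.1 * T
    if offsets is None:
        off = list(canonical_phases(label, T).offsets)
        if label.base == "T1":
            singlet = next(c[0] for c in label.clusters if len(c) == 1)
            off[singlet - 1] = T - T / 2.2
    else:
        off = list(offsets)
    delays = tuple(tau_s + ((-o) % T) % T for o in off)
    return DelayTable(label=label, T=T, tau_s=tau_s, delays=delays)  # type: ignore[arg-type]


def calibrate_mode(
    label: ModeLabel,
    fixture,
    c_inh: float,
    tau: float,
    dt: float = 5.0,
    t_cal: float = 2200.0,
    n_discard: int = 6,
) -> tuple[float, tuple[float, ...]]:
    """Settled global period and phase offsets of one seeded CPG sub-mode."""
    spec = build_cpg_spec(label, fixture, c_inh, tau, dt)
    _, spikes = simulate(spec, t_cal, sample_dt=5.0)
    res = classify_detail(spikes, n_discard=n_discard)
    if res.label != label:
        raise SimulationError(
            f"CPG seeded as {label} settled into {res.label}; cannot calibrate"
        )
    pat = phase_pattern(spikes, n_discard=n_discard)
    return pat.T, pat.offsets


def _a_cell_params(y0: float, h: float = 0.3) -> BZParameters:
    return derive_parameters(None, h, y0)


def _drive_cell_with_trains(
    params: BZParameters,
    trains: SpikeTrain,
    sources: tuple[str, ...],
    delays: dict[str, float],
    amplitude: float,
    width: float,
    t_end: float,
    t_obs: float,
) -> tuple[bool, int]:
    """Integrate one excitable cell fed by spike trains; count spikes >= t_obs."""
    windows = []
    for src in sources:
        d = delays.get(src, 0.0)
        for ts in trains[src]:
            t_on = ts + d
            if t_on < t_end:
                windows.append(PulseWindow(target="cell", kind="excitatory",
                                           amplitude=amplitude,
                                           t_on=t_on, t_off=t_on + width))
    s0 = find_steady_state(params).state.as_array()
    _, spike_times = integrate_cell(params, s0, windows, t_end, sample_dt=5.0)
    n = int(np.sum(spike_times >= t_obs))
    return n > 0, n


def run_delay_reader(
    cpg_spec: NetworkSpec,
    tables: list[DelayTable],
    t_obs: float | None = None,
    a_y0: float = 4.0e-3,
    a_h: float = 0.3,
    c_ex: float = 1.3e-6,
    dt: float = 5.0,
    n_transient_periods: float = 4.0,
    n_obs_periods: float = 4.0,
) -> ReaderReport:
    """Simulate the CPG and the tuned cells; report which cells activate.

    Observation starts after a transient of ``n_transient_periods`` global
    periods; activation means at least one spike in the observation window
    (the tuned cell may fire subharmonically).
    """
    T_ref = max(t.T for t in tables)
    t_end = (n_transient_periods + n_obs_periods + 0.5) * T_ref
    traj, spikes = simulate(cpg_spec, t_end, sample_dt=5.0)
    res = classify_detail(spikes, n_discard=4)
    if res.label.is_irregular:
        raise SimulationError("CPG did not settle into a classified mode")
    if t_obs is None:
        t_obs = n_transient_periods * T_ref
    params = _a_cell_params(a_y0, a_h)
    activations: dict[str, bool] = {}
    counts: dict[str, int] = {}
    for tab in tables:
        delays = {CPG_IDS[i]: tab.delays[i] for i in range(4)}
        act, n = _drive_cell_with_trains(
            params, spikes, CPG_IDS, delays, c_ex, dt, t_end, t_obs)
        activations[str(tab.label)] = act
        counts[str(tab.label)] = n
    return ReaderReport(mode=res.label, activations=activations, counts=counts,
                        extra=dict(T=res.T, t_obs=t_obs, t_end=t_end))


def delay_reader_for_mode(
    label: ModeLabel,
    cpg: dict | None = None,
    tables: list[DelayTable] | None = None,
) -> ReaderReport:
    """Convenience pipeline: calibrate all 26 tables, run one seeded mode."""
    cpg = dict(PRESETS["cpg_delay"]) if cpg is None else dict(cpg)
    fixture = build_fixture(h=cpg["h"], y0=cpg.get("y0", 0.0))
    if tables is None:
        tables = []
        for lab in all_mode_labels():
            T, off = calibrate_mode(lab, fixture, cpg["c_inh"], cpg["tau"], cpg["dt"])
            tables.append(build_delay_table(lab, T, offsets=off))
    spec = build_cpg_spec(label, fixture, cpg["c_inh"], cpg["tau"], cpg["dt"])
    return run_delay_reader(spec, tables)


# ---------------------------------------------------------------------------
# frequency-dispersion scenario
# ---------------------------------------------------------------------------

def run_dispersion_case(
    c_ex: float,
    dt_pulse: float,
    eps: float = 0.01,
    h0: float = 0.3,
    c_inh: float = 2e-5,
    tau: float = 30.0,
    a_y0: float = 4.0e-3,
    n_transient_periods: float = 4.0,
    n_obs_periods: float = 4.0,
) -> bool:
    """Does the IP-tuned cell still fire when the CPG oscillators are detuned?

    The four oscillators get slightly different proton concentrations
    (h0 + eps, h0 + eps/2, h0 - eps, h0 - eps/2), which staggers the
    'synchronous' spikes by a second or two; the cell fires only if the
    pulse overlap still delivers enough silver, which depends on c_ex and
    the pulse width.
    """
    from .network_sim import CouplingLink, OscillatorNode

    hs = [h0 + eps, h0 + eps / 2.0, h0 - eps, h0 - eps / 2.0]
    fixtures = [build_fixture(h=h) for h in hs]
    nodes = [
        OscillatorNode(id=CPG_IDS[i], params=fixtures[i].params,
                       initial=fixtures[i].at_phase(0.999))
        for i in range(4)
    ]
    links = [
        CouplingLink(source=CPG_IDS[j], target=CPG_IDS[i], kind="inhibitory",
                     amplitude=c_inh, delay=tau, width=5.0)
        for i in range(4) for j in range(4) if i != j
    ]
    spec = NetworkSpec(nodes=nodes, links=links)
    T0_mean = float(np.mean([f.period for f in fixtures]))
    t_end = (n_transient_periods + n_obs_periods + 0.5) * T0_mean
    _, spikes = simulate(spec, t_end, sample_dt=5.0)
    tau_s = 0.1 * T0_mean
    params = _a_cell_params(a_y0)
    act, _ = _drive_cell_with_trains(
        params, spikes, CPG_IDS, {nid: tau_s for nid in CPG_IDS},
        c_ex, dt_pulse, t_end, n_transient_periods * T0_mean)
    return act


# ---------------------------------------------------------------------------
# amplitude (cluster-summation) reader
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdCell:
    id: str
    inputs: tuple[str, ...]
    y0: float
    c_ex: float
    threshold_class: int      # k: fires on k or more simultaneous pulses


@dataclass(frozen=True)
class ThresholdBank:
    case: str
    cells: tuple[ThresholdCell, ...]
    dt: float = 5.0


@lru_cache(maxsize=32)
def _cexmin(y0: float, h: float = 0.3, dt: float = 5.0) -> float:
    return min_pulse_amplitude(derive_parameters(None, h, y0), dt_pulse=dt)


def _band_amplitude(k: int, y0: float, dt: float) -> float:
    """Per-pulse amplitude making a cell a 'k-pulse' threshold cell:
    k simultaneous pulses clear the single-pulse threshold, k-1 do not."""
    cmin = _cexmin(y0, dt=dt)
    if k == 1:
        return 1.5 * cmin
    c = cmin / (k - 0.5)
    if not (k * c > cmin and (k - 1) * c < cmin):
        raise SimulationError(
            f"no feasible per-pulse amplitude for a {k}P cell at y0 = {y0:g}"
        )
    return c


def build_threshold_bank(case: str, dt: float = 5.0) -> ThresholdBank:
    """The three bank layouts.

    Case 'i': four cells fed by all oscillators with graded inflows
    y0 = 8/6/4/2 mM giving thresholds 4P/3P/2P/1P.  Case 'ii': four 3P cells,
    one per oscillator triplet.  Case 'iii': six 2P cells, one per pair.
    """
    cells: list[ThresholdCell] = []
    if case == "i":
        for k, y0 in zip((4, 3, 2, 1), (8e-3, 6e-3, 4e-3, 2e-3)):
            cells.append(ThresholdCell(
                id=f"{k}P", inputs=CPG_IDS, y0=y0,
                c_ex=_band_amplitude(k, y0, dt), threshold_class=k))
    elif case == "ii":
        y0 = 4e-3
        c = _band_amplitude(3, y0, dt)
        for trip in itertools.combinations(range(4), 3):
            name = ",".join(str(i + 1) for i in trip)
            cells.append(ThresholdCell(
                id=name, inputs=tuple(CPG_IDS[i] for i in trip), y0=y0,
                c_ex=c, threshold_class=3))
    elif case == "iii":
        y0 = 4e-3
        c = _band_amplitude(2, y0, dt)
        for pair in itertools.combinations(range(4), 2):
            name = ",".join(str(i + 1) for i in pair)
            cells.append(ThresholdCell(
                id=name, inputs=tuple(CPG_IDS[i] for i in pair), y0=y0,
                c_ex=c, threshold_class=2))
    else:
        raise ValueError(f"unknown bank case {case!r}")
    return ThresholdBank(case=case, cells=tuple(cells), dt=dt)


def canonical_trains(
    label: ModeLabel, T: float = 144.6, n_periods: int = 8, t0: float = 10.0
) -> SpikeTrain:
    """Idealised periodic spike trains of a sub-mode (for bank studies)."""
    pat = canonical_phases(label, T)
    trains = {}
    for i, nid in enumerate(CPG_IDS):
        trains[nid] = t0 + pat.offsets[i] + T * np.arange(n_periods)
    return SpikeTrain(trains=trains)


def run_amplitude_reader(
    trains: SpikeTrain,
    bank: ThresholdBank,
    n_transient_periods: float = 2.0,
    n_obs_periods: float = 4.0,
) -> ReaderReport:
    """Feed the bank (no delays) from the given trains; one truth-table row."""
    allspk = np.concatenate([trains[nid] for nid in CPG_IDS])
    T = np.max([np.diff(trains[nid]).mean() for nid in CPG_IDS if len(trains[nid]) > 1])
    t_end = allspk.max() + 0.5 * T
    t_obs = allspk.min() + n_transient_periods * T
    activations, counts = {}, {}
    for cell in bank.cells:
        params = _a_cell_params(cell.y0)
        act, n = _drive_cell_with_trains(
            params, trains, cell.inputs, {}, cell.c_ex, bank.dt, t_end, t_obs)
        activations[cell.id] = act
        counts[cell.id] = n
    label = classify_detail(trains, n_discard=1).label
    return ReaderReport(mode=label, activations=activations, counts=counts)


# ---------------------------------------------------------------------------
# resonance reader
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResonanceCurve:
    omegas: np.ndarray
    cex_cr: np.ndarray
    omega0: float

    @property
    def argmin_omega(self) -> float:
        return float(self.omegas[int(np.argmin(self.cex_cr))])


def critical_amplitude_curve(
    params: BZParameters,
    omegas: np.ndarray | None = None,
    n_points: int = 11,
    span: float = 2.0,
    dt_pulse: float = 5.0,
    horizon_periods: float = 20.0,
    rel_tol: float = 1e-2,
    c_seed: float = 1e-7,
) -> ResonanceCurve:
    """Critical pulse-train amplitude versus forcing frequency.

    For each frequency the amplitude separating 'no spike within the horizon'
    from 'spike' is bisected to ``rel_tol``; successive frequencies reuse the
    previous critical value to bracket, since the curve is continuous.
    """
    ss = find_steady_state(params)
    sp = spectrum_at(params, ss)
    omega0 = sp.im
    if omegas is None:
        omegas = np.geomspace(omega0 / span, omega0 * span, n_points)
    s0 = ss.state.as_array()

    def fires(omega: float, c_ex: float) -> bool:
        t_end = horizon_periods * 2.0 * np.pi / omega
        sig = ExternalSignal(id="sig", omega=omega, width=dt_pulse)
        wins = signal_windows(sig, t_end, target="cell", kind="excitatory",
                              amplitude=c_ex)
        _, ts = integrate_cell(params, s0, wins, t_end, sample_dt=10.0)
        return len(ts) > 0

    cex_cr = np.empty(len(omegas))
    guess = c_seed
    for i, om in enumerate(omegas):
        lo, hi = guess / 4.0, guess * 4.0
        while not fires(om, hi):
            lo, hi = hi, hi * 4.0
            if hi > 1e-2:
                raise SimulationError(f"no spike at omega={om:g} up to {hi:g} M/s")
        while fires(om, lo):
            lo, hi = lo / 4.0, lo
            if lo < 1e-14:
                raise SimulationError(f"cell fires at negligible drive, omega={om:g}")
        while (hi - lo) > rel_tol * hi:
            mid = 0.5 * (lo + hi)
            if fires(om, mid):
                hi = mid
            else:
                lo = mid
        cex_cr[i] = hi
        guess = hi
    return ResonanceCurve(omegas=np.asarray(omegas), cex_cr=cex_cr, omega0=omega0)


def _hopf_y0(h: float) -> float:
    """Hopf-threshold inflow for proton concentration ``h`` (auto-bracketed)."""
    from scipy.optimize import brentq

    def re_leading(y0: float) -> float:
        return spectrum_at(derive_parameters(None, h, y0)).leading.real

    grid = np.geomspace(3e-4, 5e-2, 14)
    vals = [re_leading(g) for g in grid]
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa > 0 >= fb:
            return float(brentq(re_leading, a, b, xtol=1e-9))
    raise SimulationError(f"no Hopf threshold found for h = {h:g}")


def tune_resonance_cell(
    omega_target: float,
    ratio_target: float = 21.6,
    h_lo: float = 0.25,
    h_hi: float = 1.3,
) -> BZParameters:
    """Find (h, y0) placing the focus at Im(lambda) = ``omega_target`` with
    damping ratio |Im/Re| = ``ratio_target``.

    This is the tuning rule of the resonance method: the cell's damped
    frequency is matched to the pulse rate of the mode it must detect, and
    the damping ratio controls how deep and sharp the resonance minimum is.
    Solved by nested bracketing: for each ``h`` the inflow ``y0`` is raised
    just past the Hopf threshold until the damping ratio matches (the ratio
    falls monotonically from infinity at the threshold), and ``h`` is then
    bracketed on the focus frequency, which grows with acidity.
    """
    from scipy.optimize import brentq

    def y0_for_ratio(h: float) -> float:
        y0H = _hopf_y0(h)

        def f(y0: float) -> float:
            sp = spectrum_at(derive_parameters(None, h, y0))
            return (-sp.ratio) - ratio_target

        lo = y0H * 1.0005
        hi = y0H * 1.5
        while f(hi) > 0:
            hi *= 1.5
            if hi > 0.1:
                raise SimulationError(f"damping ratio never falls to "
                                      f"{ratio_target} at h = {h:g}")
        return float(brentq(f, lo, hi, xtol=1e-10))

    def freq_err(h: float) -> float:
        y0 = y0_for_ratio(h)
        sp = spectrum_at(derive_parameters(None, h, y0))
        return sp.im - omega_target

    if freq_err(h_lo) > 0 or freq_err(h_hi) < 0:
        raise SimulationError(
            f"omega0 = {omega_target:g} 1/s is outside the tunable range"
        )
    h = float(brentq(freq_err, h_lo, h_hi, xtol=1e-6))
    params = derive_parameters(None, h, y0_for_ratio(h))
    if spectrum_at(params).re >= 0:
        raise SimulationError(
            f"tuned parameters (h={h:g}, y0={params.y0:g}) are not a stable focus"
        )
    return params


def plan_resonance_amplitudes(
    cell_params: dict[str, BZParameters],
    mode_omegas: dict[str, float],
    n_sim: dict[str, float],
    margin: float = 1.12,
    cross_margin: float = 1.1,
    dt_pulse: float = 5.0,
) -> dict[str, float]:
    """Per-pulse amplitudes making each cell fire only on its own mode.

    Mode m delivers ``n_sim[m]`` simultaneous pulses per event at rate
    ``mode_omegas[m]``; cell k fires on mode m iff n_sim[m] * C_ex(k)
    exceeds that cell's critical amplitude at the mode's frequency.  The
    amplitude is placed just above the cell's own threshold (``margin``),
    because subharmonic resonances (e.g. the slow mode driving a cell at
    half its focus frequency) make the upper, cross-mode edge of the band
    the fragile one; the cross-mode thresholds must still clear
    ``cross_margin``.
    """
    names = list(cell_params)
    modes = list(mode_omegas)
    crit = {}
    for name in names:
        for m in modes:
            curve = critical_amplitude_curve(
                cell_params[name], omegas=np.array([mode_omegas[m]]),
                dt_pulse=dt_pulse)
            crit[name, m] = float(curve.cex_cr[0])
    amplitudes = {}
    for k, name in enumerate(names):
        own = modes[k]
        amp = margin * crit[name, own] / n_sim[own]
        hi = min(crit[name, m] / n_sim[m] for m in modes if m != own)
        if amp * cross_margin >= hi:
            raise SimulationError(
                f"no selective amplitude band for cell {name}: ({amp:g}, {hi:g})"
            )
        amplitudes[name] = float(amp)
    return amplitudes


# reader cells of the resonance study: stable foci with Im/Re ~ -21.6 whose
# damped frequencies sit near the pulse rates of the three target modes
RESONANCE_CELLS = {
    "A1": dict(h=0.3588, y0=1.697e-3, c_ex=6e-9),
    "A2": dict(h=0.4966, y0=2.567e-3, c_ex=25e-9),
    "A3": dict(h=0.8623, y0=5.429e-3, c_ex=29e-9),
}

_RES_CPG = {"IP": "cpg_ip", "AP": "cpg_ap", "S": "cpg_splay"}
_RES_SEED = {"IP": "IP", "AP": "AP(1,3+2,4)", "S": "S(1+2+3+4)"}
# simultaneous pulses per firing event and firing events per global period
_RES_NSIM = {"IP": 4.0, "AP": 2.0, "S": 1.0}
_RES_NPER = {"IP": 1, "AP": 2, "S": 4}


def run_resonance_reader(
    cpg_label: str,
    cells: dict[str, dict] | None = None,
    cpg: dict | None = None,
    n_transient_periods: float = 2.0,
    n_obs_periods: float = 18.0,
) -> ReaderReport:
    """Drive the three resonance cells from a CPG in mode IP, AP or S.

    All four oscillators feed every cell without delay; a cell activates
    when the aggregate pulse rate resonates with its focus frequency.
    """
    from .mode_analysis import parse_label

    if cpg_label not in _RES_CPG:
        raise ValueError("resonance reader handles the IP, AP and S modes")
    cells = RESONANCE_CELLS if cells is None else cells
    cpg = PRESETS[_RES_CPG[cpg_label]] if cpg is None else cpg
    fixture = build_fixture(h=cpg["h"], y0=cpg.get("y0", 0.0))
    label = parse_label(_RES_SEED[cpg_label])
    spec = build_cpg_spec(label, fixture, cpg["c_inh"], cpg["tau"], cpg["dt"])
    t_end = (n_transient_periods + n_obs_periods + 0.5) * fixture.period
    _, spikes = simulate(spec, t_end, sample_dt=5.0)
    res = classify_detail(spikes, n_discard=4)
    if res.label.is_irregular:
        raise SimulationError("CPG did not settle into a classified mode")
    t_obs = n_transient_periods * res.T
    activations, counts = {}, {}
    for name, cfg in cells.items():
        params = derive_parameters(None, cfg["h"], cfg["y0"])
        act, n = _drive_cell_with_trains(
            params, spikes, CPG_IDS, {}, cfg["c_ex"], cpg["dt"], t_end, t_obs)
        activations[name] = act
        counts[name] = n
    return ReaderReport(mode=res.label, activations=activations, counts=counts,
                        extra=dict(T=res.T))


def tuned_resonance_study(
    cpg_names: dict[str, str] | None = None,
    ratio_target: float = 50.0,
) -> dict:
    """Full resonance-method demonstration, retuned to this model's modes.

    Measures the pulse rate omega0(m) = 2 pi n / T of the IP, AP and splay
    CPG configurations, tunes one stable-focus cell to each rate, selects
    per-pulse amplitudes from the critical-amplitude curves, and returns the
    3x3 mode-versus-cell activation matrix together with the tuned setup.
    """
    from .mode_analysis import parse_label

    if cpg_names is None:
        cpg_names = {"IP": "cpg_ip", "AP": "cpg_ap", "S": "cpg_splay_stable"}
    omegas: dict[str, float] = {}
    trains: dict[str, SpikeTrain] = {}
    horizons: dict[str, float] = {}
    for mode, preset in cpg_names.items():
        cpg = PRESETS[preset]
        fixture = build_fixture(h=cpg["h"], y0=cpg.get("y0", 0.0))
        spec = build_cpg_spec(parse_label(_RES_SEED[mode]), fixture,
                              cpg["c_inh"], cpg["tau"], cpg["dt"])
        t_end = 20.5 * fixture.period
        _, spikes = simulate(spec, t_end, sample_dt=5.0)
        res = classify_detail(spikes, n_discard=4)
        if str(res.label) != _RES_SEED[mode]:
            raise SimulationError(
                f"CPG preset {preset} settled into {res.label}, not {mode}")
        omegas[mode] = 2.0 * np.pi * _RES_NPER[mode] / res.T
        trains[mode] = spikes
        horizons[mode] = t_end
    cell_params = {
        f"A{i+1}": tune_resonance_cell(omegas[m], ratio_target)
        for i, m in enumerate(("IP", "AP", "S"))
    }
    amplitudes = plan_resonance_amplitudes(cell_params, omegas, _RES_NSIM)
    matrix: dict[str, dict[str, bool]] = {}
    for mode in ("IP", "AP", "S"):
        row = {}
        t_obs = 2.0 * 2.0 * np.pi / omegas[mode] * _RES_NPER[mode]
        for name, params in cell_params.items():
            act, _ = _drive_cell_with_trains(
                params, trains[mode], CPG_IDS, {}, amplitudes[name], 5.0,
                horizons[mode], t_obs)
            row[name] = act
        matrix[mode] = row
    return dict(
        omegas=omegas,
        cells={k: dict(h=v.h, y0=v.y0, c_ex=amplitudes[k])
               for k, v in cell_params.items()},
        matrix=matrix,
    )
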