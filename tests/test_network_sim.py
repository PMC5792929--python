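"""Event-driven network integration: pulses, spikes, convergence."""

import numpy as np
import pytest

from bzreader import (
    CouplingLink,
    ExternalSignal,
    NetworkSpec,
    OscillatorNode,
    derive_parameters,
    detect_spikes,
    find_steady_state,
    integrate_cell,
    natural_period,
    signal_windows,
    simulate,
)
from bzreader.network_sim import PulseWindow


def test_signal_window_count_and_timing():
    sig = ExternalSignal(id="s", omega=0.052, width=5.0)
    period = 2 * np.pi / sig.omega
    one = signal_windows(sig, period)
    assert len(one) == 1
    assert one[0].t_on == pytest.approx(np.arcsin(0.99) / sig.omega)
    assert one[0].t_off - one[0].t_on == pytest.approx(5.0)
    many = signal_windows(sig, 7 * period)
    assert len(many) == 7


def test_natural_period_isolated_cell(params_oscillatory):
    T0 = natural_period(params_oscillatory)
    assert T0 == pytest.approx(144.6, abs=1.0)


def test_natural_period_decreases_with_acidity():
    Ts = [natural_period(derive_parameters(None, h, 0.0)) for h in (0.29, 0.31)]
    assert Ts[0] > Ts[1]


def test_natural_period_repeatable_across_sampling(params_oscillatory):
    a = natural_period(params_oscillatory)
    b = natural_period(params_oscillatory, t_end=6390.0)
    assert abs(a - b) < 0.1


def _single_node_spec(params, initial):
    return NetworkSpec(nodes=[OscillatorNode(id="c", params=params, initial=initial)])


def test_window_summation_equals_double_amplitude(params_excitable):
    """Two coincident windows of amplitude C act exactly like one of 2C."""
    s0 = find_steady_state(params_excitable).state.as_array()
    w1 = [PulseWindow("c", "excitatory", 1.0e-6, 10.0, 15.0),
          PulseWindow("c", "excitatory", 1.0e-6, 10.0, 15.0)]
    w2 = [PulseWindow("c", "excitatory", 2.0e-6, 10.0, 15.0)]
    t1, _ = integrate_cell(params_excitable, s0, w1, 120.0, sample_dt=0.5)
    t2, _ = integrate_cell(params_excitable, s0, w2, 120.0, sample_dt=0.5)
    assert np.allclose(t1.states, t2.states, rtol=1e-6, atol=1e-15)


def test_injected_silver_quadrature():
    """Total injected species equals amplitude*width of the windows.

    With an empty cell and zero inflow the silver balance has no sink, so
    the integrated silver equals the window area exactly — a clean
    quadrature check of the rectangular-pulse bookkeeping."""
    params = derive_parameters(None, 0.3, 0.0)
    amp = 2.0e-7
    win = [PulseWindow("c", "excitatory", amp, 3.0, 8.0),
           PulseWindow("c", "excitatory", 0.5 * amp, 6.0, 10.0)]
    traj, _ = integrate_cell(params, np.zeros(5), win, 20.0, sample_dt=1.0)
    total = amp * 5.0 + 0.5 * amp * 4.0
    assert traj.states[0, 4, -1] == pytest.approx(total, rel=1e-9)


def test_injected_inhibitor_retention(params_excitable):
    """An inhibitory window raises bromide by at most amplitude*width; part
    of the injection relaxes away already during the window."""
    s0 = find_steady_state(params_excitable).state.as_array()
    amp, width = 2.0e-7, 5.0
    win = [PulseWindow("c", "inhibitory", amp, 0.0, width)]
    drv, _ = integrate_cell(params_excitable, s0, win, width, sample_dt=width / 10)
    ref, _ = integrate_cell(params_excitable, s0, [], width, sample_dt=width / 10)
    dy = drv.states[0, 1, -1] - ref.states[0, 1, -1]
    assert 0.5 * amp * width < dy < amp * width


def test_zero_coupling_equals_isolated(params_oscillatory, fixture_h03):
    init = [fixture_h03.at_phase(0.2), fixture_h03.at_phase(0.7)]
    nodes = [OscillatorNode(id=f"o{i}", params=params_oscillatory, initial=init[i])
             for i in range(2)]
    links = [CouplingLink(source="o0", target="o1", kind="inhibitory",
                          amplitude=0.0, delay=10.0, width=5.0)]
    coupled, spk_c = simulate(NetworkSpec(nodes=nodes, links=links), 400.0)
    solo, spk_s = simulate(_single_node_spec(params_oscillatory, init[1]), 400.0)
    # jointly integrated system shares step-size control, so agreement is
    # bounded by the solver tolerance, not bitwise
    assert np.allclose(coupled.states[1], solo.states[0], rtol=1e-3, atol=1e-12)
    assert np.max(np.abs(spk_c["o1"] - spk_s["c"])) < 0.05


def test_state_bounds_along_oscillation(params_oscillatory):
    traj, spikes = simulate(
        _single_node_spec(params_oscillatory, np.array([1e-8, 1e-8, 1e-6, 1e-5, 0.0])),
        1500.0)
    assert traj.states.min() >= -1e-12
    assert traj.states[0, 2].max() <= params_oscillatory.c0 * (1 + 1e-9)
    assert len(spikes["c"]) > 5


def test_detector_on_flat_trajectory(params_excitable):
    s0 = find_steady_state(params_excitable).state.as_array()
    traj, _ = integrate_cell(params_excitable, s0, [], 300.0)
    assert len(detect_spikes(traj)["cell"]) == 0


def test_detector_threshold_invariance(params_oscillatory):
    """Spike times barely move when the threshold varies over a decade,
    because the activator rises orders of magnitude within a second."""
    traj, _ = simulate(
        _single_node_spec(params_oscillatory, np.array([1e-8, 1e-8, 1e-6, 1e-5, 0.0])),
        1200.0, sample_dt=0.25)
    base = detect_spikes(traj, theta=3e-6)["c"]
    for theta in (1e-6, 1e-5, 3e-5):
        other = detect_spikes(traj, theta=theta)["c"]
        assert len(other) == len(base)
        assert np.max(np.abs(other - base)) < 1.0


def test_spike_times_stable_under_tighter_tolerances(fixture_h03, params_oscillatory):
    """Refining solver tolerances tenfold moves spike times by < 0.05 s."""
    spec = _single_node_spec(params_oscillatory, fixture_h03.at_phase(0.5))
    _, a = simulate(spec, 2000.0, rtol=1e-9, atol=1e-12)
    _, b = simulate(spec, 2000.0, rtol=1e-10, atol=1e-13)
    assert len(a["c"]) == len(b["c"])
    assert np.max(np.abs(a["c"] - b["c"])) < 0.05


def test_single_pulse_above_threshold_gives_one_spike(params_excitable):
    s0 = find_steady_state(params_excitable).state.as_array()
    win = [PulseWindow("c", "excitatory", 5.0e-6, 0.0, 5.0)]
    _, ts = integrate_cell(params_excitable, s0, win, 450.0)
    assert len(ts) == 1


def test_delayed_pulse_scheduling(params_oscillatory, params_excitable, fixture_h03):
    """A spike in the source opens the target's window delay seconds later."""
    s0 = find_steady_state(params_excitable).state.as_array()
    nodes = [
        OscillatorNode(id="src", params=params_oscillatory,
                       initial=fixture_h03.at_phase(0.9)),
        OscillatorNode(id="dst", params=params_excitable, initial=s0, role="A"),
    ]
    links = [CouplingLink(source="src", target="dst", kind="excitatory",
                          amplitude=5.0e-6, delay=25.0, width=5.0)]
    traj, spikes = simulate(NetworkSpec(nodes=nodes, links=links), 300.0,
                            sample_dt=0.5)
    t_src = spikes["src"][0]
    t_dst = spikes["dst"][0]
    assert t_dst > t_src + 25.0
    assert t_dst < t_src + 40.0


def test_invalid_specs_rejected(params_oscillatory):
    node = OscillatorNode(id="a", params=params_oscillatory,
                          initial=np.zeros(5))
    with pytest.raises(ValueError):
        NetworkSpec(nodes=[node, node])
    with pytest.raises(ValueError):
        NetworkSpec(nodes=[node],
                    links=[CouplingLink(source="ghost", target="a",
                                        kind="inhibitory", amplitude=1e-6)])
    with pytest.raises(ValueError):
        CouplingLink(source="a", target="a", kind="sideways", amplitude=1e-6)
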