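"""Steady states, spectra, Hopf threshold and excitability thresholds."""

import numpy as np
import pytest

from bzreader import (
    derive_parameters,
    find_steady_state,
    hopf_threshold,
    jacobian,
    min_pulse_amplitude,
    spectrum_at,
    subthreshold_trajectory,
)
from bzreader.linstab import SteadyStateError


def test_steady_state_matches_published_focus(params_focus):
    ss = find_steady_state(params_focus)
    assert ss.y_ss == pytest.approx(8.68402e-6, rel=1e-3)
    assert ss.state.x == pytest.approx(2.3055e-7, rel=1e-3)
    assert ss.residual < 1e-14


def test_steady_state_excitable_row(params_excitable):
    ss = find_steady_state(params_excitable)
    assert ss.y_ss == pytest.approx(23.7e-6, rel=1e-2)


def test_steady_state_increases_with_inflow():
    y_ss = []
    for y0 in (1.4e-3, 2.0e-3, 4.0e-3, 8.0e-3, 20.0e-3):
        ss = find_steady_state(derive_parameters(None, 0.3, y0))
        y_ss.append(ss.y_ss)
    assert np.all(np.diff(y_ss) > 0)


def test_spectrum_focus_frequency(params_focus):
    sp = spectrum_at(params_focus)
    assert sp.im == pytest.approx(0.0538, rel=0.01)
    assert sp.re < 0
    # eigenvalues sorted by descending real part, conjugate pair present
    re_parts = [ev.real for ev in sp.eigenvalues]
    assert re_parts == sorted(re_parts, reverse=True)
    assert any(ev.imag < 0 for ev in sp.eigenvalues)


def test_spectrum_reports_complex_pair_not_leading_real():
    # at high acidity the leading eigenvalue is real but the focus frequency
    # is carried by the complex pair
    sp = spectrum_at(derive_parameters(None, 0.8623, 5.429e-3))
    assert abs(sp.leading.imag) < 1e-12
    assert sp.im == pytest.approx(0.24571, rel=0.01)


def test_eigenvalues_match_finite_difference_jacobian(params_focus):
    """Spectrum of the analytic Jacobian agrees with a finite-difference
    Jacobian oracle at the converged steady state to 1e-5 relative."""
    ss = find_steady_state(params_focus)
    arr = ss.state.as_array()[:4]
    from bzreader import BZState, rhs

    J_fd = np.empty((4, 4))
    for j in range(4):
        h = 1e-7 * max(arr[j], 1e-9)
        sp_, sm_ = arr.copy(), arr.copy()
        sp_[j] += h
        sm_[j] -= h
        dp = rhs(BZState(*sp_), params_focus).as_array()[:4]
        dm = rhs(BZState(*sm_), params_focus).as_array()[:4]
        J_fd[:, j] = (dp - dm) / (2 * h)
    ev_a = np.sort_complex(np.linalg.eigvals(jacobian(ss.state, params_focus)))
    ev_f = np.sort_complex(np.linalg.eigvals(J_fd))
    assert np.allclose(ev_a, ev_f, rtol=1e-5)


def test_hopf_threshold_location_and_stability():
    hp = hopf_threshold(h=0.3)
    assert hp.y0H == pytest.approx(1.3331e-3, rel=1e-3)
    assert hp.ySSH == pytest.approx(8.58e-6, rel=1e-3)
    # above threshold the steady state is stable
    sp = spectrum_at(derive_parameters(None, 0.3, 1.1 * hp.y0H))
    assert sp.leading.real < 0


def test_hopf_threshold_invariant_under_tighter_tolerance():
    a = hopf_threshold(h=0.3, xtol=1e-10)
    b = hopf_threshold(h=0.3, xtol=5e-11)
    assert abs(a.y0H - b.y0H) < 1e-8


def test_hopf_invalid_bracket():
    with pytest.raises(ValueError):
        hopf_threshold(h=0.3, bracket=(2e-3, 3e-3))


def test_subthreshold_trajectory(params_focus):
    ss = find_steady_state(params_focus)
    sp = spectrum_at(params_focus, ss)
    y_ini = 1e-7
    t = np.linspace(0, 500, 2001)
    y = subthreshold_trajectory(ss, sp, y_ini, t)
    # initial value
    assert y[0] == pytest.approx(ss.y_ss + y_ini, rel=1e-12)
    # envelope at whole periods is non-increasing
    tk = 2 * np.pi * np.arange(4) / sp.im
    yk = subthreshold_trajectory(ss, sp, y_ini, tk)
    assert np.all(np.diff(np.abs(yk - ss.y_ss)) < 0)
    # first zero crossing of (y - y_ss) at pi/(2 w0)
    z = np.nonzero(np.diff(np.sign(y - ss.y_ss)))[0][0]
    assert t[z] == pytest.approx(np.pi / (2 * sp.im), abs=t[1] - t[0])


def test_min_pulse_amplitude_increases_with_inflow():
    c2 = min_pulse_amplitude(derive_parameters(None, 0.3, 2.0e-3))
    c4 = min_pulse_amplitude(derive_parameters(None, 0.3, 4.0e-3))
    assert 0 < c2 < c4


def test_min_pulse_amplitude_rejects_oscillatory_cell():
    with pytest.raises(SteadyStateError):
        min_pulse_amplitude(derive_parameters(None, 0.3, 0.0))
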