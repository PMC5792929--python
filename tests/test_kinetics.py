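"""Unit tests of the four-variable BZ cell model."""

import numpy as np
import pytest

from bzreader import BZState, PulseDrive, RateConstants, derive_parameters, jacobian, rhs
from bzreader._kernels import network_jac, network_rhs
from bzreader.kinetics import param_vector

# (3 kr k10 c0)^(1/2) / kred with the default constants, evaluated by hand
CMIN_DEFAULT = 1.0954451150103324e-05


def test_derived_rates():
    p = derive_parameters(None, h=0.3, y0=0.0)
    assert p.k1 == pytest.approx(6e5)
    assert p.k2 == pytest.approx(2.0 * 0.09 * 0.25)
    assert p.k4 == pytest.approx(42.0 * 0.3 * 0.25)
    assert p.k10 == pytest.approx(5e-3)
    assert p.cmin == pytest.approx(CMIN_DEFAULT, rel=1e-12)
    assert p.cmin < p.c0 / 10


@pytest.mark.parametrize("bad", [0.0, -0.1])
def test_invalid_proton_concentration(bad):
    with pytest.raises(ValueError):
        derive_parameters(None, h=bad, y0=0.0)


def test_negative_inflow_rejected():
    with pytest.raises(ValueError):
        derive_parameters(None, h=0.3, y0=-1e-3)


def test_nonpositive_rate_constant_rejected():
    with pytest.raises(ValueError):
        RateConstants(k3=0.0)


def test_rhs_at_origin_reduces_to_inflow():
    p = derive_parameters(None, h=0.3, y0=2e-3)
    d = rhs(BZState(0, 0, 0, 0, 0), p)
    k0 = p.raw.k0
    assert d.x == 0 and d.z == 0 and d.v == 0 and d.ag == 0
    assert d.y == pytest.approx(k0 * p.y0, rel=1e-14)


def test_rhs_vanishes_at_published_steady_state(params_focus):
    # steady state printed for the stable-focus showcase cell; the printed
    # values carry 5-7 digits, so the residual is rounding-limited relative
    # to the dominant balance terms (~1e-6 M/s)
    s = BZState(x=2.3055e-7, y=8.68402e-6, z=1.14411e-4, v=5.270125e-4)
    d = rhs(s, params_focus)
    p = params_focus
    scale = p.k1 * s.x * s.y + p.k2 * s.y
    for comp in (d.x, d.y, d.z, d.v):
        assert abs(comp) < 1e-4 * scale


def test_inhibitory_drive_is_additive(params_excitable):
    s = BZState(1e-7, 1e-5, 1e-4, 5e-4, 0.0)
    base = rhs(s, params_excitable)
    driven = rhs(s, params_excitable, PulseDrive(inh=3.7e-6))
    assert driven.y - base.y == pytest.approx(3.7e-6, rel=1e-12)
    assert driven.x == base.x and driven.z == base.z and driven.v == base.v


def test_silver_free_model_reduces_to_four_variables(params_excitable):
    s = BZState(2e-7, 9e-6, 1e-4, 5e-4, ag=0.0)
    d = rhs(s, params_excitable)
    assert d.ag == 0.0
    J5 = jacobian(s, params_excitable, include_silver=True)
    J4 = jacobian(s, params_excitable)
    assert np.allclose(J5[:4, :4], J4)


def test_jacobian_entry_matches_inhibitor_balance(params_excitable):
    p = params_excitable
    s = BZState(0.0, 1e-5, 1e-4, 0.0, 0.0)
    J = jacobian(s, p)
    assert J[1, 1] == pytest.approx(-(p.k2 + p.raw.k0), rel=1e-14)


def _random_states(rng, n):
    # concentrations spanning the magnitudes visited along a spike
    for _ in range(n):
        yield BZState(
            x=10 ** rng.uniform(-9, -4),
            y=10 ** rng.uniform(-8, -3),
            z=10 ** rng.uniform(-7, -3.1),
            v=10 ** rng.uniform(-6, -2),
            ag=10 ** rng.uniform(-12, -7),
        )


def test_jacobian_matches_finite_differences(rng, params_excitable):
    """Analytic partial derivatives agree with central differences on 100
    random states across the dynamic range of the model."""
    p = params_excitable
    for s in _random_states(rng, 100):
        arr = s.as_array()
        J = jacobian(s, p, include_silver=True)
        for j in range(5):
            # step large enough that central-difference round-off stays
            # below the 1e-6 relative agreement being asserted
            h = max(1e-4 * arr[j], 1e-9)
            sp, sm = arr.copy(), arr.copy()
            sp[j] += h
            sm[j] -= h
            dp = rhs(BZState.from_array(sp), p)
            dm = rhs(BZState.from_array(sm), p)
            col = (dp.as_array() - dm.as_array()) / (2 * h)
            tol = 1e-6 * np.abs(J[:, j]) + 1e-6 * np.abs(J[:, j]).max() + 1e-9
            assert np.all(np.abs(col - J[:, j]) <= tol)


def test_compiled_kernels_match_reference(rng, params_excitable):
    """The numba network kernels equal the plain-python single-cell model."""
    p = params_excitable
    P = param_vector(p)[None, :]
    for s in _random_states(rng, 20):
        arr = s.as_array()
        d_ref = rhs(s, p, PulseDrive(inh=1e-6, exc=2e-7)).as_array()
        d_k = network_rhs(arr, P, np.array([1e-6]), np.array([2e-7]))
        assert np.allclose(d_k, d_ref, rtol=1e-14, atol=0)
        J_ref = jacobian(s, p, include_silver=True)
        J_k = network_jac(arr, P)
        assert np.allclose(J_k, J_ref, rtol=1e-14, atol=0)


def test_rhs_as_array_helper():
    s = BZState.from_array(np.array([1.0, 2.0, 3.0, 4.0]))
    assert s.ag == 0.0
    assert np.allclose(s.as_array(), [1, 2, 3, 4, 0])
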