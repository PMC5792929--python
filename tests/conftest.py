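import numpy as np
import pytest

from bzreader import derive_parameters
from bzreader.cli_io import PRESETS, build_fixture
from bzreader.mode_analysis import all_mode_labels
from bzreader.readers import build_delay_table, calibrate_mode


@pytest.fixture(scope="session")
def fixture_h03():
    return build_fixture(h=0.3)


@pytest.fixture(scope="session")
def params_oscillatory():
    return derive_parameters(None, 0.3, 0.0)


@pytest.fixture(scope="session")
def params_excitable():
    return derive_parameters(None, 0.3, 4.0e-3)


@pytest.fixture(scope="session")
def params_focus():
    """The stable-focus showcase cell (very close to its Hopf threshold)."""
    return derive_parameters(None, 0.371757, 1.7743e-3)


@pytest.fixture(scope="session")
def delay_tables():
    """All 26 delay tables, calibrated from each sub-mode's settled pattern.

    Calibration itself asserts the seed -> simulate -> classify round trip:
    it raises if any seeded sub-mode fails to classify back to its label.
    """
    cpg = PRESETS["cpg_delay"]
    fixture = build_fixture(h=cpg["h"], y0=cpg.get("y0", 0.0))
    tables = []
    for label in all_mode_labels():
        T, off = calibrate_mode(label, fixture, cpg["c_inh"], cpg["tau"], cpg["dt"])
        tables.append(build_delay_table(label, T, offsets=off))
    return tables


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
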