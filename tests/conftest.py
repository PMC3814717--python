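"""Shared fixtures: model presets, calibrated operating points, and small
operating tables, computed once per session."""

import numpy as np
import pytest

from synchrate import (NeuronParams, build_operating_table,
                       calibrate_operating_point)


@pytest.fixture(scope="session")
def lif():
    return NeuronParams.lif()


@pytest.fixture(scope="session")
def qif():
    return NeuronParams.qif()


@pytest.fixture(scope="session")
def eif():
    return NeuronParams.eif()


@pytest.fixture(scope="session")
def eif_baseline(eif):
    """(mu, sigma) of the 50 Hz / CV 0.1 network baseline for the EIF."""
    return calibrate_operating_point(eif, 50.0, 0.1)


@pytest.fixture(scope="session")
def eif_step_table(eif):
    """Small table around mu in [10, 16] at sigma near 1 for step drives."""
    return build_operating_table(eif, np.linspace(9.0, 17.0, 9),
                                 np.array([0.8, 1.0, 1.2]),
                                 with_eigenvalues=False)


@pytest.fixture(scope="session")
def eif_network_table(eif):
    """Wide (mu, sigma) table covering the E-I network's drive range."""
    return build_operating_table(eif, np.arange(-20.0, 50.1, 2.0),
                                 np.geomspace(0.4, 8.0, 14),
                                 with_eigenvalues=False)
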