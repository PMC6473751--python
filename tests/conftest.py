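import numpy as np
import pytest

import stiffsim as ss


@pytest.fixture(scope="session")
def cygggyc():
    return ss.TABLE_KINETICS["cygggyc"]


@pytest.fixture(scope="session")
def ltyr():
    return ss.TABLE_KINETICS["l-tyr"]


@pytest.fixture(scope="session")
def ldopa():
    return ss.TABLE_KINETICS["l-dopa"]


@pytest.fixture(scope="session")
def stiff_slab():
    """1 mm slab with the stiff-gel diffusivity, unit surface concentration."""
    return ss.SlabProblem(thickness_m=1e-3, diffusivity=3.58e-11,
                          surface_concentration=1.0)


@pytest.fixture(scope="session")
def coarse_grid():
    """Fast grid for coupled runs: 10 um / 1 s, 8 h horizon, 60 s output."""
    return ss.Grid1D(dx_m=10e-6, dt_s=1.0, horizon_s=8 * 3600.0,
                     output_every=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
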