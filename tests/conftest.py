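import numpy as np
import pytest

from tftgrad import (
    Grid, MaturationParams, default_params, make_model, simulate,
)

T_NC14 = 2.5 * 3600.0  # observation time (s), early nuclear cycle 14


@pytest.fixture(scope="session")
def grid():
    return Grid(500.0, 250)


@pytest.fixture(scope="session")
def coarse_grid():
    return Grid(500.0, 100)


@pytest.fixture(scope="session")
def sdd_spec():
    return make_model("SDD", default_params("SDD"))


@pytest.fixture(scope="session")
def all_specs():
    return {name: make_model(name, default_params(name))
            for name in ("SDD", "NucSh", "RNA-grad", "RNA-diff")}


@pytest.fixture(scope="session")
def maturation():
    """Exact preset means (no prior SDs): sfGFP 27 min, mCherry 40 + 9 min."""
    return MaturationParams(27.0, 40.0, 9.0)


@pytest.fixture(scope="session")
def sdd_state_nc14(sdd_spec, grid, maturation):
    """Six-state SDD field at 2.5 h on the default grid (shared by tests)."""
    return simulate(sdd_spec, grid, t_end=T_NC14, dt_out=T_NC14,
                    maturation=maturation)[-1]


@pytest.fixture(scope="session")
def sdd_history_nc14(sdd_spec, grid, maturation):
    """Six-state SDD history (5-min snapshots) for flux-integral tests."""
    return simulate(sdd_spec, grid, t_end=T_NC14, dt_out=300.0,
                    maturation=maturation)
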