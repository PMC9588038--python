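import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import diazocomp as dz
from diazocomp.geometry import BoxGeometry
from diazocomp.state import EcosystemState

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return dz.default_geometry()


@pytest.fixture(scope="session")
def contr_equilibrium(geometry):
    """A CONTR quasi-equilibrium shared by the slower integration tests."""
    config = dz.build_config("CONTR")
    return dz.spinup_to_equilibrium(config, geometry, max_years=800)


def single_column_geometry(kv=0.02, temp=25.0, J_IO=10.0, fe=1.0,
                           denit=False):
    """One warm, light-saturated column for chemostat-style oracles."""
    return BoxGeometry(
        names=("column",), band=np.array([2]), area=np.array([1.0e12]),
        temp=np.array([temp]), J_IO=np.array([J_IO]), kv=np.array([kv]),
        fe_limit=np.array([fe]), denit_box=np.array([denit]),
    )


def single_column_state(NO3_deep, PO4_deep, P_O=0.05, P_D=0.05):
    data = np.zeros((1, 2, 6))
    data[0, 1, 0] = NO3_deep
    data[0, 1, 1] = PO4_deep
    data[0, 0, 0] = NO3_deep / 10.0
    data[0, 0, 1] = PO4_deep / 10.0
    data[0, 0, 2] = P_O
    data[0, 0, 3] = P_D
    return EcosystemState(data)


def random_state(rng, n_col):
    """A positive, physically plausible random state."""
    data = rng.uniform(0.0, 1.0, size=(n_col, 2, 6))
    data[:, :, 0] *= 30.0     # NO3
    data[:, :, 1] *= 2.5      # PO4
    return EcosystemState(data)
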