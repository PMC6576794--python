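import numpy as np
import pytest

from landscape_kinetics import fp, synthetic


@pytest.fixture(scope="session")
def grid128():
    return np.linspace(0.0, 6.0, 128)


@pytest.fixture(scope="session")
def double_well_model(grid128):
    """Asymmetric double well (no growth), used by several solver tests."""
    g = grid128
    U = 0.05 * (g - 3.0) ** 2 \
        - 0.40 * np.exp(-((g - 2.0) ** 2) / (2 * 0.35**2)) \
        - 0.25 * np.exp(-((g - 4.0) ** 2) / (2 * 0.40**2))
    mu = -2.0 * np.gradient(U, g)
    return fp.LandscapeModel(grid=g, D=0.35, mu=mu)


@pytest.fixture(scope="session")
def gaussian_p0(grid128):
    p = np.exp(-((grid128 - 2.0) ** 2) / (2 * 0.25**2))
    return p / np.trapezoid(p, grid128)


@pytest.fixture(scope="session")
def m397_clouds():
    """Small drug-treated cloud series shared by trajectory tests."""
    truth = synthetic.m397_like_simulation_truth(
        n_grid=192, cells_per_timepoint=2500, seed=11)
    clouds = synthetic.gen_flow_clouds(truth, synthetic.M397_TIMEPOINTS)
    return truth, clouds
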