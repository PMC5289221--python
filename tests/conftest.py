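import numpy as np
import pytest

import tlgate as tg


@pytest.fixture(scope="session")
def initial_params():
    return tg.RateParams.preset("initial")


@pytest.fixture(scope="session")
def revised_params():
    return tg.RateParams.preset("revised")


@pytest.fixture(scope="session")
def reduced_params():
    """Low-production regime where the truncated CME is cheap and tight."""
    return tg.RateParams(kprodA=5.0, kprodB=5.0, kdeg=0.3,
                         kflipA=0.4, kflipB=0.4, KdA=10.0, KdB=10.0)


@pytest.fixture(scope="session")
def reduced_grid():
    return np.linspace(0.0, 10.0, 41)


@pytest.fixture(scope="session")
def reduced_ensemble(reduced_params, reduced_grid):
    profile = tg.InductionProfile.step_pair(0.0)
    return tg.simulate_population(reduced_params, profile, t_end=10.0,
                                  n_cells=10_000, seed=6, grid=reduced_grid)


@pytest.fixture(scope="session")
def reduced_cme(reduced_params, reduced_grid):
    profile = tg.InductionProfile.step_pair(0.0)
    return tg.solve_truncated_cme(reduced_params, profile, 10.0,
                                  capA=40, capB=40, grid=reduced_grid)


@pytest.fixture(scope="session")
def calib_table(revised_params):
    """Synthetic 7x7 (∆t, PW_b) calibration with default noise, 3 replicates."""
    design = [(dt, pw) for dt in range(7) for pw in range(7)]
    return tg.generate_fraction_dataset(revised_params, design,
                                        noise=tg.NoiseModel(), n_cells=500,
                                        seed=7)


@pytest.fixture(scope="session")
def calib_surface(calib_table):
    return tg.fit_surface(calib_table)
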