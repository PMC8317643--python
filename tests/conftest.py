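import numpy as np
import pytest

from restforge.cell import default_stim_amplitude
from restforge.params import make_base_params


@pytest.fixture(scope="session")
def base_params():
    return make_base_params()


@pytest.fixture(scope="session", autouse=True)
def _warm_stimulus():
    # calibrate the shared stimulus amplitude once (also warms numba caches)
    default_stim_amplitude()


@pytest.fixture(scope="session")
def ga_fits():
    """Scaled GA calibrations for both cohorts (shared across tests).

    Population 100, at most 60 generations, fixed seed — the desk-scale
    settings used throughout the acceptance checks.
    """
    from restforge.ga import GACalibrator

    fits = {}
    for cohort in ("snlv", "icmp"):
        fits[cohort] = GACalibrator(
            seed=1, population_size=100, max_generations=60
        ).fit(cohort)
    return fits


@pytest.fixture(scope="session")
def tissue_cfg():
    from restforge.tissue import TissueConfig, calibrate_kappa

    return TissueConfig(kappa=calibrate_kappa())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
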