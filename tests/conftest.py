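import numpy as np
import pytest

from thalnet.atlas import default_atlas
from thalnet.cohort import CohortConfig, PlantedEffect


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort that keeps every pipeline stage exercised."""
    return CohortConfig(
        group_sizes={"control": 24, "TLE": 14, "FLE": 8, "PQE": 6},
        calibration_samples=15,
        seed=7,
    )


@pytest.fixture()
def volume_only_config():
    """No connectivity effects: cohort generation skips AUC calibration."""
    return CohortConfig(
        group_sizes={"control": 24, "TLE": 14, "FLE": 8, "PQE": 6},
        planted_effects=[
            PlantedEffect("volume", "anterior", "ipsi", "patients", -0.6)
        ],
        duration_effects=[],
        seed=11,
    )


@pytest.fixture(scope="session")
def random_symmetric():
    def make(n, seed=0, scale=0.3):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, scale, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        return a

    return make
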