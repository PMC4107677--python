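import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stnfc.core import VolumeGrid
from stnfc.seed_fc import FCMap
from stnfc.synthetic import SimulationConfig, simulate_cohort, null_config

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid_246():
    """Acquisition-like grid: 3.1 mm isotropic, TR 2.2 s."""
    return VolumeGrid.isotropic((8, 8, 8), 3.1, 2.2)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small in-memory cohort with baseline couplings but no age effects."""
    cfg = null_config(n_subjects=12, n_volumes=60, rng_seed=11,
                      grid=VolumeGrid.isotropic((12, 12, 12), 3.1, 2.2))
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_361_phenotypes():
    return __import__("stnfc.synthetic", fromlist=["sample_phenotypes"]).sample_phenotypes(
        SimulationConfig(rng_seed=1)
    )


def make_phenotypes(ages, sexes=None, sites=None):
    n = len(ages)
    if sexes is None:
        sexes = ["F" if i % 3 == 0 else "M" for i in range(n)]
    if sites is None:
        sites = [f"site_{i % 2 + 1}" for i in range(n)]
    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "subject_id": ids,
            "age_years": np.asarray(ages, float),
            "sex": pd.Categorical(sexes),
            "site": pd.Categorical(sites),
            "bold_path": [f"{s}_bold.nii.gz" for s in ids],
            "motion_path": [f"{s}_motion.txt" for s in ids],
        }
    )
    return df


def make_fcmap(grid, z_volume, subject_id="sub-0001", mask=None):
    z_volume = np.asarray(z_volume, float)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    z_volume = np.where(mask, z_volume, 0.0)
    return FCMap(grid=grid, z_values=z_volume, mask=mask,
                 subject_id=subject_id, seed_source="bilateral")
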