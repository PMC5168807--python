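import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from survscreen.simulate import (PlantedMarker, SimulationConfig,
                                 simulate_cohort)

SMALL_COUNTS = {"mirna": 30, "mrna": 50, "protein": 25, "cnv": 24,
                "methylation": 40, "mutation": 15}


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with planted effects on several platforms."""
    cfg = SimulationConfig(
        n_patients=260,
        feature_counts=dict(SMALL_COUNTS),
        planted=(
            PlantedMarker("mrna", 5, np.log(3.0)),
            PlantedMarker("methylation", 7, np.log(3.0), stage_coupling=0.5),
            PlantedMarker("methylation", 9, np.log(2.0),
                          pair_with=("mirna", 3, -1.0)),
            PlantedMarker("cnv", 4, np.log(2.0)),
            PlantedMarker("mutation", 2, np.log(4.0)),
        ),
        censoring_fraction=0.5,
        n_normals={"methylation": 25, "mirna": 25},
        rng_seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_null_cohort():
    """A small cohort with no planted signal and null clinical effects."""
    cfg = SimulationConfig(
        n_patients=240,
        feature_counts={"mrna": 60, "methylation": 30},
        planted=(),
        clinical_betas={"gender": 0.0, "age_per_decade": 0.0,
                        "grade": 0.0, "stage": 0.0},
        censoring_fraction=0.4,
        rng_seed=5,
    )
    return simulate_cohort(cfg)


def random_censored(rng, n, cens_scale=2.0, tie_grid=None):
    """Random censored survival data for oracle comparisons."""
    from survscreen.stats import survival_array
    t_event = rng.exponential(1.0, n)
    t_cens = rng.exponential(cens_scale, n)
    t = np.minimum(t_event, t_cens)
    e = t_event <= t_cens
    if tie_grid:
        t = np.ceil(t * tie_grid) / tie_grid
    return survival_array(t, e)
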