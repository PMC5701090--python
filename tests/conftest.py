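import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mstrisk import SimulationConfig, simulate_cohort_genotypes, simulate_reference

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_read_config(**overrides) -> SimulationConfig:
    """A read-level config small enough for per-test simulation.

    Depth keeps the high-coverage regime of the study design; the locus
    and sample counts are reduced for test runtime.
    """
    params = dict(
        seed=11,
        n_loci=8,
        n_informative=3,
        n_cases=6,
        n_controls=10,
        tract_len_range=(12, 20),
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def default_cohort():
    """Genotype-level cohort at the full default study design (347 loci,
    30 cases / 89 controls, 13 informative)."""
    config = SimulationConfig(seed=29)
    _, catalog = simulate_reference(config)
    matrix, manifest = simulate_cohort_genotypes(config, catalog)
    return config, catalog, matrix, manifest


@pytest.fixture(scope="session")
def loocv_cohort():
    """30/89 cohort over a reduced panel, sized for LOOCV runtime."""
    config = SimulationConfig(seed=5, n_loci=20, n_informative=8)
    _, catalog = simulate_reference(config)
    matrix, manifest = simulate_cohort_genotypes(config, catalog)
    return config, matrix, manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
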