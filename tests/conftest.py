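import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promoter_turnover.classify import ClassifierConfig, classify_promoters
from promoter_turnover.expression import build_profiles
from promoter_turnover.sim import SimulationConfig, noise_free, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


NOISE_FREE_CONFIG = noise_free(
    SimulationConfig(
        seed=2024,
        n_ancestral_promoters=500,
        genome_length=1_200_000,
        insertion_rate_per_lineage=60.0,
        deletion_rate_per_lineage=40.0,
        mouse_deletion_multiplier=4.0,
        n_variants=0,
    )
)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """A seeded 500-promoter, two-lineage dataset with observation noise off."""
    return simulate_dataset(NOISE_FREE_CONFIG)


@pytest.fixture(scope="session")
def noise_free_profiles(noise_free_dataset):
    return {
        sp: build_profiles(*noise_free_dataset.expression[sp])
        for sp in noise_free_dataset.config.species
    }


@pytest.fixture(scope="session")
def noise_free_outcomes(noise_free_dataset, noise_free_profiles):
    ds = noise_free_dataset
    cfg = ClassifierConfig()
    sp_a, sp_b = ds.config.species
    out = {}
    for sp, other in ((sp_a, sp_b), (sp_b, sp_a)):
        out[sp] = classify_promoters(
            ds.promoters[sp], ds.alignment_statuses[sp], other,
            ds.promoters[other], noise_free_profiles[sp],
            noise_free_profiles[other], cfg,
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
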