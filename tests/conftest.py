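"""Shared fixtures: small synthetic worlds generated at test time (no stored data)."""

import pytest

from linkbias.config import (
    CorruptionConfig,
    ExperimentConfig,
    MatchParams,
    OutcomeConfig,
    PopulationConfig,
    THRESHOLD_PERCENTILES,
)
from linkbias.outcome import threshold_experiment
from linkbias.pipeline import attenuation_world_config
from linkbias.synthetic_data import generate_population, generate_world


@pytest.fixture(scope="session")
def small_world():
    """Default high-corruption replicate world: 800 persons, 160 diagnoses."""
    cfg = attenuation_world_config(seed=1)
    return generate_world(cfg.population, cfg.outcome, cfg.corruption, seed=1)


@pytest.fixture(scope="session")
def small_report(small_world):
    cfg = attenuation_world_config(seed=1)
    return threshold_experiment(small_world, cfg.match, cfg.percentiles)


@pytest.fixture(scope="session")
def perfect_world():
    """Error-free encounters over a fully complete registry (large households so
    that every cohort member has a recordable household-member name)."""
    pop = PopulationConfig(
        n_people=600,
        mean_household_size=8.0,
        registry_completeness={k: 1.0 for k in
                               ("birth_year", "birth_month", "birth_day",
                                "tcl_name", "hh_member_name")},
    )
    out = OutcomeConfig(cohort_size=120)
    return generate_world(pop, out, CorruptionConfig.perfect(), seed=3)


@pytest.fixture(scope="session")
def tiny_population():
    return generate_population(PopulationConfig(n_people=300), seed=11)


@pytest.fixture()
def default_params():
    return MatchParams()
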