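"""Shared fixtures: a small seeded synthetic study generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cohortcapture import synthetic


@pytest.fixture(scope="session")
def small_config() -> synthetic.PopulationConfig:
    return synthetic.PopulationConfig(
        n_patients=6000, disease_prevalence=0.344, seed=11
    )


@pytest.fixture(scope="session")
def population(small_config) -> pd.DataFrame:
    return synthetic.generate_population(small_config)


@pytest.fixture(scope="session")
def profiles(small_config) -> list:
    return synthetic.default_profiles(small_config.disease_prevalence)


@pytest.fixture(scope="session")
def membership(population, profiles) -> pd.DataFrame:
    return synthetic.generate_membership(population, profiles, seed=12)


@pytest.fixture(scope="session")
def disease_status(population) -> pd.Series:
    return population.set_index("patient_id")["disease_status"]


@pytest.fixture(scope="session")
def gold(membership, disease_status) -> pd.DataFrame:
    return synthetic.sample_gold_standard(
        membership, disease_status, n=1000, min_databases=2,
        split_fraction=0.3, target_prevalence=0.75, seed=13,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
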