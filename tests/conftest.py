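import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import colliderbias as cb

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_cohort6() -> pd.DataFrame:
    """Fixed 6-record cohort with continuous, untied times: the fixture for
    partial-likelihood oracle checks (one binary group term)."""
    return pd.DataFrame(
        {
            "id": range(6),
            "ethnicity": ["Black", "White", "Black", "White", "Black", "White"],
            "time_to_event": [2.3, 4.1, 5.7, 7.2, 9.9, 12.4],
            "event_type": ["death", "death", "discharge", "death", "censored", "death"],
            "weight": [1.5, 2.0, 1.0, 3.0, 1.2, 0.8],
        }
    )


def small_population(seed: int = 11, n: int = 30_000, **overrides) -> cb.SimulationConfig:
    """A quick single-wave simulation config for unit tests."""
    config = cb.SimulationConfig(
        population_size=n,
        wave_proportions={1: 1.0, 2: 0.0},
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(config, key, value)
    return config


@pytest.fixture(scope="session")
def collider_run(tmp_path_factory):
    """The reference collider scenario: a single-wave population of 200,000
    with survivor hospitalisation risks of a few per thousand, 90% of deaths
    hospitalised, and a true Black-vs-White death hazard ratio of 1.1.

    Session-scoped because the simulation and the three Cox fits are shared
    by several recovery and sensitivity checks.
    """
    out = tmp_path_factory.mktemp("collider-run")
    config = cb.AnalysisConfig(
        mode="synthetic",
        model_form="eq1",
        seed=20,
        output_dir=str(out),
    )
    config.simulation.wave_proportions = {1: 1.0, 2: 0.0}
    assert config.simulation.population_size == 200_000
    bundle = cb.run_analysis(config)
    return config, bundle
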