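import numpy as np
import pandas as pd
import pytest

from ewaskit import ModelSpec, PlantedEffect, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """200+200 cohort, 120 probes, one planted 5pp DMP and a DMR block."""
    cfg = SimulationConfig(n_cases=200, n_controls=200, n_probes=120, seed=11)
    effects = [
        PlantedEffect("dmp", ("cg0000010",), 5.0),
        PlantedEffect("dmr_block", tuple(f"cg{i:07d}" for i in range(40, 45)), 3.0, 0.5),
    ]
    return generate_cohort(cfg, effects)


@pytest.fixture(scope="session")
def null_cohort():
    """100+100 cohort with no planted effects."""
    cfg = SimulationConfig(n_cases=100, n_controls=100, n_probes=200, seed=5)
    return generate_cohort(cfg, [])


def base_spec(cohort, predictor="status", extra=()):
    cells = tuple(c for c in cohort.sheet.columns if c.startswith("cell_"))[:-1]
    return ModelSpec(predictor, ("age", "sex", "batch") + cells + tuple(extra))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
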