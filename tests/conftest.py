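from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from thyrobmd import LinkSpec, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def linked_cohort() -> pd.DataFrame:
    """Small synthetic cohort with a nickel–fT3 dose-response link."""
    config = SyntheticConfig(
        n_male=60,
        n_female=60,
        links=(LinkSpec(endpoint="ft3", background=0.05, bmd=5.0),),
    )
    return generate_cohort(config, seed=11)


@pytest.fixture()
def cohort_csv(tmp_path, linked_cohort):
    path = tmp_path / "cohort.csv"
    linked_cohort.to_csv(path, index=False)
    return path


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
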