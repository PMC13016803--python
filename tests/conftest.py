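import dataclasses

import pytest

from score2modes.engine import ChartGrid, default_model_spec
from score2modes.simulate import preset_populations, simulate_cohort


@pytest.fixture(scope="session")
def spec():
    return default_model_spec()


@pytest.fixture(scope="session")
def grid():
    return ChartGrid()


@pytest.fixture(scope="session")
def low_cohort_small(spec):
    """A 2000-person low-risk-region cohort, fixed seed."""
    params = dataclasses.replace(preset_populations()["low_region"], n=2000)
    return simulate_cohort(params, seed=42, spec=spec)


@pytest.fixture(scope="session")
def low_cohort_large(spec):
    """The default low-risk-region preset (n = 100 000), fixed seed."""
    return simulate_cohort(preset_populations()["low_region"], seed=7, spec=spec)
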