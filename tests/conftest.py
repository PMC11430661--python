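import numpy as np
import pytest

from flipnorms import (
    GeneratorConfig,
    generate_uniform_cohort,
    load_design,
    load_reference_table,
)


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def target_design():
    return load_design("target")


@pytest.fixture(scope="session")
def actual_design():
    return load_design("actual")


@pytest.fixture(scope="session")
def mega_cohort(reference_table):
    """Large continuous-score cohort for recovery/validation tests.

    Shared session-wide: generating and refitting it dominates suite
    runtime, so every consumer reuses the same draw (seed fixed).
    """
    return generate_uniform_cohort(
        20_000, reference_table, GeneratorConfig(seed=20240828),
        age_range=(3.0, 72.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
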