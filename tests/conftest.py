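import numpy as np
import pytest

from hbchoice import (
    assign_blocks,
    build_default_schema,
    generate_design,
    simulate_choices,
    simulate_respondents,
    published_importance_calibration,
)


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def plan(schema):
    return generate_design(schema, 8, 8, seed=1)


@pytest.fixture(scope="session")
def calibration(schema):
    return published_importance_calibration(schema)


@pytest.fixture(scope="session")
def panel(schema, plan, calibration):
    """Full synthetic survey panel: profiles, assignment, choices."""
    profiles = simulate_respondents(calibration, seed=2)
    assignment = assign_blocks(plan, profiles.to_frame(), seed=3)
    choices = simulate_choices(profiles, plan, assignment, seed=4)
    return profiles, assignment, choices
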