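import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import numcomp as nc

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study1_spec():
    return nc.build_study1_design(repeats=20, seed=1)


@pytest.fixture(scope="session")
def study2_value_set():
    return nc.ValueSet(nc.STUDY2_VALUES)


@pytest.fixture(scope="session")
def everyday_table(study2_value_set):
    return nc.build_frequency_table("everyday", study2_value_set)


@pytest.fixture(scope="session")
def everyday_spec(everyday_table):
    return nc.build_trial_templates(everyday_table, repeats=2, seed=1)


@pytest.fixture(scope="session")
def uniform_spec(study2_value_set):
    table = nc.build_frequency_table("uniform", study2_value_set)
    return nc.build_trial_templates(table, repeats=22, seed=1)


@pytest.fixture(scope="session")
def reversed_spec(study2_value_set):
    table = nc.build_frequency_table("reversed_everyday", study2_value_set)
    return nc.build_trial_templates(table, repeats=2, seed=1)


@pytest.fixture(scope="session")
def small_ans_trials(everyday_spec):
    """Uncoupled diffusion cohort on the everyday design (6 participants)."""
    return nc.simulate_ans_cohort(
        everyday_spec, nc.CohortSpec(n_participants=6, seed=11)
    )


@pytest.fixture(scope="session")
def small_dss_trials(study1_spec):
    """Statistics-driven cohort on the omitted-range design (6 participants)."""
    return nc.simulate_dss_cohort(
        study1_spec, nc.CohortSpec(n_participants=6, seed=7), basis="value"
    )
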