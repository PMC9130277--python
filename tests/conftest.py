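"""Shared fixtures: one synthetic world and its fitted model suite.

The expensive artifacts (an 800-mother paper-like dataset and the
twelve-model GLMM suite fitted to it) are built once per session and shared;
tests that need other worlds (null, strong-P, heterogeneity) build smaller
ones locally.
"""

import numpy as np
import pandas as pd
import pytest

import twinfert as tf

WORLD_SEED = 3
SIM_SEED = 4
N_MOTHERS = 800


@pytest.fixture(scope="session")
def truth():
    return tf.make_truth("paper_like")


@pytest.fixture(scope="session")
def world(truth):
    """(models, init_mothers, effects) for the paper-like truth."""
    return tf.truth_models(truth, N_MOTHERS, seed=WORLD_SEED)


@pytest.fixture(scope="session")
def dataset(world):
    models, init, _ = world
    return tf.simulate_dataset(models, init, seed=SIM_SEED)


@pytest.fixture(scope="session")
def suite(dataset):
    return tf.fit_model_suite(dataset.births, dataset.mothers,
                              poly_orders={4: 2, 5: 2, 6: 2})


@pytest.fixture(scope="session")
def init_mothers(dataset):
    return dataset.mothers[["maternal_id", "population_id", "AFB_months"]]


@pytest.fixture()
def toy_children():
    """Six children / three mothers covering singleton, twin and edge cases."""
    return pd.DataFrame({
        "population_id": ["A"] * 6,
        "maternal_id": ["m1", "m1", "m2", "m2", "m3", "m3"],
        "maternal_birth_year": [1760] * 6,
        "maternal_birth_month": [6] * 6,
        "child_birth_year": [1800, 1800, 1800, 1800, 1800, 1802],
        "child_birth_month": [5, 5, 5, 5, 5, 1],
        "child_birth_day": [3, 4, 3, 5, 10, 20],
        "followup_to_45": [True] * 6,
    })
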