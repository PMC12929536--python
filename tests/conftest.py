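"""Shared fixtures: a small synthetic corpus and the models fitted from it.

Everything is generated programmatically with fixed seeds; session scope
keeps the k-means fit and null calibration to one run per test session.
"""

import numpy as np
import pytest

from thermomimic.etfr import build_substitution_matrix, calibrate_null
from thermomimic.profiles import (STATES, assign_environments,
                                  fit_environment_model, predict_profile)
from thermomimic.synthetic import generate_propensity_table, generate_sequences


@pytest.fixture(scope="session")
def propensity_table():
    return generate_propensity_table(seed=11, window=7)


@pytest.fixture(scope="session")
def corpus_sequences():
    return generate_sequences(40, (60, 120), seed=7, id_prefix="corp")


@pytest.fixture(scope="session")
def corpus_profiles(corpus_sequences, propensity_table):
    return [predict_profile(s, propensity_table) for s in corpus_sequences]


@pytest.fixture(scope="session")
def env_model(corpus_profiles):
    return fit_environment_model(corpus_profiles, seed=3)


@pytest.fixture(scope="session")
def encoded_corpus(corpus_profiles, env_model):
    return [assign_environments(p, env_model) for p in corpus_profiles]


@pytest.fixture(scope="session")
def matrices(encoded_corpus):
    return {state: build_substitution_matrix(encoded_corpus, state)
            for state in STATES}


@pytest.fixture(scope="session")
def uniform_composition():
    return np.full(20, 0.05)


@pytest.fixture(scope="session")
def nulls(matrices, uniform_composition):
    # fixed query length, growing target length: the ln(m*n) location term
    # then tracks the register count, as in E-value practice
    grid = [(60, 300), (60, 500), (60, 800)]
    return {state: calibrate_null(matrices[state], uniform_composition, grid,
                                  n_shuffles=300, seed=19)
            for state in STATES}
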