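"""Shared fixtures: the fixed-seed phantom cohort and trained cascade stages.

The heavy fixtures are session-scoped so the full 8-phantom experiment (the
study condition: 64×64 grids, noise_sd 0.4, bias_amplitude 0.2, 6 train /
2 test) is fitted once and reused by every test that inspects it.
"""

import numpy as np
import pytest

from cascadeseg import (CascadeConfig, PhantomConfig, binarize_whole_tumor,
                        fit_pipeline, generate_cohort, run_case)
from cascadeseg.metrics import case_metrics

COHORT_SEED = 0
N_TRAIN = 6


@pytest.fixture(scope="session")
def phantom_cohort():
    """8 noisy biased 64×64 phantoms, fixed seed."""
    return generate_cohort(8, PhantomConfig(), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cascade_config():
    return CascadeConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def trained_models(phantom_cohort, cascade_config):
    """CNN + SVM ensemble fitted on the 6 training phantoms."""
    return fit_pipeline(phantom_cohort[:N_TRAIN], cascade_config)


@pytest.fixture(scope="session")
def test_cases(phantom_cohort):
    return phantom_cohort[N_TRAIN:]


@pytest.fixture(scope="session")
def cascade_results(trained_models, test_cases, cascade_config):
    """Full cascade output on the 2 held-out phantoms."""
    cnn_model, svm_model = trained_models
    return [run_case(cnn_model, svm_model, case, cascade_config) for case in test_cases]


@pytest.fixture(scope="session")
def heldout_metrics(cascade_results, test_cases):
    """Per-case (preseg_row, final_row) metric tuples on the held-out phantoms."""
    rows = []
    for result, case in zip(cascade_results, test_cases):
        truth = binarize_whole_tumor(case.truth)
        rows.append((case_metrics(result.presegmentation, truth, case.case_id),
                     case_metrics(result.final, truth, case.case_id)))
    return rows
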