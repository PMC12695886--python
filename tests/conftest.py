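import numpy as np
import pandas as pd
import pytest

from csf_nathist.adjust import adjust_pipeline
from csf_nathist.preprocess import log_transform
from csf_nathist.synthetic import (CohortConfig, generate_cohort,
                                   generate_reference_list)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_hc_patients=24, n_hc_longitudinal=10,
        n_ms_patients={"RRMS": 30, "SPMS": 25, "PPMS": 25},
        n_somamer=120, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Matrix, sample table, clinical table and ground truth (shared)."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def logged(small_cohort):
    matrix, *_ = small_cohort
    return log_transform(matrix)


@pytest.fixture(scope="session")
def adjusted(small_cohort, logged):
    _, samples, _, truth = small_cohort
    ref = generate_reference_list(truth, noise=0.2)
    return adjust_pipeline(logged, samples, ref)


@pytest.fixture(scope="session")
def hc_ids(small_cohort):
    _, samples, _, _ = small_cohort
    return list(samples.index[samples["diagnosis"] == "HC"])


@pytest.fixture(scope="session")
def untreated_ms_ids(small_cohort):
    _, samples, _, _ = small_cohort
    return list(samples.index[(samples["diagnosis"] != "HC")
                              & (~samples["treated"])])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
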