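from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import segscan as sg

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(values, gene_ids=None, sample_ids=None) -> sg.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
    return sg.ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))


@pytest.fixture
def small_matrix() -> sg.ExpressionMatrix:
    return make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])


@pytest.fixture(scope="session")
def default_study():
    """Full-size default synthetic study (outliers and zeros at their
    default low rates), shared across tests."""
    design = sg.SyntheticDesign(seed=1)
    return design, *sg.generate(design)


@pytest.fixture(scope="session")
def clean_study():
    """Default-size study with no injected outliers and no zeros."""
    design = sg.SyntheticDesign(outlier_rate=0.0, zero_rate=0.0, seed=1)
    return design, *sg.generate(design)


@pytest.fixture(scope="session")
def small_study():
    """Small, fast study for pipeline-level tests."""
    design = sg.SyntheticDesign(
        n_stable_genes=25,
        n_variable_genes=150,
        n_unannotated=20,
        n_redundant_extra=20,
        n_organs=4,
        n_ages=2,
        seed=7,
    )
    return design, *sg.generate(design)


@pytest.fixture(scope="session")
def preprocessed_default(default_study):
    _, matrix, _, genes, truth = default_study
    clean, report = sg.preprocess_pipeline(matrix, genes)
    return clean, report, truth
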