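"""Shared fixtures: tiny hand-built tables and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tmegraph import (
    CellTable,
    PhenotypeVocabulary,
    RunConfig,
    SimConfig,
    simulate_cohort,
    worked_example_cohort,
)


@pytest.fixture(scope="session")
def vocab2() -> PhenotypeVocabulary:
    return PhenotypeVocabulary(
        names=("tumor_ck", "t_cell"),
        category_of={"tumor_ck": "tumor", "t_cell": "immune"},
    )


@pytest.fixture(scope="session")
def vocab3() -> PhenotypeVocabulary:
    return PhenotypeVocabulary(
        names=("tumor_ck", "t_cell", "fibroblast"),
        category_of={"tumor_ck": "tumor", "t_cell": "immune", "fibroblast": "stromal"},
    )


def make_cells(rows, vocab, expression=None) -> CellTable:
    df = pd.DataFrame(rows, columns=["patient_id", "image_id", "x", "y", "phenotype"])
    return CellTable(df, vocab, expression)


@pytest.fixture()
def two_cell_patient(vocab2) -> CellTable:
    """Two cells 10 µm apart: edge weight e^-1 at alpha = 0.01."""
    return make_cells(
        [("p1", "i1", 0.0, 0.0, "tumor_ck"), ("p1", "i1", 10.0, 0.0, "t_cell")], vocab2
    )


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 12-patient simulated cohort for pipeline-level tests."""
    return simulate_cohort(SimConfig(n_patients=12, seed=7))


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig(min_cells=1, k_pheno=30, k_star=5, random_seed=7)
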