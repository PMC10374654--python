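import numpy as np
import pandas as pd
import pytest

from met53.cohort_io import ClinicalTable, ExpressionMatrix, GeneSet, MutationTable
from met53.synthetic_data import CohortSimConfig, simulate_cohort


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples with easy hand-checkable numbers."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[0.0, 2.0, 4.0, 6.0],
             [1.0, 1.0, 1.0, 1.0],   # constant: dropped by standardization
             [5.0, 3.0, 1.0, 7.0]],
            index=["G1", "G2", "G3"],
            columns=["S1", "S2", "S3", "S4"],
        )
    )


@pytest.fixture
def small_clinical() -> ClinicalTable:
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4"],
                "sample_type": ["ST", "ST", "HCC", "HCC"],
                "os_time": [10.0, 12.0, 24.5, 8.0],
                "os_event": [0, 0, 1, 0],
            }
        )
    )


@pytest.fixture
def toy_gene_set() -> GeneSet:
    return GeneSet("TOY", ("G1", "G3"))


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition simulated cohort shared across tests."""
    return simulate_cohort(CohortSimConfig(seed=20230727))
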