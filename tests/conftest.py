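import numpy as np
import pandas as pd
import pytest

from gliomanet import (
    ExpressionMatrix,
    LogRatioMatrix,
    SimConfig,
    simulate_cohort,
    to_log_ratios,
)

SMALL_SIM = SimConfig(
    n_genes=500,
    n_tfs=8,
    n_targets=60,
    samples_per_grade={"PA1": 12, "AS2": 12, "AS3": 12, "GBM4": 12},
    n_reference=12,
    de_counts={"PA1": 10, "AS2": 20, "AS3": 30, "GBM4": 60},
    network_density=0.05,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale synthetic cohort shared across fast tests."""
    return simulate_cohort(SMALL_SIM)


@pytest.fixture(scope="session")
def small_lr(small_cohort):
    expr, _ = small_cohort
    return to_log_ratios(expr)


@pytest.fixture()
def tiny_expression():
    """5 genes x 4 samples (2 normals, 2 tumors) with hand-set values."""
    genes = [f"g{i}" for i in range(5)]
    samples = ["N1", "N2", "T1", "T2"]
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.normal(7, 1, size=(5, 4)), index=genes, columns=samples
    )
    metadata = pd.DataFrame(
        {"grade": ["NORMAL", "NORMAL", "PA1", "GBM4"], "cohort": "toy"},
        index=samples,
    )
    return ExpressionMatrix(values=values, metadata=metadata)


def make_lr(values: pd.DataFrame, grades: list[str]) -> LogRatioMatrix:
    """Helper: wrap a genes x samples frame as a log-ratio matrix."""
    metadata = pd.DataFrame({"grade": grades}, index=values.columns)
    return LogRatioMatrix(values=values, metadata=metadata)
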