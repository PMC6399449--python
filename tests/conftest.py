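import numpy as np
import pandas as pd
import pytest

from perioscope import periodicity, preprocess, synthetic
from perioscope.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def time_grid():
    return synthetic.default_time_grid()


@pytest.fixture(scope="session")
def wt_preset():
    return synthetic.make_strain_preset("WT")


@pytest.fixture(scope="session")
def calibration():
    """Score/BIC cutoffs calibrated on the 200-gene synthetic reference set."""
    ref = synthetic.simulate_reference_set(200, seed=1)
    fits = periodicity.fit_expression_matrix(
        preprocess.preprocess_counts(ref, min_total=0.0)
    )
    return periodicity.calibrate_cutoffs(fits, fnr=0.2)


def counts_matrix(values, times=None, gene_ids=None):
    """Small raw-count ExpressionMatrix from a nested list."""
    values = np.asarray(values)
    times = list(times) if times is not None else [5 * i for i in range(values.shape[1])]
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=times), stage="raw_counts"
    )


@pytest.fixture
def toy_counts():
    return counts_matrix([[2, 10, 5], [3, 20, 10], [5, 30, 15]])
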