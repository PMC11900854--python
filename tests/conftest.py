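import numpy as np
import pandas as pd
import pytest

from plumage import io as pio
from plumage.simulate import CohortDesign, simulate_cohort


@pytest.fixture(scope="session")
def signal_cohort():
    """One seeded cohort with the default design (13/18 birds, 800 proteins,
    30% affected at +/-1 log2). Shared across tests; treat as read-only."""
    return simulate_cohort(CohortDesign(seed=1))


@pytest.fixture(scope="session")
def signal_differential(signal_cohort):
    from plumage import differential as da

    matrix, metadata, _annotations, _truth = signal_cohort
    groups = pio.group_samples(metadata)
    return da.mann_whitney_differential(matrix, groups)


@pytest.fixture()
def tiny_matrix():
    """3 proteins x 4 samples with one missing cell."""
    values = pd.DataFrame(
        [[10.0, 12.0, 9.0, 11.0],
         [5.0, np.nan, 6.0, 7.0],
         [100.0, 90.0, 110.0, 95.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return pio.IntensityMatrix(values)
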