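import numpy as np
import pandas as pd
import pytest

import flexemg as fx
from flexemg.pipeline import rat_feature_table


@pytest.fixture(scope="session")
def full_rat_features():
    """Feature table + evoked parameters of the full default rat cohort.

    6 + 6 subjects x 150 acquisitions with pre-injury baselines; shared by
    the accounting and cross-validation acceptance tests.
    """
    cohort = fx.generate_rat_cohort(seed=20260101)
    table, evoked = rat_feature_table(cohort)
    return cohort, table, evoked


@pytest.fixture(scope="session")
def small_rat_table():
    """A scaled-down rat cohort feature table for fast classifier tests."""
    config = fx.default_rat_config(
        groups=(("immobilization", 3), ("nerve_injury", 3)),
        acquisitions_per_subject=25,
        baseline_epochs=4,
    )
    cohort = fx.generate_rat_cohort(config, seed=99)
    table, _ = rat_feature_table(cohort, with_evoked=False)
    return table


@pytest.fixture()
def separable_table():
    """Two well-separated Gaussian clusters (4 SD per feature): separable."""
    rng = np.random.default_rng(42)
    n = 60
    rows = []
    for label, center in ((0, 0.0), (1, 4.0)):
        X = rng.normal(center, 1.0, size=(n, 4))
        for x in X:
            rows.append(dict(rms=x[0], iemg=x[1], mdf=x[2], mpf=x[3], label=label))
    return pd.DataFrame(rows)
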