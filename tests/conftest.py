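import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from diffpairct import (CtMatrix, aggregate_replicates, compute_diffpairs,
                        filter_globally_undetected, paper_shaped_cohort,
                        screen_all)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_ct(values, censored=None, samples=None, mirnas=None, cycle_limit=40.0):
    """Small CtMatrix builder for tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    mirnas = mirnas or [f"miR-{j}" for j in range(m)]
    if censored is None:
        censored = np.zeros_like(values, dtype=bool)
    return CtMatrix(pd.DataFrame(values, index=samples, columns=mirnas),
                    pd.DataFrame(np.asarray(censored, bool), index=samples,
                                 columns=mirnas),
                    cycle_limit)


def make_meta(samples, groups, splits):
    return pd.DataFrame({"sample_id": samples, "group": groups, "split": splits})


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper-geometry cohort (181 miRNAs, 30/20 train, 55/75 test),
    aggregated and filtered, shared across tests for speed."""
    mats, meta, truth = paper_shaped_cohort(seed=20120301)
    m = filter_globally_undetected(aggregate_replicates(mats))
    return m, meta, truth


@pytest.fixture(scope="session")
def paper_screen(paper_cohort):
    m, meta, truth = paper_cohort
    dp = compute_diffpairs(m)
    records = screen_all(dp, meta)
    return dp, meta, truth, records
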