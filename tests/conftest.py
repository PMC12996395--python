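import numpy as np
import pandas as pd
import pytest

from endosafe import synthdata
from endosafe.io import BetaMatrix, SampleSheet


@pytest.fixture(scope="session")
def profiles_l1():
    return synthdata.make_reference_profiles(150, level=1, seed=3)


@pytest.fixture(scope="session")
def profiles_l2():
    return synthdata.make_reference_profiles(240, level=2, seed=4)


@pytest.fixture(scope="session")
def small_cohort(profiles_l1):
    """60-sample cohort with moderate signal, shared across tests."""
    cfg = synthdata.CohortSimConfig(n_cases=30, n_controls=30, n_cpgs=1200,
                                    n_differential=50, n_age_cpgs=20, seed=1)
    return synthdata.simulate_cohort(cfg, profiles_l1)


@pytest.fixture
def toy_sheet():
    return SampleSheet(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(4)],
        "subject_id": [f"p{i}" for i in range(4)],
        "group": ["control", "control", "case", "case"],
        "timepoint": "NA",
        "age": [40.0, 40.0, 40.0, 40.0],
    }))


def mixture_betas(profiles, pi, sample_ids=None):
    """Noiseless convex mixtures of reference columns (markers x samples)."""
    pi = np.atleast_2d(pi)
    vals = profiles.values.to_numpy() @ pi.T
    cols = sample_ids or [f"m{i}" for i in range(pi.shape[0])]
    return BetaMatrix(pd.DataFrame(vals, index=profiles.marker_ids,
                                   columns=cols))
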