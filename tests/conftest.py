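import numpy as np
import pytest
from hypothesis import settings

import fctopo

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from fctopo.fc import ROITimeSeries, compute_fc


@pytest.fixture(scope="session")
def small_config():
    return fctopo.SimConfig(
        n_men=10,
        n_women=12,
        n_regions=12,
        n_timepoints=80,
        sex_effect_scale=1.0,
        reversal_regions=(),
        seed=12345,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort = fctopo.generate_cohort(small_config)
    ts = fctopo.generate_cohort_timeseries(cohort, small_config)
    return cohort, ts


@pytest.fixture(scope="session")
def small_fc_stack(small_cohort):
    cohort, ts = small_cohort
    sids = list(ts)
    fcs = [compute_fc(ROITimeSeries(ts[s], cohort.region_labels, s)) for s in sids]
    sess = cohort.sessions.set_index("session_id").loc[sids].reset_index()
    return fcs, sess


def random_weighted_graph(rng, n, density=0.5):
    """Symmetric nonnegative weight matrix with zero diagonal."""
    w = rng.random((n, n))
    w = np.triu(w, k=1)
    mask = rng.random((n, n)) < density
    w = np.where(np.triu(mask, k=1), w, 0.0)
    w = w + w.T
    return w
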