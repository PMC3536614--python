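import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import sorn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    return sorn.NetworkParams(n_exc=10, n_inh=2, seed=42)


@pytest.fixture(scope="session")
def default_record_10k():
    """One default 10,000-step run shared by the statistics tests.

    Snapshots every 200 steps and the STDP delta log are recorded so the
    fluctuation and rich-get-richer analyses can run on the same data.
    """
    params = sorn.NetworkParams(seed=1)
    return sorn.run(params, 10_000,
                    record=sorn.RecordSpec(snapshot_every=200,
                                           stdp_deltas=True))
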