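import numpy as np
import pytest

from wmtier.synth import default_cohort_spec, gen_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with the default planted group patterns.

    Reduced channel count, sampling rate and trial count keep the suite
    fast; the coupling structure is the default qualitative group pattern.
    """
    spec = default_cohort_spec(
        group_sizes={"HC": 7, "MCI": 6, "AD": 6},
        n_channels=17, fs=250.0, rest_duration=44.0,
        n_trials=5, n_sessions=1, seed=11,
    )
    return gen_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
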