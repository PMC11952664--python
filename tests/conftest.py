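import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import salnet

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_atlas():
    return salnet.make_parcel_atlas(V=120, K=6, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def noiseless_session(small_atlas):
    """A noiseless BOLD run whose truth maps are the atlas indicator blocks."""
    mean, var = salnet.default_prior_truth(small_atlas, in_between_sd=0.0, out_between_sd=0.0)
    subject = salnet.simulate_subject_engagement(small_atlas, mean, var, 1, seed=5)[0]
    bold, motion = salnet.simulate_bold_session(
        subject, small_atlas, T=80, TR=0.5, seed=7
    )
    return subject, bold, motion


def make_engagement(rng, V=40, K=3, scale=1.0, var=0.5):
    values = rng.normal(0, scale, (V, K))
    sampling = np.full((V, K), var)
    return salnet.EngagementMap(values=values, sampling_var=sampling)
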