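import numpy as np
import pytest

from embryoscreen import CohortConfig, MovieSpec, generate_cohort, render_zygote_movie


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_mc=30, n_lb=90, seed=7))


@pytest.fixture(scope="session")
def linear_movie():
    spec = MovieSpec(trajectory_kind="linear", speed=0.8, noise_sd=0.0,
                     n_frames=12, seed=5)
    stack, gt = render_zygote_movie(spec)
    return spec, stack, gt


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh, deterministic stream
    return np.random.default_rng(12345)
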