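import numpy as np
import pytest

from epac import ActorParams, EPConfig


def random_actor(n_in, n_hid, n_out, seed, tie_feedback=True, scale=None):
    """Small random actor instance for dynamics tests."""
    rng = np.random.default_rng(seed)
    p = ActorParams.initialize(n_in, n_hid, n_out, rng,
                               tie_feedback=tie_feedback)
    if scale is not None:
        p.w_in_hid *= scale
        p.w_hid_out *= scale
        p.retie()
        if not tie_feedback:
            p.w_out_hid *= scale
    return p


@pytest.fixture
def cfg():
    return EPConfig(h=0.5, beta=0.02, gamma_fb=0.5, iters_free=150,
                    iters_clamped=25)


@pytest.fixture
def small_actor():
    return random_actor(4, 8, 2, seed=123)
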