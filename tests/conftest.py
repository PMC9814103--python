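import numpy as np
import pytest

from flowbo import (
    AcquisitionConfig,
    CategoricalParam,
    Condition,
    ContinuousParam,
    ParameterSpace,
)


@pytest.fixture
def mixer_param():
    return CategoricalParam("mixer", ["comet_x", "beta_type", "t_shaped"])


@pytest.fixture
def small_space(mixer_param):
    """Temperature + equivalents + mixer: enough structure for encoding tests."""
    return ParameterSpace(
        [
            ContinuousParam("temp_c", 20, 60, units="°C", precision=5),
            ContinuousParam("equiv", 1.0, 3.0, units="equiv", precision=0.1),
            mixer_param,
        ]
    )


@pytest.fixture
def line_space():
    """A 1-D space whose lab grid has exactly 12 points (0, 1, ..., 11)."""
    return ParameterSpace([ContinuousParam("x", 0.0, 11.0, precision=1.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Small candidate pool for tests that only need plumbing, not precision."""
    return AcquisitionConfig(n_candidates=256, n_refine=3, seed=7)


def make_line_history(space, xs, ys):
    conds = [Condition({"x": float(v)}) for v in xs]
    return conds, [float(y) for y in ys]
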