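import numpy as np
import pytest

from amylogel.curves import ScatteringCurve
from amylogel.models import Eq1Params, Eq2Params, eq1_intensity, eq2_intensity

#: post-gelation parameter sets used as canonical truths throughout the suite
POST_GEL_EQ1 = Eq1Params(scale_rod=1.0, rc=0.6, i0_ex=1.0, xi=17.0, x=0.85)
POST_GEL_EQ2 = Eq2Params(scale_rod=1.0, rc=0.6, i0_db=1.0, a=10.0)


@pytest.fixture
def q_window_grid():
    """80-point grid spanning the standard fit window."""
    return np.linspace(0.1, 3.5, 80)


@pytest.fixture
def eq1_curve(q_window_grid):
    """Noise-free post-gelation rod + stretched-exponential curve."""
    return ScatteringCurve(q_window_grid, eq1_intensity(q_window_grid, POST_GEL_EQ1))


@pytest.fixture
def eq2_curve(q_window_grid):
    """Noise-free post-gelation rod + Debye-Bueche curve."""
    return ScatteringCurve(q_window_grid, eq2_intensity(q_window_grid, POST_GEL_EQ2))


def perturb(params, rel, seed):
    """Multiply every parameter by (1 +/- rel), signs drawn from ``seed``."""
    rng = np.random.default_rng(seed)
    kw = {
        k: v * (1.0 + rel * rng.choice([-1.0, 1.0]))
        for k, v in params.to_dict().items()
        if v != 0
    }
    return params.replace(**kw)
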