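import hypothesis
import numpy as np
import pytest
from hypothesis import strategies as hst

from sittr import ModelParams, PRESETS, State

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def fig7():
    return PRESETS["fig7"]


@pytest.fixture
def fig8():
    return PRESETS["fig8"]


@pytest.fixture
def fig9():
    return PRESETS["fig9"]


def _finite_float(lo, hi):
    return hst.floats(min_value=lo, max_value=hi, allow_nan=False,
                      allow_infinity=False)


#: Random valid parameter sets: rates in (0, 3], fractions in [0, 1].
params_strategy = hst.builds(
    ModelParams,
    alpha=_finite_float(1e-3, 3.0),
    gamma=_finite_float(0.0, 3.0),
    beta=_finite_float(0.0, 3.0),
    lam=_finite_float(0.0, 3.0),
    b=_finite_float(0.0, 1.0),
    eta=_finite_float(0.0, 3.0),
    zeta=_finite_float(0.0, 3.0),
    mu1=_finite_float(0.0, 3.0),
    mu2=_finite_float(0.0, 3.0),
    u1=_finite_float(0.0, 1.0),
    u2=_finite_float(0.0, 1.0),
)


@hst.composite
def consistent_states(draw, lo=0.0, hi=1e3):
    """States satisfying N = S + I + T1 + T2 + R exactly (in floats)."""
    s, i, t1, t2, r = (draw(_finite_float(lo, hi)) for _ in range(5))
    return State(S=s, I=i, T1=t1, T2=t2, N=s + i + t1 + t2 + r, R=r)


arbitrary_states = hst.builds(
    State,
    S=_finite_float(-1e3, 1e3), I=_finite_float(-1e3, 1e3),
    T1=_finite_float(-1e3, 1e3), T2=_finite_float(-1e3, 1e3),
    N=_finite_float(-1e3, 1e3), R=_finite_float(-1e3, 1e3),
)


def finite_difference_jacobian(f, y, step=1e-6):
    """Central-difference Jacobian of a vector map f at y, with a
    per-coordinate step scaled by max(1, |y_k|)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    f0 = np.asarray(f(y))
    J = np.empty((f0.size, n))
    for k in range(n):
        hk = step * max(1.0, abs(y[k]))
        e = np.zeros(n)
        e[k] = hk
        J[:, k] = (np.asarray(f(y + e)) - np.asarray(f(y - e))) / (2.0 * hk)
    return J


def random_params(rng):
    """Draw one valid ModelParams from a numpy Generator (for loops that
    need many cheap samples without hypothesis overhead)."""
    return ModelParams(
        alpha=rng.uniform(1e-3, 2.0), gamma=rng.uniform(0.0, 2.0),
        beta=rng.uniform(0.0, 2.0), lam=rng.uniform(0.0, 2.0),
        b=rng.uniform(0.0, 1.0), eta=rng.uniform(0.0, 2.0),
        zeta=rng.uniform(0.0, 2.0), mu1=rng.uniform(0.0, 2.0),
        mu2=rng.uniform(0.0, 2.0), u1=rng.uniform(0.0, 1.0),
        u2=rng.uniform(0.0, 1.0),
    )


def random_consistent_state(rng, hi=1e3):
    s, i, t1, t2, r = rng.uniform(0.0, hi, size=5)
    return State(S=s, I=i, T1=t1, T2=t2, N=s + i + t1 + t2 + r, R=r)
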