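"""Core definitions of the SIT1T2R infertility-treatment model.

The model tracks five classes of women attending an infertility clinic
where polycystic ovary syndrome (PCOS) is the infertility factor —
susceptible newcomers ``S``, diagnosed patients ``I``, a drug-treatment
arm ``T1`` (clomiphene citrate + gonadotropin), an IVF arm ``T2`` and
recovered patients ``R`` — together with the total clinic population
``N``, which carries its own rate equation:

    S'  = γN − αS − βS(ηT1 + ζT2)
    I'  = −λI − αI + βS(ηT1 + ζT2)
    T1' = −μ1 T1 − αT1 + λIb
    T2' = −μ2 T2 − αT2 + (1−u1)μ1 T1 + (1−b)λI
    R'  = −αR + u1 μ1 T1 + u2 μ2 T2
    N'  = γN − (1−u2)μ2 T2 − αN

All eleven parameters are nonnegative rates per unit time except the
dimensionless fractions ``b`` (share of treatment assignments going to
the drug arm), ``u1`` and ``u2`` (cure fractions of the two arms), which
live in [0, 1].  The bilinear term βS(ηT1 + ζT2) models relapse —
miscarriage or ovarian hyperstimulation returning treated women to the
patient pool.

The system is integrated as written, all six equations: ``N`` is
redundant given the bookkeeping identity N = S + I + T1 + T2 + R, and
keeping it turns the redundancy into a free accuracy diagnostic
(:func:`conservation_residual`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "PARAM_NAMES",
    "ModelParams",
    "State",
    "rhs",
    "conservation_residual",
    "divergence",
    "volume_form_divergence_printed",
    "N_CONSISTENCY_RTOL",
]

#: Fixed component order used everywhere: state vectors, Jacobian rows
#: and columns, trajectory CSV columns.
COMPARTMENTS = ("S", "I", "T1", "T2", "N", "R")

PARAM_NAMES = (
    "alpha", "gamma", "beta", "lam", "b", "eta", "zeta",
    "mu1", "mu2", "u1", "u2",
)

#: Relative tolerance for the N = S + I + T1 + T2 + R bookkeeping check.
#: The identity is exact analytically; the slack only absorbs float drift.
N_CONSISTENCY_RTOL = 1e-8

_FRACTIONS = frozenset({"b", "u1", "u2"})


@dataclass(frozen=True)
class ModelParams:
    """The eleven rates and fractions of the SIT1T2R system.

    Parameters
    ----------
    alpha : drop-out ("death") rate — leaving the clinic without result.
    gamma : arrival ("birth") rate of new infertile couples.
    beta  : relapse rate — return to treatment after miscarriage/OHSS.
    lam   : treatment-assignment rate of diagnosed patients (λ).
    b     : fraction of assignments going to the drug arm, in [0, 1].
    eta   : treatment speed of the drug arm (η).
    zeta  : treatment speed of the IVF arm (ζ).
    mu1   : recovery/progression rate of the drug arm (μ1).
    mu2   : recovery rate of the IVF arm (μ2).
    u1    : cure fraction of the drug arm, in [0, 1].
    u2    : cure fraction of the IVF arm, in [0, 1].
    """

    alpha: float
    gamma: float
    beta: float
    lam: float
    b: float
    eta: float
    zeta: float
    mu1: float
    mu2: float
    u1: float
    u2: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            object.__setattr__(self, f.name, v)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name!r} must be nonnegative, got {v!r}")
            if f.name in _FRACTIONS and v > 1:
                raise ValueError(
                    f"parameter {f.name!r} is a fraction and must lie in [0, 1], got {v!r}"
                )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass(frozen=True)
class State:
    """One point (S, I, T1, T2, N, R) in compartment space.

    Counts are treated as continuous; every component must be finite.
    Negative values are representable on purpose — the integrator reports
    rather than clips them.
    """

    S: float
    I: float
    T1: float
    T2: float
    N: float
    R: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            object.__setattr__(self, f.name, v)
            if not math.isfinite(v):
                raise ValueError(f"state component {f.name!r} must be finite, got {v!r}")

    @classmethod
    def from_array(cls, arr) -> "State":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (6,):
            raise ValueError(f"state array must have shape (6,), got {arr.shape}")
        return cls(*arr)

    def to_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.T1, self.T2, self.N, self.R], dtype=float)

    def consistency_residual(self) -> float:
        """Signed defect N − (S + I + T1 + T2 + R)."""
        return self.N - (self.S + self.I + self.T1 + self.T2 + self.R)

    def is_consistent(self, rtol: float = N_CONSISTENCY_RTOL) -> bool:
        """Whether the bookkeeping identity holds to ``rtol · max(1, N)``.

        The flag is verified here, never assumed elsewhere.
        """
        return abs(self.consistency_residual()) <= rtol * max(1.0, abs(self.N))

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPARTMENTS}


def _rhs_array(y: np.ndarray, p: ModelParams) -> np.ndarray:
    # Hot path shared with the RK4 integrator; y is a length-6 float array
    # in COMPARTMENTS order.  No clipping or projection of any kind.
    S, I, T1, T2, N, R = y
    relapse = p.beta * S * (p.eta * T1 + p.zeta * T2)
    return np.array(
        [
            p.gamma * N - p.alpha * S - relapse,
            -p.lam * I - p.alpha * I + relapse,
            -p.mu1 * T1 - p.alpha * T1 + p.lam * I * p.b,
            -p.mu2 * T2 - p.alpha * T2 + (1 - p.u1) * p.mu1 * T1 + (1 - p.b) * p.lam * I,
            p.gamma * N - (1 - p.u2) * p.mu2 * T2 - p.alpha * N,
            -p.alpha * R + p.u1 * p.mu1 * T1 + p.u2 * p.mu2 * T2,
        ]
    )


def _coerce_state(state) -> np.ndarray:
    if isinstance(state, State):
        return state.to_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (6,):
        raise ValueError(f"state must have 6 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"state has non-finite components: {arr!r}")
    return arr


def rhs(state, params: ModelParams) -> np.ndarray:
    """Vector field of the SIT1T2R system.

    Parameters
    ----------
    state : State or array-like of 6 finite reals in (S, I, T1, T2, N, R) order.
    params : ModelParams

    Returns
    -------
    numpy.ndarray of the six derivatives (S', I', T1', T2', N', R'), in
    the same component order.
    """
    return _rhs_array(_coerce_state(state), params)


def conservation_residual(state, params: ModelParams) -> float:
    """Defect of the bookkeeping identity under the flow.

    Returns (S' + I' + T1' + T2' + R') − N' evaluated through :func:`rhs`.
    Symbolic expansion cancels every λ, μ1, μ2 and γ term and leaves
    exactly α·(N − (S + I + T1 + T2 + R)), so the residual is zero (up to
    round-off) on every consistent state — and its own time derivative
    vanishes along trajectories started from one, which is what makes it
    a useful integrator diagnostic.
    """
    d = rhs(state, params)
    return float(d[0] + d[1] + d[2] + d[3] + d[5] - d[4])


def divergence(state, params: ModelParams) -> float:
    """Trace of the Jacobian of :func:`rhs` at ``state``.

    Term-by-term partial derivatives of the implemented field give

        −6α − β(ηT1 + ζT2) − λ − μ1 − μ2 + γ.

    Under γ < 6α + λ + μ1 + μ2 this is strictly negative on the
    nonnegative orthant, which by the standard Dulac/divergence argument
    rules out closed orbits there.  See also
    :func:`volume_form_divergence_printed` for the variant coefficient
    used in the original volume-form computation.
    """
    y = _coerce_state(state)
    p = params
    return float(
        -6.0 * p.alpha
        - p.beta * (p.eta * y[2] + p.zeta * y[3])
        - p.lam
        - p.mu1
        - p.mu2
        + p.gamma
    )


def volume_form_divergence_printed(state, params: ModelParams) -> float:
    """Coefficient −6α − β(ηT1 + ζT2) − μ1 − μ2 of the 6-form dω.

    This is the expression the original volume-form (Stokes) computation
    states for the divergence.  It differs from :func:`divergence` — the
    term-by-term trace of the implemented field — by omitting −λ and +γ.
    Both are exposed so the discrepancy is measurable; neither is
    silently "corrected" into the other.
    """
    y = _coerce_state(state)
    p = params
    return float(
        -6.0 * p.alpha - p.beta * (p.eta * y[2] + p.zeta * y[3]) - p.mu1 - p.mu2
    )
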