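"""Reproduction number and local stability of the disease-free equilibrium.

The basic reproduction number R0 — here, the expected number of relapses
("secondary returns to infertility") generated per treated case near the
disease-free population — comes from a next-generation decomposition of
the infected subsystem (I, T1, T2) linearized with S = N = S0: new
relapses enter through the "returning matrix" F and move between classes
through the "affected matrix" K, and R0 = trace(F·K⁻¹).

Local stability of the free equilibrium Q0 = (S0, 0, 0, 0, S0, 0) is
classified, under the hypothesis R0 < 1, by the sign of γ − α: the
linearization factors into the explicit eigenvalues −α (twice) and γ − α
plus a cubic whose Routh–Hurwitz minors Δ2, Δ3 are all positive when
R0 < 1, so the verdict rests entirely on γ − α.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass

import numpy as np

from .model import ModelParams, State, _coerce_state

__all__ = [
    "NextGenDecomposition",
    "StabilityReport",
    "Classification",
    "next_generation",
    "jacobian",
    "cubic_coefficients",
    "routh_hurwitz",
    "RouthHurwitz",
    "classify_free_equilibrium",
]


class Classification(enum.Enum):
    """Verdict for the free equilibrium, driven by sign(γ − α) when R0 < 1."""

    STABLE_NOT_ASYMPTOTIC = "stable_not_asymptotic"  # γ − α > 0
    UNSTABLE = "unstable"                            # γ − α = 0
    ASYMPTOTICALLY_STABLE = "asymptotically_stable"  # γ − α < 0
    NOT_APPLICABLE = "not_applicable"                # hypothesis R0 < 1 fails


@dataclass(frozen=True)
class NextGenDecomposition:
    """Next-generation matrices for the (I, T1, T2) subsystem at S = N = S0.

    ``K_inv`` holds the closed-form inverse; ``K_inv_numeric`` the dense
    numeric inverse, retained so their agreement is checkable.  ``H`` is
    the closed-form trace of F·K⁻¹ and equals ``R0``; ``G`` is the
    companion closed-form off-sum reported alongside it.
    """

    F: np.ndarray
    K: np.ndarray
    K_inv: np.ndarray
    K_inv_numeric: np.ndarray
    H: float
    G: float
    R0: float


def next_generation(params: ModelParams, S0: float) -> NextGenDecomposition:
    """Compute F, K, K⁻¹ (closed form and numeric), H, G and R0.

    F has the single nonzero first row (0, βηS0, βζS0) — relapse is the
    only route back into the patient class.  K is lower triangular with
    diagonal (α+λ, α+μ1, α+μ2), hence invertible for valid parameters.
    """
    if S0 < 0:
        raise ValueError(f"S0 must be nonnegative, got {S0!r}")
    p = params
    d1, d2, d3 = p.alpha + p.lam, p.alpha + p.mu1, p.alpha + p.mu2
    if d1 == 0 or d2 == 0 or d3 == 0:
        raise ZeroDivisionError(
            "affected matrix K is singular: one of α+λ, α+μ1, α+μ2 is zero "
            f"(α+λ={d1}, α+μ1={d2}, α+μ2={d3})"
        )

    F = np.array(
        [[0.0, p.beta * p.eta * S0, p.beta * p.zeta * S0],
         [0.0, 0.0, 0.0],
         [0.0, 0.0, 0.0]]
    )
    K = np.array(
        [[d1, 0.0, 0.0],
         [-p.b * p.lam, d2, 0.0],
         [-(1 - p.b) * p.lam, -(1 - p.u1) * p.mu1, d3]]
    )
    # Closed-form inverse of the lower-triangular K.
    K_inv = np.array(
        [
            [1.0 / d1, 0.0, 0.0],
            [p.b * p.lam / (d1 * d2), 1.0 / d2, 0.0],
            [
                (p.b * p.lam * (1 - p.u1) * p.mu1 + d2 * p.lam * (1 - p.b))
                / (d1 * d2 * d3),
                (1 - p.u1) * p.mu1 / (d3 * d2),
                1.0 / d3,
            ],
        ]
    )
    K_inv_numeric = np.linalg.inv(K)

    H = (
        p.beta * p.eta * S0 * p.b * p.lam / (d1 * d2)
        + p.beta * p.zeta * S0
        * (p.b * p.lam * p.mu1 * (1 - p.u1) + d2 * p.lam * (1 - p.b))
        / (d1 * d2 * d3)
    )
    G = (
        p.beta * p.eta * S0 / d2
        + p.beta * p.zeta * S0 * (1 - p.u1) * p.mu1 / (d2 * d3)
    )
    return NextGenDecomposition(F=F, K=K, K_inv=K_inv, K_inv_numeric=K_inv_numeric,
                                H=float(H), G=float(G), R0=float(H))


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic 6×6 Jacobian of the vector field.

    Row and column order is fixed as (S, I, T1, T2, N, R).  The only
    state dependence enters through the bilinear relapse term, so the
    matrix is affine in the state.
    """
    S, I, T1, T2, N, R = _coerce_state(state)
    p = params
    force = p.beta * (p.eta * T1 + p.zeta * T2)  # ∂(relapse)/∂S
    J = np.zeros((6, 6))
    # S' = γN − αS − βS(ηT1 + ζT2)
    J[0, 0] = -p.alpha - force
    J[0, 2] = -p.beta * p.eta * S
    J[0, 3] = -p.beta * p.zeta * S
    J[0, 4] = p.gamma
    # I' = −(λ+α)I + βS(ηT1 + ζT2)
    J[1, 0] = force
    J[1, 1] = -(p.lam + p.alpha)
    J[1, 2] = p.beta * p.eta * S
    J[1, 3] = p.beta * p.zeta * S
    # T1' = λbI − (μ1+α)T1
    J[2, 1] = p.lam * p.b
    J[2, 2] = -(p.mu1 + p.alpha)
    # T2' = (1−b)λI + (1−u1)μ1T1 − (μ2+α)T2
    J[3, 1] = (1 - p.b) * p.lam
    J[3, 2] = (1 - p.u1) * p.mu1
    J[3, 3] = -(p.mu2 + p.alpha)
    # N' = (γ−α)N − (1−u2)μ2T2
    J[4, 3] = -(1 - p.u2) * p.mu2
    J[4, 4] = p.gamma - p.alpha
    # R' = u1μ1T1 + u2μ2T2 − αR
    J[5, 2] = p.u1 * p.mu1
    J[5, 3] = p.u2 * p.mu2
    J[5, 5] = -p.alpha
    return J


def cubic_coefficients(params: ModelParams, S0: float) -> tuple[float, float, float, float]:
    """Coefficients (a0, a1, a2, a3) of the cubic eigenvalue factor at Q0.

    These are the closed forms of the characteristic polynomial of the
    inner (I, T1, T2) block of the Q0 Jacobian:

        a0 = 1
        a1 = 3α + λ + μ1 + μ2
        a2 = −bλβηS0 + (α+λ)(α+μ1) + (α+μ2)(λ+α) + (α+μ1)(α+μ2) − βζS0(1−b)λ
        a3 = −bλβηS0(α+μ2) − bλβS0ζμ1(1−u1) + (α+μ1)(α+μ2)(α+λ) − (α+μ1)βζS0(1−b)λ
    """
    if S0 < 0:
        raise ValueError(f"S0 must be nonnegative, got {S0!r}")
    p = params
    d1, d2, d3 = p.alpha + p.lam, p.alpha + p.mu1, p.alpha + p.mu2
    a0 = 1.0
    a1 = 3 * p.alpha + p.lam + p.mu1 + p.mu2
    a2 = (
        -p.b * p.lam * p.beta * p.eta * S0
        + d1 * d2 + d3 * d1 + d2 * d3
        - p.beta * p.zeta * S0 * (1 - p.b) * p.lam
    )
    a3 = (
        -p.b * p.lam * p.beta * p.eta * S0 * d3
        - p.b * p.lam * p.beta * S0 * p.zeta * p.mu1 * (1 - p.u1)
        + d2 * d3 * d1
        - d2 * p.beta * p.zeta * S0 * (1 - p.b) * p.lam
    )
    return (a0, float(a1), float(a2), float(a3))


@dataclass(frozen=True)
class RouthHurwitz:
    delta2: float
    delta3: float
    all_roots_negative_real_part: bool


def routh_hurwitz(coeffs: tuple[float, float, float, float]) -> RouthHurwitz:
    """Hurwitz minors of a cubic a0λ³ + a1λ² + a2λ + a3 with a0 > 0.

    Δ2 = a1a2 − a0a3 and Δ3 = a3·Δ2.  All roots have negative real part
    iff a1 > 0, Δ2 > 0 and Δ3 > 0.
    """
    a0, a1, a2, a3 = (float(c) for c in coeffs)
    if a0 <= 0:
        raise ValueError(f"leading coefficient a0 must be positive, got {a0!r}")
    delta2 = a1 * a2 - a0 * a3
    delta3 = a3 * delta2
    stable = (a1 > 0) and (delta2 > 0) and (delta3 > 0)
    return RouthHurwitz(delta2=float(delta2), delta3=float(delta3),
                        all_roots_negative_real_part=stable)


@dataclass(frozen=True)
class StabilityReport:
    """Everything the free-equilibrium classification rests on.

    ``factored_roots`` are the two explicit eigenvalues (−α, γ−α);
    ``eigenvalues`` are the six numeric eigenvalues of the full 6×6
    Jacobian at Q0, sorted by descending real part (ties by descending
    imaginary part) so reports are deterministic.  The numeric
    eigenvalues are reported alongside the closed-form rule but never
    override it.
    """

    jacobian: np.ndarray
    factored_roots: tuple[float, float]
    cubic_coeffs: tuple[float, float, float, float]
    delta2: float
    delta3: float
    eigenvalues: np.ndarray
    R0: float
    classification: Classification

    def to_text(self) -> str:
        buf = io.StringIO()
        kv = self.to_flat_dict()
        for k, v in kv.items():
            buf.write(f"{k} = {v}\n")
        return buf.getvalue()

    def to_flat_dict(self) -> dict[str, object]:
        d: dict[str, object] = {
            "R0": self.R0,
            "root_minus_alpha": self.factored_roots[0],
            "root_gamma_minus_alpha": self.factored_roots[1],
            "a0": self.cubic_coeffs[0],
            "a1": self.cubic_coeffs[1],
            "a2": self.cubic_coeffs[2],
            "a3": self.cubic_coeffs[3],
            "delta2": self.delta2,
            "delta3": self.delta3,
            "classification": self.classification.value,
        }
        for i, ev in enumerate(self.eigenvalues, start=1):
            d[f"eig{i}_re"] = float(np.real(ev))
            d[f"eig{i}_im"] = float(np.imag(ev))
        return d


def _sorted_eigenvalues(J: np.ndarray) -> np.ndarray:
    ev = np.linalg.eigvals(J)
    order = np.lexsort((-ev.imag, -ev.real))
    return ev[order]


def classify_free_equilibrium(params: ModelParams, S0: float) -> StabilityReport:
    """Classify Q0 = (S0, 0, 0, 0, S0, 0) by the sign of γ − α.

    The rule applies only under the hypothesis R0 < 1; otherwise the
    verdict is NOT_APPLICABLE.  γ − α > 0: locally stable but not
    asymptotically stable (the population drifts); γ − α = 0: unstable;
    γ − α < 0: locally asymptotically stable.  The sign comparison is
    exact — parameters are user-specified literals, no epsilon.
    """
    from .equilibria import free_equilibrium  # local import avoids a cycle

    p = params
    ngd = next_generation(p, S0)
    q0 = free_equilibrium(S0)
    J = jacobian(q0, p)
    coeffs = cubic_coefficients(p, S0)
    rh = routh_hurwitz(coeffs)
    if ngd.R0 >= 1:
        verdict = Classification.NOT_APPLICABLE
    else:
        gap = p.gamma - p.alpha
        if gap > 0:
            verdict = Classification.STABLE_NOT_ASYMPTOTIC
        elif gap == 0:
            verdict = Classification.UNSTABLE
        else:
            verdict = Classification.ASYMPTOTICALLY_STABLE
    return StabilityReport(
        jacobian=J,
        factored_roots=(-p.alpha, p.gamma - p.alpha),
        cubic_coeffs=coeffs,
        delta2=rh.delta2,
        delta3=rh.delta3,
        eigenvalues=_sorted_eigenvalues(J),
        R0=ngd.R0,
        classification=verdict,
    )
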