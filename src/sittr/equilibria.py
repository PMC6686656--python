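"""Closed-form equilibria of the SIT1T2R system and a Newton audit.

Two fixed points are analysed.  The free (disease-free) equilibrium
Q0 = (S0, 0, 0, 0, S0, 0) has no patients in any treatment class; note
it is an exact root of the vector field only when γ = α — otherwise
S' = N' = (γ−α)S0 there, and :func:`free_equilibrium_residual` exposes
exactly that defect rather than hiding it.

The endemic equilibrium Q* is transcribed literally from its stated
closed forms: every starred component is a multiple of T1*, with the
intermediate scalars E (the S*/T1* ratio) and L (the T2*/T1* ratio)
carrying the parameter dependence.  The transcription chain contains
internal tensions — the E numerator's grouping, (λ−α) versus (γ−α) in
the N* denominator — so rather than guessing authorial intent the
package evaluates the formulas as written and *measures* the defect:
``residual_norm`` is the max-norm of the vector field at Q*, and
:func:`solve_equilibrium_numeric` is an independent damped-Newton root
finder that audits the closed forms against a true root of the system.

There is no closed form for R*; it is reconstructed from R' = 0 as
R* = (u1μ1T1* + u2μ2T2*)/α, the unique value forced by the R equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import COMPARTMENTS, ModelParams, State, rhs
from . import stability as _stability

__all__ = [
    "EndemicEquilibrium",
    "NewtonResult",
    "free_equilibrium",
    "free_equilibrium_residual",
    "endemic_equilibrium",
    "solve_equilibrium_numeric",
]


def free_equilibrium(S0: float) -> State:
    """The free equilibrium Q0 with S = N = S0 and no patients.

    The point is stated as the 5-tuple (S0, 0, 0, 0, S0) for a
    6-compartment model; the final entry maps to N and R is set to 0
    (an interpretation, flagged as such).
    """
    S0 = float(S0)
    if S0 < 0:
        raise ValueError(f"S0 must be nonnegative, got {S0!r}")
    return State(S=S0, I=0.0, T1=0.0, T2=0.0, N=S0, R=0.0)


def free_equilibrium_residual(S0: float, params: ModelParams) -> np.ndarray:
    """Vector field at Q0: exactly (γ−α)S0 in the S and N slots, 0 elsewhere."""
    return rhs(free_equilibrium(S0), params)


@dataclass(frozen=True)
class EndemicEquilibrium:
    """The endemic equilibrium Q* = (S*, I*, T1*, T2*, N*) plus audit fields.

    ``E`` and ``L`` are the intermediate scalars (S* = E·T1*,
    T2* = L·T1*).  ``lambda_gt_alpha`` and ``interior_inequality`` are
    the two stated interior-positivity conditions; ``feasible`` is their
    conjunction together with nonnegativity of every starred component,
    so feasible=True guarantees a point in the closed positive orthant.
    ``residual_norm`` is the max-norm of the vector field at the point
    (R* reconstructed) — the measured defect of the transcribed formulas.
    """

    S_star: float
    I_star: float
    T1_star: float
    T2_star: float
    N_star: float
    R_star: float
    E: float
    L: float
    lambda_gt_alpha: bool
    interior_inequality: bool
    feasible: bool
    residual_norm: float

    @property
    def P_star(self) -> float:
        """Alias used by the sign-stability analysis: P* = I*."""
        return self.I_star

    def to_state(self) -> State:
        return State(S=self.S_star, I=self.I_star, T1=self.T1_star,
                     T2=self.T2_star, N=self.N_star, R=self.R_star)

    def to_flat_dict(self) -> dict[str, float | bool]:
        return {
            "S_star": self.S_star, "I_star": self.I_star,
            "T1_star": self.T1_star, "T2_star": self.T2_star,
            "N_star": self.N_star, "R_star": self.R_star,
            "E": self.E, "L": self.L,
            "lambda_gt_alpha": self.lambda_gt_alpha,
            "interior_inequality": self.interior_inequality,
            "feasible": self.feasible,
            "residual_norm": self.residual_norm,
        }


def _require_nonzero(value: float, description: str) -> float:
    if value == 0:
        raise ZeroDivisionError(f"denominator {description} vanishes for these parameters")
    return value


def endemic_equilibrium(params: ModelParams) -> EndemicEquilibrium:
    """Evaluate the stated closed forms for Q* literally.

    E = [γλ(1−u2)μ2(1−u1)μ1 + (1−u2)μ2(1−b)(μ1+α)
         − (λ+α)(μ1+α)(γ−α)(μ2+α)] / [λb(γ−α)(μ2+α)]
    L = [b(1−u1)μ1 + (1−b)(μ1+α)] / [b(μ2+α)]
    T1* = (α+λ)(α+μ1) / (λb(βηE + βELζ)),  S* = E·T1*,
    I* = (α+μ1)/(bλ)·T1*,  T2* = L·T1*,
    N* = (1−u2)μ2[b(1−u1)μ1 + (1−b)(μ1+α)] / ((λ−α)b(μ2+α))·T1*.

    Interior positivity requires λ > α together with the displayed
    inequality (equivalently: E's numerator positive).  The returned
    ``residual_norm`` measures how far the point is from an actual root;
    use :func:`solve_equilibrium_numeric` for the audited root.
    """
    p = params
    _require_nonzero(p.lam * p.b, "λ·b")
    _require_nonzero(p.b * (p.alpha + p.mu2), "b(α+μ2)")
    _require_nonzero(p.gamma - p.alpha, "(γ−α)")
    _require_nonzero(p.lam - p.alpha, "(λ−α)")

    E_num = (
        p.gamma * p.lam * (1 - p.u2) * p.mu2 * (1 - p.u1) * p.mu1
        + (1 - p.u2) * p.mu2 * (1 - p.b) * (p.mu1 + p.alpha)
        - (p.lam + p.alpha) * (p.mu1 + p.alpha) * (p.gamma - p.alpha) * (p.mu2 + p.alpha)
    )
    E_den = p.lam * p.b * (p.gamma - p.alpha) * (p.mu2 + p.alpha)
    E = E_num / E_den

    L = (p.b * (1 - p.u1) * p.mu1 + (1 - p.b) * (p.mu1 + p.alpha)) / (
        p.b * (p.mu2 + p.alpha)
    )

    T1_den = _require_nonzero(
        p.lam * p.b * (p.beta * p.eta * E + p.beta * E * L * p.zeta),
        "λb·βE(η + Lζ)",
    )
    T1 = (p.alpha + p.lam) * (p.alpha + p.mu1) / T1_den
    S = E * T1
    I = (p.alpha + p.mu1) / (p.b * p.lam) * T1
    T2 = L * T1
    N = (
        (1 - p.u2) * p.mu2
        * (p.b * (1 - p.u1) * p.mu1 + (1 - p.b) * (p.mu1 + p.alpha))
        / ((p.lam - p.alpha) * p.b * (p.mu2 + p.alpha))
        * T1
    )
    _require_nonzero(p.alpha, "α (R* reconstruction)")
    R = (p.u1 * p.mu1 * T1 + p.u2 * p.mu2 * T2) / p.alpha

    lam_gt = p.lam > p.alpha
    # Displayed interior inequality, same literal grouping as E's numerator:
    interior = (
        p.gamma * p.lam * (1 - p.u2) * p.mu2 * (1 - p.u1) * p.mu1
        + (1 - p.u2) * p.mu2 * (1 - p.b) * (p.mu1 + p.alpha)
    ) > (p.lam + p.alpha) * (p.mu1 + p.alpha) * (p.gamma - p.alpha) * (p.mu2 + p.alpha)

    starred = (S, I, T1, T2, N, R)
    feasible = bool(lam_gt and interior and all(np.isfinite(starred))
                    and all(v >= 0 for v in starred))

    if all(np.isfinite(starred)):
        resid = float(np.max(np.abs(rhs(np.array(starred), p))))
    else:  # pragma: no cover - only reachable through pathological params
        resid = float("inf")

    return EndemicEquilibrium(
        S_star=float(S), I_star=float(I), T1_star=float(T1), T2_star=float(T2),
        N_star=float(N), R_star=float(R), E=float(E), L=float(L),
        lambda_gt_alpha=bool(lam_gt), interior_inequality=bool(interior),
        feasible=feasible, residual_norm=resid,
    )


@dataclass(frozen=True)
class NewtonResult:
    state: State
    residual_norm: float
    converged: bool
    iterations: int
    message: str


def solve_equilibrium_numeric(
    params: ModelParams,
    initial_guess: State,
    tol: float = 1e-10,
    max_iter: int = 200,
    max_halvings: int = 50,
) -> NewtonResult:
    """Damped Newton iteration on the vector field from ``initial_guess``.

    Serves as the independent oracle for the closed-form Q*: whatever
    root it finds is re-checked to max-norm residual ≤ tol·scale, where
    scale = max(1, ‖y‖_∞).  The step is halved (up to ``max_halvings``
    times) until the residual norm decreases; a singular Jacobian or
    stalled line search is reported with the current iterate rather than
    raised.
    """
    y = initial_guess.to_array()
    f = rhs(y, params)

    def scale(v: np.ndarray) -> float:
        return max(1.0, float(np.max(np.abs(v))))

    for it in range(max_iter):
        fnorm = float(np.max(np.abs(f)))
        if fnorm <= tol * scale(y):
            return NewtonResult(State.from_array(y), fnorm, True, it, "converged")
        J = _stability.jacobian(y, params)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return NewtonResult(
                State.from_array(y), fnorm, False, it,
                f"singular Jacobian at iterate {it}",
            )
        s = 1.0
        for _ in range(max_halvings):
            y_new = y + s * step
            if np.all(np.isfinite(y_new)):
                f_new = rhs(y_new, params)
                if float(np.max(np.abs(f_new))) < fnorm:
                    break
            s *= 0.5
        else:
            return NewtonResult(
                State.from_array(y), fnorm, False, it,
                f"line search stalled at iterate {it}",
            )
        y, f = y_new, f_new

    fnorm = float(np.max(np.abs(f)))
    converged = fnorm <= tol * scale(y)
    return NewtonResult(State.from_array(y), fnorm, converged, max_iter,
                        "converged" if converged else "maximum iterations reached")
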