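# Methods

## The model

`sittr` implements a compartmental dynamic model of infertility
treatment in a clinic population where polycystic ovary syndrome (PCOS)
is the infertility factor. Women move through five classes — susceptible
newcomers S, diagnosed patients I, a drug-treatment arm T1 (clomiphene
citrate + gonadotropin), an IVF arm T2, and recovered patients R — and
the total clinic population N carries its own rate equation:

    S'  = γN − αS − βS(ηT1 + ζT2)
    I'  = −λI − αI + βS(ηT1 + ζT2)
    T1' = −μ1 T1 − αT1 + λIb
    T2' = −μ2 T2 − αT2 + (1−u1)μ1 T1 + (1−b)λI
    R'  = −αR + u1 μ1 T1 + u2 μ2 T2
    N'  = γN − (1−u2)μ2 T2 − αN

The bilinear term βS(ηT1 + ζT2) models relapse: miscarriage or ovarian
hyperstimulation returning women under treatment to the patient pool,
at a rate proportional to both the susceptible pool and the
treatment-speed-weighted occupancy of the two arms. The model assumes
homogeneous mixing within the clinic population, continuous counts, and
time-constant rates; there is no age structure and no explicit delay
between treatment cycles.

### Parameters

All rates are per unit time; fractions are dimensionless in [0, 1].

| name  | meaning                                             | preset value |
|-------|-----------------------------------------------------|--------------|
| alpha | drop-out rate (leaving the clinic without result)   | 0.3 / 0.16   |
| gamma | arrival rate of new infertile couples               | 0.5 / 0.23   |
| beta  | relapse (return-to-treatment) rate                  | 0.1          |
| lam   | treatment-assignment rate (λ)                       | 0.47         |
| b     | fraction assigned to the drug arm                   | 0.34         |
| eta   | treatment speed of the drug arm (η)                 | 0.47         |
| zeta  | treatment speed of the IVF arm (ζ)                  | 0.16 / 0.08  |
| mu1   | recovery/progression rate of the drug arm (μ1)      | 0.9          |
| mu2   | recovery rate of the IVF arm (μ2)                   | 0.92 / 0.96  |
| u1    | cure fraction of the drug arm                       | 0.04         |
| u2    | cure fraction of the IVF arm                        | 0.29 / 0.19  |

The three scenario presets (`fig7`: ages 20–25, `fig8`: ages 25–30, both
with ovarian reserve above 3.5; `fig9`: reserve below 3.5) carry the ten
documented parameter values each. **The relapse rate β is not part of
any documented scenario**; the package fixes β = 0.1 per unit time for
all presets. The value was chosen once, on two grounds: it keeps the
relapse flow βS(ηT1 + ζT2) at the shared initial state (≈ 22 per unit
time) the same order of magnitude as the other flows, and it keeps
R0 < 1 for all three presets (R0 ≈ 0.23, 0.32, 0.24 at S0 = 15), the
regime in which the free-equilibrium classification applies. All
reported scenario numbers inherit this choice.

### Redundant N and the conservation diagnostic

N is definitionally S + I + T1 + T2 + R, yet the system integrates all
six equations. The package keeps the 6-dimensional form and turns the
redundancy into a diagnostic: symbolically, (S'+I'+T1'+T2'+R') − N'
= α·(N − (S+I+T1+T2+R)), so the bookkeeping defect obeys
defect' = −α·defect and stays at round-off zero along any trajectory
started from a consistent state. `conservation_residual` exposes this,
and `Trajectory.max_conservation_defect()` tracks it along runs
(≈ 1e-13 on the presets). Consistency of a state is checked against a
relative tolerance of 1e-8·max(1, N) — the identity is exact; the slack
only absorbs float drift.

## Reproduction number

R0 is computed from the next-generation decomposition of the infected
(I, T1, T2) subsystem linearized with S = N = S0: the "returning
matrix" F holds the relapse inflow (single nonzero row
(0, βηS0, βζS0)), the "affected matrix" K the transitions, and
R0 = trace(F·K⁻¹) = H. K is lower triangular with diagonal
(α+λ, α+μ1, α+μ2); the closed-form inverse is kept alongside a dense
numeric inverse and the two are required to agree to 1e-10. Since F·K⁻¹
has a single nonzero row its trace equals its spectral radius, so the
trace form coincides with the usual spectral definition.

## Equilibria

The free equilibrium Q0 = (S0, 0, 0, 0, S0) is stated as a 5-tuple for
a 6-compartment model; the final entry is mapped to N and R is set to 0
(an interpretation, exposed as such). Q0 is an exact root of the field
only when γ = α; otherwise S' = N' = (γ−α)S0 there. The package does
not reinterpret: `free_equilibrium_residual` reports the defect, and
the stability classification below follows the stated rule regardless.

The endemic equilibrium Q* is transcribed literally from its closed
forms: every starred component is a multiple of T1*, with E = S*/T1*
and L = T2*/T1*. The transcription chain is internally inconsistent —
the E numerator is a run-on product whose grouping is ambiguous, and
the N* denominator carries (λ−α) where the N-equation derivation gives
(γ−α). Where grouping was genuinely ambiguous the package takes the
most literal token-by-token reading:

    E = [γλ(1−u2)μ2(1−u1)μ1 + (1−u2)μ2(1−b)(μ1+α)
         − (λ+α)(μ1+α)(γ−α)(μ2+α)] / [λb(γ−α)(μ2+α)]

and never "corrects" any formula. Instead the defect is *measured*:
`EndemicEquilibrium.residual_norm` is the max-norm of the vector field
at Q* (with R* reconstructed from R' = 0 as (u1μ1T1* + u2μ2T2*)/α, the
unique value the R equation forces), and `solve_equilibrium_numeric` is
an independent damped-Newton root finder used to audit the closed
forms. On the fig7 preset the closed-form Q* is positive and "feasible"
by the stated interior conditions (λ > α plus the displayed inequality,
here augmented with a nonnegativity check on all components) yet has
residual_norm ≈ 24; Newton seeded there converges to a genuine root
with negative treatment compartments — consistent with R0 < 1, under
which no positive endemic equilibrium should exist.

Newton defaults: max 200 iterations, step halving up to 50 times until
the residual norm decreases, convergence at max-norm residual
≤ 1e-10·max(1, ‖y‖∞). Singular Jacobians and stalled line searches are
reported with the iterate, not raised.

## Free-equilibrium stability

The 6×6 Jacobian at Q0 factors into explicit eigenvalues −α (twice, the
decoupled S and R columns) and γ−α (the N row), plus the cubic
characteristic polynomial of the (I, T1, T2) block with coefficients

    a0 = 1,  a1 = 3α + λ + μ1 + μ2,
    a2 = (α+λ)(α+μ1) + (α+μ2)(λ+α) + (α+μ1)(α+μ2) − bλβηS0 − βζS0(1−b)λ,
    a3 = (α+μ1)(α+μ2)(α+λ) − bλβηS0(α+μ2) − bλβS0ζμ1(1−u1) − (α+μ1)βζS0(1−b)λ.

(Note a3 = (α+λ)(α+μ1)(α+μ2)(1 − R0).) Routh–Hurwitz minors
Δ2 = a1a2 − a0a3 and Δ3 = a3Δ2 decide the cubic; when R0 < 1 all are
positive, so the classification rests entirely on the sign of γ − α:
positive → locally stable but not asymptotically stable; zero →
unstable; negative → locally asymptotically stable. The rule is applied
exactly as stated, gated on R0 < 1 (otherwise NOT_APPLICABLE); numeric
eigenvalues are reported alongside (sorted by descending real part,
ties by descending imaginary part, for deterministic fixtures) but
never override it. The γ − α sign comparison is exact, no epsilon —
parameters are user-supplied literals.

In the characteristic-equation display two stray symbols δ1, δ2 appear;
they are read as η, ζ, the only reading consistent with H.

## Sign stability

`sign_stability` is a general tester of the five-condition qualitative
stability criterion (diagonal, antisymmetry, long cycles, colouring,
matching) for n ≤ 20, with exhaustive enumeration throughout. Design
readings, each adopted once and flagged:

- Condition (i) is implemented as *diagonal* nonpositivity (a_ii ≤ 0).
  The verbatim "a_ij ≤ 0 for all i, j" would disqualify any positive
  off-diagonal entry, contradicting the worked rejection of the
  reference pattern via its (5,5) diagonal entry alone.
- The directed and undirected graph edge sets are printed identically
  in the source material (a copy error); the standard definitions are
  used: D_A edges {(i,j): i≠j, a_ij≠0}, G_A edges {{i,j}: i≠j,
  a_ij≠0≠a_ji}.
- Zero tolerance for sign extraction defaults to 0 (patterns from
  symbolic structure); for numerically computed Jacobians callers pass
  a relative tolerance (1e-12·‖J‖max in the report pipeline).

The shipped reference pattern `MATRIX_B` for the endemic-equilibrium
community matrix has (2,1) = 0, whereas the analytic Jacobian carries
∂I'/∂S = β(ηT1*+ζT2*) > 0 at any positive equilibrium; tests pin the
discrepancy down to that single entry. Both objects fail condition (i)
through the (5,5) entry (γ − α > 0 whenever arrivals outpace
drop-outs), so the qualitative conclusion — the endemic point is not
sign stable under population growth — is identical either way. A
Monte-Carlo soundness oracle (`sample_same_pattern`, magnitudes
uniform(0.1, 10), fixed seed) backs every accepted pattern with 500
eigenvalue checks in the test suite.

## Numerical integration

The integrator is the classical fixed-step RK4 scheme exactly as the
model's numerical treatment specifies (stages K1..K4, weights
(1, 2, 2, 1)/6), applied to all six compartments simultaneously. The
stage formulas in the source print "K1,i = h_i(...)"; this is read as
h·f_i(...), the only reading compatible with the stated update rule.
The grid symbol clash (h defined, k used) is read as the same quantity.

The integration horizon is nowhere stated in the source material. The
package default is t_start = 0, t_end = 10, M = 50 (h = 0.2), chosen so
the preset trajectories exhibit the interior minima the scenario
narrative describes; the horizon is a config knob and every report
bundle records it. Negative compartment values are reported (first
crossing time per compartment), never clipped. A non-finite stage ends
the run with a partial trajectory and an error index rather than an
exception. Trajectories serialize with 12 significant digits.

Convergence order is verified two ways: one RK4 step of y' = −y
reproduces the degree-4 Taylor polynomial of e^(−h) exactly, and global
errors against an M = 10000 reference on the fig7 scenario scale as h⁴.
The error ratio per halving is 21.1 at the coarsest pair (h = 0.4 →
0.2) — pre-asymptotic, within a factor of two of 16 — and 18.4 and 17.2
for h = 0.2 → 0.1 → 0.05; the strict [12, 20] order check is therefore
measured on h ≤ 0.2, the asymptotic regime.

## Scenario comparisons and known discrepancies

The scenario narrative makes two quantitative claims about the fig8 vs
fig7 trajectories: the minimum of R in fig8 is "approximately 0.25" of
fig7's, and the minimum of T2 is "half". Under the package's study
conditions (β = 0.1, default horizon, M = 50) the measured ratios are
1.131 (R) and 0.627 (T2). Scanning every horizon t_end ∈ [5, 50] (both
at M = 50 and at fixed h = 0.2) gives R ratios in [1.03, 1.29] and T2
ratios in [0.63, 0.78]; beyond t_end ≈ 35 the exponentially growing
population (γ > α) drives the bilinear relapse term into overflow at
these step sizes. The stated ratios are therefore not reproducible from
the documented information — the source states neither the horizon nor
the axes of its figures nor β — and the corresponding two checks in
`tests/test_acceptance.py` fail by design rather than being weakened;
the property-based suite carries the validation. The qualitative
claims, by contrast, are reproduced: R dips to an interior minimum
before recovering, T1 and T2 end in an increasing mode, and fig8's
minima occur later than fig7's (slower treatment turnaround in the
older cohort).

A second narrative comparison (fig8 vs fig9 treatment-duration and γ
ratios) is self-contradictory as stated and no check is built from it.

## What the presets do and do not emulate

The presets are parameter sets, not data: they reproduce the model's
published case studies, with counts treated as continuous and a single
shared initial state. They do not emulate measurement noise,
demographic stochasticity, parameter uncertainty, or any feature of the
underlying clinic records (which are not public); passing tests
demonstrate internal correctness of the implementation and
reproducibility of the model's qualitative behaviour, not fit to
patient data.

## Limitations

- The closed-form Q* is transcribed, not derived; its residual is the
  honest measure of the source formulas' internal consistency, and the
  Newton audit, not the closed form, should be used when an actual
  root is needed.
- The sign-stability tester covers the five classical conditions only —
  no sign semi-stability and no full Jeffries–Klee–van den Driessche
  characterization.
- Fixed-step RK4 only: no adaptive stepping, stiffness control or event
  detection; long horizons under population growth require manually
  refining h.
- β and the horizon are modelling choices of this package (documented
  above), not published values; conclusions sensitive to them should be
  re-run across a range.
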