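"""Scenario presets, config handling and end-to-end report bundles.

Three presets — ``fig7``, ``fig8``, ``fig9`` — carry the parameter sets
of the model's three numerical case studies (younger patients, older
patients, and low ovarian reserve respectively) together with the
shared initial state (S, I, T1, T2, N, R) = (15, 30, 27, 12, 104, 20),
which is consistent by construction (15+30+27+12+20 = 104).  The case
studies never state the relapse rate β; all presets use β = 0.1 per
unit time (see docs/methods.md for the rationale) and the default
horizon [0, 10] with M = 50 steps (h = 0.2).

Scenario files are flat YAML documents with exactly the documented
keys; unknown keys are rejected by name, and the initial state must
pass the bookkeeping consistency check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .equilibria import endemic_equilibrium, solve_equilibrium_numeric
from .model import COMPARTMENTS, PARAM_NAMES, ModelParams, State
from .sign_stability import SignStabilityVerdict, is_sign_stable
from .solver import (CSV_FLOAT_FORMAT, IntegrationWarning, TimeGrid, Trajectory,
                     integrate, summarize)
from .stability import classify_free_equilibrium, jacobian, next_generation

__all__ = [
    "Scenario",
    "SchemaError",
    "PRESETS",
    "CONFIG_KEYS",
    "load_scenario",
    "save_scenario",
    "run_report",
    "compare_scenarios",
    "ComparisonRecord",
]


class SchemaError(ValueError):
    """A scenario config violates the documented flat schema."""


_STATE_KEYS = ("S0", "I0", "T1_0", "T2_0", "N0", "R0_init")
_GRID_KEYS = ("t_start", "t_end", "M")

#: Required keys of a scenario config, in canonical order.
CONFIG_KEYS = PARAM_NAMES + _STATE_KEYS + _GRID_KEYS

_OPTIONAL_KEYS = ("name", "description")


@dataclass(frozen=True)
class Scenario:
    name: str
    params: ModelParams
    initial: State
    grid: TimeGrid
    description: str = ""

    def to_config_dict(self) -> dict[str, object]:
        d: dict[str, object] = {"name": self.name, "description": self.description}
        d.update(self.params.as_dict())
        s = self.initial
        d.update(S0=s.S, I0=s.I, T1_0=s.T1, T2_0=s.T2, N0=s.N, R0_init=s.R)
        d.update(t_start=self.grid.t_start, t_end=self.grid.t_end, M=self.grid.M)
        return d


def _preset(name, description, *, alpha, gamma, zeta=0.16, mu2=0.92, u2=0.29):
    return Scenario(
        name=name,
        description=description,
        params=ModelParams(alpha=alpha, gamma=gamma, beta=0.1, lam=0.47, b=0.34,
                           eta=0.47, zeta=zeta, mu1=0.9, mu2=mu2, u1=0.04, u2=u2),
        initial=State(S=15.0, I=30.0, T1=27.0, T2=12.0, N=104.0, R=20.0),
        grid=TimeGrid(t_start=0.0, t_end=10.0, M=50),
    )


PRESETS: dict[str, Scenario] = {
    "fig7": _preset("fig7", "ages 20-25, ovarian reserve > 3.5",
                    alpha=0.3, gamma=0.5),
    "fig8": _preset("fig8", "ages 25-30, ovarian reserve > 3.5",
                    alpha=0.16, gamma=0.23),
    "fig9": _preset("fig9", "ovarian reserve < 3.5",
                    alpha=0.16, gamma=0.23, zeta=0.08, mu2=0.96, u2=0.19),
}


def load_scenario(source: str | Path) -> Scenario:
    """Load a preset by name or a flat YAML config by path.

    Raises :class:`SchemaError` listing the offending keys on any
    missing key, unknown key, non-numeric value, out-of-range parameter
    or inconsistent initial state.
    """
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    path = Path(source)
    if not path.exists():
        raise SchemaError(
            f"{source!r} is neither a preset ({', '.join(sorted(PRESETS))}) "
            "nor an existing config file"
        )
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"config {path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} must be a flat key-value mapping")

    unknown = sorted(set(raw) - set(CONFIG_KEYS) - set(_OPTIONAL_KEYS))
    missing = sorted(set(CONFIG_KEYS) - set(raw))
    problems = []
    if unknown:
        problems.append(f"unknown keys: {', '.join(unknown)}")
    if missing:
        problems.append(f"missing keys: {', '.join(missing)}")
    if problems:
        raise SchemaError(f"config {path}: " + "; ".join(problems))

    numeric: dict[str, float] = {}
    bad_types = []
    for key in CONFIG_KEYS:
        v = raw[key]
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            bad_types.append(key)
        else:
            numeric[key] = float(v)
    if bad_types:
        raise SchemaError(f"config {path}: non-numeric values for: {', '.join(bad_types)}")

    try:
        params = ModelParams(**{k: numeric[k] for k in PARAM_NAMES})
        initial = State(S=numeric["S0"], I=numeric["I0"], T1=numeric["T1_0"],
                        T2=numeric["T2_0"], N=numeric["N0"], R=numeric["R0_init"])
        grid = TimeGrid(t_start=numeric["t_start"], t_end=numeric["t_end"],
                        M=int(numeric["M"]))
    except ValueError as exc:
        raise SchemaError(f"config {path}: {exc}") from exc
    if not initial.is_consistent():
        raise SchemaError(
            f"config {path}: initial state inconsistent: "
            f"N0 − (S0+I0+T1_0+T2_0+R0_init) = {initial.consistency_residual()!r}"
        )
    return Scenario(
        name=str(raw.get("name", path.stem)),
        description=str(raw.get("description", "")),
        params=params, initial=initial, grid=grid,
    )


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario as a flat YAML config (round-trips through
    :func:`load_scenario`)."""
    Path(path).write_text(
        yaml.safe_dump(scenario.to_config_dict(), sort_keys=False)
    )


def _write_flat(path: Path, mapping: dict[str, object]) -> None:
    path.write_text("".join(f"{k} = {v}\n" for k, v in mapping.items()))


def _write_flat_csv(path: Path, mapping: dict[str, object]) -> None:
    pd.DataFrame([mapping]).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def run_report(
    scenario: Scenario,
    outdir: str | Path,
    plot: bool = False,
    seed: int | None = None,
) -> dict[str, object]:
    """Produce the full report bundle for one scenario in ``outdir``.

    Writes trajectory.csv, summary.csv, the next-generation/R0 record
    (S0 taken as the scenario's initial S — the disease-free derivation
    sets S(t) = S0 — overridable by editing the scenario), the
    free-equilibrium stability report, the sign-stability verdict of the
    endemic-equilibrium Jacobian (evaluated at the Newton root when the
    audit converges, else at the closed-form Q*), the Q0 Jacobian as
    CSV, a manifest, and optionally a compartments-vs-time plot.

    ``outdir`` must not exist or must be empty.  Each stage's failure is
    recorded in the manifest and the remaining stages still run.
    Returns the manifest mapping.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        raise FileExistsError(f"output directory {outdir} is not empty")
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, object] = {"software_version": _pkg_version,
                                   "seed": "" if seed is None else seed}
    manifest.update(scenario.to_config_dict())
    stages: dict[str, str] = {}

    traj: Trajectory | None = None
    try:
        traj = integrate(scenario.initial, scenario.grid, scenario.params)
        traj.to_csv(outdir / "trajectory.csv")
        summarize(traj).to_csv(outdir / "summary.csv", index=False,
                               float_format=CSV_FLOAT_FORMAT)
        stages["simulate"] = "ok" if traj.completed else (
            f"partial: non-finite after node {traj.error_index}"
        )
        for name, t_neg in traj.negative_crossings().items():
            warnings.warn(
                f"compartment {name} first goes negative at t = {t_neg:g}",
                IntegrationWarning,
            )
            stages[f"negative_{name}"] = f"{t_neg:g}"
    except Exception as exc:  # recorded, remaining stages still attempted
        stages["simulate"] = f"failed: {exc}"

    S0 = scenario.initial.S
    try:
        ngd = next_generation(scenario.params, S0)
        _write_flat_csv(outdir / "r0.csv",
                        {"S0": S0, "R0": ngd.R0, "H": ngd.H, "G": ngd.G})
        stages["r0"] = "ok"
    except Exception as exc:
        stages["r0"] = f"failed: {exc}"

    try:
        report = classify_free_equilibrium(scenario.params, S0)
        (outdir / "stability.txt").write_text(report.to_text())
        _write_flat_csv(outdir / "stability.csv", report.to_flat_dict())
        pd.DataFrame(report.jacobian, index=list(COMPARTMENTS),
                     columns=list(COMPARTMENTS)).to_csv(
            outdir / "jacobian_q0.csv", float_format=CSV_FLOAT_FORMAT)
        stages["stability"] = "ok"
    except Exception as exc:
        stages["stability"] = f"failed: {exc}"

    try:
        verdict, at = _endemic_sign_stability(scenario)
        (outdir / "sign_stability.txt").write_text(
            f"evaluated_at = {at}\n" + verdict.to_text())
        _write_flat_csv(outdir / "sign_stability.csv",
                        {"evaluated_at": at, **verdict.to_flat_dict()})
        stages["signstab"] = "ok"
    except Exception as exc:
        stages["signstab"] = f"failed: {exc}"

    if plot and traj is not None:
        try:
            _plot_trajectory(traj, scenario.name, outdir / "trajectory.png")
            stages["plot"] = "ok"
        except Exception as exc:  # pragma: no cover - backend issues only
            stages["plot"] = f"failed: {exc}"

    manifest.update({f"stage_{k}": v for k, v in stages.items()})
    _write_flat(outdir / "manifest.txt", manifest)
    return manifest


def _endemic_sign_stability(scenario: Scenario) -> tuple[SignStabilityVerdict, str]:
    """Sign-stability verdict of the (S, I, T1, T2, N) community matrix at Q*.

    The endemic point is the Newton root seeded at the closed-form Q*
    when that audit converges, else the closed-form point itself.  The
    5×5 block matches the model's qualitative-stability analysis (the R
    column is decoupled); a relative zero tolerance distinguishes
    structural zeros from round-off.
    """
    q_closed = endemic_equilibrium(scenario.params)
    newton = solve_equilibrium_numeric(scenario.params, q_closed.to_state())
    if newton.converged:
        point, at = newton.state, "newton_root"
    else:
        point, at = q_closed.to_state(), "closed_form"
    J5 = jacobian(point, scenario.params)[:5, :5]
    zero_tol = 1e-12 * float(np.max(np.abs(J5)))
    return is_sign_stable(J5, zero_tol=zero_tol), at


def _plot_trajectory(traj: Trajectory, title: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name in COMPARTMENTS:
        ax.plot(traj.t, traj.component(name), label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("count")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class ComparisonRecord:
    """Ratios (b over a) of per-compartment minima and times of minima,
    plus a parameter-difference table."""

    scenario_a: str
    scenario_b: str
    min_ratio: dict[str, float]
    t_min_ratio: dict[str, float]
    param_table: pd.DataFrame
    grid: TimeGrid


def compare_scenarios(a: Scenario, b: Scenario) -> ComparisonRecord:
    """Compare two scenarios on a shared grid.

    When the grids differ the coarser one (larger step h) is used for
    both, with a warning — the comparison is only meaningful on a
    common set of nodes.
    """
    grid = a.grid
    if (a.grid.t_start, a.grid.t_end, a.grid.M) != (b.grid.t_start, b.grid.t_end, b.grid.M):
        grid = a.grid if a.grid.h >= b.grid.h else b.grid
        warnings.warn(
            f"scenario grids differ; comparing both on the coarser grid "
            f"[{grid.t_start}, {grid.t_end}] with M={grid.M}"
        )
    sum_a = summarize(integrate(a.initial, grid, a.params)).set_index("compartment")
    sum_b = summarize(integrate(b.initial, grid, b.params)).set_index("compartment")
    with np.errstate(divide="ignore", invalid="ignore"):
        min_ratio = {c: float(sum_b.loc[c, "min"] / sum_a.loc[c, "min"])
                     for c in COMPARTMENTS}
        t_min_ratio = {c: float(np.divide(sum_b.loc[c, "t_min"], sum_a.loc[c, "t_min"]))
                       for c in COMPARTMENTS}
    pa, pb = a.params.as_dict(), b.params.as_dict()
    with np.errstate(divide="ignore", invalid="ignore"):
        param_table = pd.DataFrame(
            {
                "parameter": list(PARAM_NAMES),
                "a": [pa[k] for k in PARAM_NAMES],
                "b": [pb[k] for k in PARAM_NAMES],
                "ratio": [float(np.divide(pb[k], pa[k])) for k in PARAM_NAMES],
                "differs": [pa[k] != pb[k] for k in PARAM_NAMES],
            }
        )
    return ComparisonRecord(scenario_a=a.name, scenario_b=b.name,
                            min_ratio=min_ratio, t_min_ratio=t_min_ratio,
                            param_table=param_table, grid=grid)
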