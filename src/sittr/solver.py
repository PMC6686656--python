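"""Fixed-step classical Runge–Kutta integration of the SIT1T2R system.

The scheme is the textbook explicit RK4: four stages K1..K4 (K1 at the
node, K2 and K3 at the half step, K4 at the full step, each stage h·f at
the incremented state) combined as W_{j+1} = W_j + (K1 + 2K2 + 2K3 + K4)/6,
applied to all six compartments simultaneously — no per-component
splitting.  The grid is uniform: h = (t_end − t_start)/M.

Because the bookkeeping defect N − (S+I+T1+T2+R) obeys the exact ODE
residual' = −α·residual, a trajectory started from a consistent state
keeps its defect at zero up to round-off; :class:`Trajectory` exposes
the running defect as an accuracy diagnostic.  Compartments that go
negative are reported, never clipped — silent projection would mask
parameter or step-size pathologies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import COMPARTMENTS, ModelParams, State, _rhs_array

__all__ = [
    "TimeGrid",
    "Trajectory",
    "rk4_step",
    "rk4_step_general",
    "integrate",
    "summarize",
    "IntegrationWarning",
    "CSV_FLOAT_FORMAT",
]

#: Trajectories are written with 12 significant digits for fixture
#: reproducibility.
CSV_FLOAT_FORMAT = "%.12g"


class IntegrationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid on [t_start, t_end] with M steps (M+1 nodes)."""

    t_start: float
    t_end: float
    M: int

    def __post_init__(self) -> None:
        if int(self.M) != self.M or self.M < 1:
            raise ValueError(f"M must be a positive integer, got {self.M!r}")
        object.__setattr__(self, "M", int(self.M))
        object.__setattr__(self, "t_start", float(self.t_start))
        object.__setattr__(self, "t_end", float(self.t_end))
        if not (self.t_end > self.t_start):
            raise ValueError(
                f"t_end must exceed t_start, got [{self.t_start}, {self.t_end}]"
            )

    @property
    def h(self) -> float:
        return (self.t_end - self.t_start) / self.M

    def times(self) -> np.ndarray:
        return self.t_start + self.h * np.arange(self.M + 1)


def rk4_step_general(f, t: float, y: np.ndarray, h: float) -> np.ndarray:
    """One classical RK4 step of y' = f(t, y) for any vector field."""
    k1 = h * f(t, y)
    k2 = h * f(t + h / 2.0, y + k1 / 2.0)
    k3 = h * f(t + h / 2.0, y + k2 / 2.0)
    k4 = h * f(t + h, y + k3)
    return y + (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0


_STAGES = ("K1", "K2", "K3", "K4")


def _rk4_step_array(y: np.ndarray, h: float, params: ModelParams) -> np.ndarray:
    # The field is autonomous, so the stage times never enter f.
    stages: list[np.ndarray] = []
    increments = (None, 0.5, 0.5, 1.0)
    with np.errstate(over="ignore", invalid="ignore"):
        for name, frac in zip(_STAGES, increments):
            y_stage = y if frac is None else y + frac * stages[-1]
            k = h * _rhs_array(y_stage, params)
            if not np.all(np.isfinite(k)):
                raise FloatingPointError(f"non-finite RK4 stage {name}")
            stages.append(k)
    k1, k2, k3, k4 = stages
    return y + (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0


def rk4_step(state: State, t: float, h: float, params: ModelParams) -> State:
    """One RK4 step of the SIT1T2R system.  ``t`` is carried for the
    grid only — the field is autonomous."""
    if not (h > 0) or not math.isfinite(h):
        raise ValueError(f"step size h must be positive and finite, got {h!r}")
    y = state.to_array() if isinstance(state, State) else np.asarray(state, float)
    return State.from_array(_rk4_step_array(y, h, params))


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus one state per node, with summary accessors.

    ``completed`` is False when the run hit a non-finite stage;
    ``error_index`` then holds the index of the last valid node and
    ``values`` is truncated there (a partial trajectory).
    """

    grid: TimeGrid
    params: ModelParams
    values: np.ndarray  # shape (n_nodes, 6), COMPARTMENTS order
    completed: bool = True
    error_index: int | None = None

    @property
    def t(self) -> np.ndarray:
        return self.grid.times()[: self.values.shape[0]]

    @property
    def states(self) -> list[State]:
        return [State.from_array(row) for row in self.values]

    def component(self, name: str) -> np.ndarray:
        return self.values[:, COMPARTMENTS.index(name)]

    def conservation_defect(self) -> np.ndarray:
        """N − (S + I + T1 + T2 + R) at every node."""
        v = self.values
        return v[:, 4] - (v[:, 0] + v[:, 1] + v[:, 2] + v[:, 3] + v[:, 5])

    def max_conservation_defect(self) -> float:
        return float(np.max(np.abs(self.conservation_defect())))

    def negative_crossings(self) -> dict[str, float]:
        """First time each compartment goes negative, if ever."""
        out: dict[str, float] = {}
        t = self.t
        for k, name in enumerate(COMPARTMENTS):
            neg = np.nonzero(self.values[:, k] < 0)[0]
            if neg.size:
                out[name] = float(t[neg[0]])
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(COMPARTMENTS))
        df.insert(0, "t", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def integrate(initial: State, grid: TimeGrid, params: ModelParams) -> Trajectory:
    """Run M sequential RK4 steps over the grid.

    The trajectory is returned complete even if compartments go negative
    (inspect :meth:`Trajectory.negative_crossings`).  If a stage
    overflows to non-finite values mid-run the partial trajectory up to
    the last valid node is returned with ``completed=False`` and the
    ``error_index`` set.
    """
    y = initial.to_array() if isinstance(initial, State) else np.asarray(initial, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("initial state must be finite")
    h = grid.h
    rows = np.empty((grid.M + 1, 6))
    rows[0] = y
    for j in range(grid.M):
        try:
            y = _rk4_step_array(y, h, params)
        except FloatingPointError:
            return Trajectory(grid=grid, params=params, values=rows[: j + 1].copy(),
                              completed=False, error_index=j)
        if not np.all(np.isfinite(y)):
            return Trajectory(grid=grid, params=params, values=rows[: j + 1].copy(),
                              completed=False, error_index=j)
        rows[j + 1] = y
    return Trajectory(grid=grid, params=params, values=rows)


def summarize(traj: Trajectory, trailing_fraction: float = 0.1) -> pd.DataFrame:
    """Per-compartment minimum, time of minimum, final value and trend.

    The time of minimum is the *first* attainment on the grid (ties
    break to the earliest node).  ``trailing_increasing`` reports
    whether the compartment is increasing over the last
    ``trailing_fraction`` of the grid — "an incremental mode at the end
    of the cycle" — measured as final value strictly above the value at
    the start of that window.
    """
    t = traj.t
    n = traj.values.shape[0]
    tail_start = min(n - 1, int(math.floor((1.0 - trailing_fraction) * (n - 1))))
    records = []
    for k, name in enumerate(COMPARTMENTS):
        series = traj.values[:, k]
        imin = int(np.argmin(series))  # argmin returns the first minimizer
        records.append(
            {
                "compartment": name,
                "min": float(series[imin]),
                "t_min": float(t[imin]),
                "final": float(series[-1]),
                "trailing_increasing": bool(series[-1] > series[tail_start]),
            }
        )
    return pd.DataFrame.from_records(records)
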