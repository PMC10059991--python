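"""Insulin and carbohydrate absorption signals on the CGM grid.

Discrete dosing/meal events are converted to the continuous covariates
the forecasting models consume:

* **Insulin** — a linear two-compartment subcutaneous absorption chain
  feeding plasma insulin concentration I(t) [mU/L]:

      dS1/dt = U(t) - S1/t_max_I
      dS2/dt = (S1 - S2)/t_max_I
      dI/dt  = S2/(V_I * t_max_I) - k_e * I

  Boluses are impulses added to S1; the basal infusion is the
  piecewise-constant input U(t) [mU/min].  Being linear, the system obeys
  superposition, and each 5-minute step is propagated with the *exact*
  discrete update (matrix exponential), not an Euler approximation, so
  there is no step-size error to tune.

* **Carbohydrate** — the gut absorption kernel for a meal of Dg grams at
  time t0:

      C(t) = Dg * A_g * (t - t0) * exp(-(t - t0)/t_max) / t_max**2

  which peaks at lag t_max and integrates to Dg * A_g (bioavailable
  mass); overlapping meals sum, and C is zero before each meal.

V_I is a per-kilogram distribution volume; signals are treated as per-kg
concentrations (weight = 1 by default) since the evolved models only
need a consistent covariate scale — an explicit ``weight`` parameter is
exposed for users who want absolute concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .series import EventRecord


@dataclass(frozen=True)
class AbsorptionParams:
    """Absorption constants (standard two-compartment values).

    t_max_I : time-to-maximum insulin absorption [min]
    k_e     : fractional plasma insulin elimination rate [1/min]
    V_I     : insulin distribution volume [L/kg]
    t_max   : time-of-maximum glucose appearance after a meal [min]
    A_g     : carbohydrate bioavailability (dimensionless, <= 1)
    weight  : body weight [kg]; 1 keeps signals on a per-kg scale
    """

    t_max_I: float = 55.0
    k_e: float = 0.138
    V_I: float = 0.12
    t_max: float = 40.0
    A_g: float = 0.8
    weight: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t_max_I", "k_e", "V_I", "t_max", "A_g", "weight"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.A_g > 1:
            raise ValueError("A_g is a bioavailability fraction, must be <= 1")


def _discrete_update(params: AbsorptionParams, dt: float):
    """Exact one-step propagators (Ad, Bd) for the linear insulin chain."""
    tm, ke, vol = params.t_max_I, params.k_e, params.V_I * params.weight
    A = np.array([
        [-1.0 / tm, 0.0, 0.0],
        [1.0 / tm, -1.0 / tm, 0.0],
        [0.0, 1.0 / (vol * tm), -ke],
    ])
    B = np.array([[1.0], [0.0], [0.0]])
    aug = np.zeros((4, 4))
    aug[:3, :3] = A
    aug[:3, 3:] = B
    M = expm(aug * dt)
    return M[:3, :3], M[:3, 3]


def insulin_signal(insulin_events: list[EventRecord],
                   params: AbsorptionParams,
                   grid: np.ndarray) -> np.ndarray:
    """Plasma insulin concentration I(t) [mU/L] on the grid.

    ``bolus`` events (mU) are impulses into S1 at their timestamp;
    ``basal`` events set the infusion rate U(t) [mU/min] from their
    timestamp onward.  Events must already be aligned to the grid.
    Initial state is S1 = S2 = I = 0.
    """
    grid = np.asarray(grid, dtype=np.int64)
    if len(grid) == 0:
        return np.zeros(0)
    for ev in insulin_events:
        if ev.kind not in ("bolus", "basal"):
            raise ValueError(f"insulin_signal got event of kind {ev.kind!r}")
        if ev.value < 0:
            raise ValueError("negative dose")

    on_grid = set(int(t) for t in grid)
    boluses: dict[int, float] = {}
    basal_changes: dict[int, float] = {}
    for ev in insulin_events:
        if ev.timestamp not in on_grid:
            raise ValueError(
                f"event at t={ev.timestamp} is not on the grid; "
                "run align_events first")
        if ev.kind == "bolus":
            boluses[ev.timestamp] = boluses.get(ev.timestamp, 0.0) + ev.value
        else:
            basal_changes[ev.timestamp] = ev.value

    dt = float(grid[1] - grid[0]) if len(grid) > 1 else 5.0
    Ad, Bd = _discrete_update(params, dt)

    x = np.zeros(3)
    out = np.empty(len(grid))
    rate = 0.0
    for i, t in enumerate(grid):
        if int(t) in basal_changes:
            rate = basal_changes[int(t)]
        if int(t) in boluses:
            x[0] += boluses[int(t)]
        out[i] = x[2]
        x = Ad @ x + Bd * rate
    return out


def carb_kernel(lag: np.ndarray, params: AbsorptionParams) -> np.ndarray:
    """Gut absorption response to 1 g of carbohydrate taken at lag 0.

    Peaks at lag t_max with value A_g/(t_max*e); integrates to A_g.
    """
    lag = np.asarray(lag, dtype=float)
    out = params.A_g * lag * np.exp(-lag / params.t_max) / params.t_max ** 2
    return np.where(lag >= 0, out, 0.0)


def carb_signal(meal_events: list[EventRecord],
                params: AbsorptionParams,
                grid: np.ndarray) -> np.ndarray:
    """Summed gut absorption signal C(t) on the grid (zero before meals)."""
    grid = np.asarray(grid, dtype=np.int64)
    out = np.zeros(len(grid), dtype=float)
    for ev in meal_events:
        if ev.kind != "meal":
            raise ValueError(f"carb_signal got event of kind {ev.kind!r}")
        if ev.value < 0:
            raise ValueError("negative meal size")
        out += ev.value * carb_kernel(grid - ev.timestamp, params)
    return out


def align_events(events: list[EventRecord],
                 glucose_timestamps: np.ndarray) -> list[EventRecord]:
    """Snap each event to the nearest glucose reading time.

    Exact midpoints between two readings resolve to the *earlier* one.
    """
    ts = np.asarray(glucose_timestamps, dtype=float)
    if len(ts) == 0:
        raise ValueError("glucose timestamp grid is empty")
    aligned = []
    for ev in events:
        pos = np.searchsorted(ts, ev.timestamp)
        if pos == 0:
            new_t = ts[0]
        elif pos == len(ts):
            new_t = ts[-1]
        else:
            before, after = ts[pos - 1], ts[pos]
            # ties (exact midpoint) go to the earlier reading
            new_t = before if ev.timestamp - before <= after - ev.timestamp else after
        aligned.append(EventRecord(int(new_t), ev.kind, ev.value))
    return aligned
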