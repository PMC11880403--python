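"""Annual simulation of the lake N budget under watershed input reduction.

The dynamic mass balance advances the budget one year at a time. With a
reduction fraction ``b`` applied to the watershed N input of each
preceding year, the update order is fixed:

    loading'  = loading × (1 − b)          (deposition included by default)
    outflow'  = outflow × (1 − b)
    storage'  = max(0, storage + loading' − outflow' − removal)
    removal'  = removal × (loading' + storage') / (loading + storage)

The removal rescaling is the discrete form of the proportionality
between removal and its substrate pool (loading + storage): the ratio
``removal_t / (loading_t + storage_t)`` is conserved exactly along the
trajectory. Using end-of-step loading and storage in the numerator makes
that conservation hold to machine precision by construction.

Concentration is evaluated at integer year ends as
``storage × 1000 / water_volume`` (mg N L⁻¹); the goal year is the first
year at or below the target concentration.

``deposition_constant=True`` restricts the reduction to the river inflow
term — watershed management cannot curb direct atmospheric deposition —
while the default reduces total loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .n_budget import NBudget

__all__ = [
    "ScenarioConfig",
    "Trajectory",
    "SCENARIOS",
    "step",
    "simulate",
    "years_to_goal",
    "goal_years_batch",
    "simulate_batch_states",
]

#: The three named reduction scenarios: low, intermediate, high annual
#: reduction of watershed N input relative to each preceding year.
SCENARIOS = {"SC1": 0.02, "SC2": 0.05, "SC3": 0.10}


@dataclass(frozen=True)
class ScenarioConfig:
    """Reduction schedule and goal for one simulation run.

    ``b`` is the constant annual reduction fraction, or a per-year
    sequence. ``goal_conc`` is the water-quality target (default
    1 mg N L⁻¹). ``horizon`` is the planning deadline used by the
    classification stage (default 20 years, aligned with a 2030 target
    from a data epoch around 2008).
    """

    b: float | Sequence[float] = 0.02
    goal_conc: float = 1.0
    max_years: int = 500
    deposition_constant: bool = False
    horizon: int = 20

    def __post_init__(self) -> None:
        bs = np.atleast_1d(np.asarray(self.b, dtype=float))
        if np.any((bs < 0) | (bs > 1)):
            raise ConfigError("reduction fraction b must lie in [0, 1] every year")
        if not self.goal_conc > 0:
            raise ConfigError("goal concentration must be positive")
        if self.max_years < 1:
            raise ConfigError("max_years must be at least 1")

    def b_at(self, year: int) -> float:
        """Reduction fraction applied in ``year`` (1-based)."""
        if np.ndim(self.b) == 0:
            return float(self.b)
        seq = np.asarray(self.b, dtype=float)
        return float(seq[min(year - 1, len(seq) - 1)])


@dataclass
class Trajectory:
    """Year-indexed budget series for one lake (year 0 = baseline)."""

    lake_id: str
    water_volume: float
    years: np.ndarray
    loading: np.ndarray
    outflow: np.ndarray
    removal: np.ndarray
    storage: np.ndarray
    conc: np.ndarray = field(init=False)
    goal_year: int | None = None

    def __post_init__(self) -> None:
        self.conc = self.storage * 1000.0 / self.water_volume

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lake_id": self.lake_id,
                "year": self.years,
                "loading": self.loading,
                "outflow": self.outflow,
                "removal": self.removal,
                "storage": self.storage,
                "conc": self.conc,
            }
        )


def step(
    state: tuple[float, float, float, float],
    b_t: float,
    deposition: float = 0.0,
    deposition_constant: bool = False,
) -> tuple[float, float, float, float]:
    """Advance ``(loading, outflow, removal, storage)`` by one year.

    ``deposition`` is only consulted when ``deposition_constant`` is
    true, in which case the reduction applies to the inflow component
    alone and the deposition term persists unreduced.
    """
    loading, outflow, removal, storage = state
    if not 0.0 <= b_t <= 1.0:
        raise ConfigError(f"b must lie in [0, 1], got {b_t}")
    if deposition_constant:
        loading_next = (loading - deposition) * (1.0 - b_t) + deposition
    else:
        loading_next = loading * (1.0 - b_t)
    outflow_next = outflow * (1.0 - b_t)
    storage_next = max(0.0, storage + loading_next - outflow_next - removal)
    denom = loading + storage
    if denom > 0:
        # grouped so an unchanged substrate pool rescales by exactly 1.0
        removal_next = removal * ((loading_next + storage_next) / denom)
    else:
        removal_next = 0.0
    return loading_next, outflow_next, removal_next, storage_next


def simulate(
    budget: NBudget,
    scenario: ScenarioConfig,
    stop_at_goal: bool = True,
) -> Trajectory:
    """Run the annual loop from the assembled baseline budget.

    Stops at the first year whose end-of-year concentration is at or
    below the goal (unless ``stop_at_goal`` is false, in which case the
    full ``max_years`` series is produced). ``goal_year`` is None when
    the goal is not reached within ``max_years``.
    """
    wv = budget.water_volume
    goal_storage = scenario.goal_conc * wv / 1000.0
    state = (budget.loading, budget.outflow, budget.removal_flux, budget.storage)
    series = [state]
    goal_year: int | None = 0 if state[3] <= goal_storage else None
    t = 0
    while t < scenario.max_years and not (stop_at_goal and goal_year is not None):
        t += 1
        state = step(
            state,
            scenario.b_at(t),
            deposition=budget.loading_deposition,
            deposition_constant=scenario.deposition_constant,
        )
        series.append(state)
        if goal_year is None and state[3] <= goal_storage:
            goal_year = t
    arr = np.asarray(series, dtype=float)
    return Trajectory(
        lake_id=budget.lake_id,
        water_volume=wv,
        years=np.arange(arr.shape[0]),
        loading=arr[:, 0],
        outflow=arr[:, 1],
        removal=arr[:, 2],
        storage=arr[:, 3],
        goal_year=goal_year,
    )


def years_to_goal(budget: NBudget, b: float, scenario: ScenarioConfig) -> int | None:
    """First year at or below the goal under constant reduction ``b``.

    Thin wrapper over :func:`simulate` with the scenario's ``b``
    replaced; returns None when the goal is not reached in
    ``max_years``.
    """
    sc = ScenarioConfig(
        b=b,
        goal_conc=scenario.goal_conc,
        max_years=scenario.max_years,
        deposition_constant=scenario.deposition_constant,
        horizon=scenario.horizon,
    )
    return simulate(budget, sc).goal_year


# ---------------------------------------------------------------------------
# vectorised forms (one numpy op per year across all lakes)


def _batch_step(loading, outflow, removal, storage, b, deposition, deposition_constant):
    if deposition_constant:
        loading_next = (loading - deposition) * (1.0 - b) + deposition
    else:
        loading_next = loading * (1.0 - b)
    outflow_next = outflow * (1.0 - b)
    storage_next = np.maximum(0.0, storage + loading_next - outflow_next - removal)
    denom = loading + storage
    removal_next = np.where(
        denom > 0,
        removal * ((loading_next + storage_next) / np.where(denom > 0, denom, 1.0)),
        0.0,
    )
    return loading_next, outflow_next, removal_next, storage_next


def goal_years_batch(budgets: pd.DataFrame, b, scenario: ScenarioConfig) -> np.ndarray:
    """Goal year per lake over a budgets table; NaN = not reached.

    ``b`` is a scalar or a per-lake array. Equivalent to calling
    :func:`years_to_goal` per row, but loops over years only.
    """
    n = len(budgets)
    loading = budgets["loading"].to_numpy(dtype=float).copy()
    outflow = budgets["outflow"].to_numpy(dtype=float).copy()
    removal = budgets["removal_flux"].to_numpy(dtype=float).copy()
    storage = budgets["storage"].to_numpy(dtype=float).copy()
    deposition = budgets["loading_deposition"].to_numpy(dtype=float)
    wv = budgets["water_volume"].to_numpy(dtype=float)
    goal_storage = scenario.goal_conc * wv / 1000.0
    b = np.broadcast_to(np.asarray(b, dtype=float), (n,))

    years = np.full(n, np.nan)
    done = storage <= goal_storage
    years[done] = 0
    for t in range(1, scenario.max_years + 1):
        if done.all():
            break
        loading, outflow, removal, storage = _batch_step(
            loading, outflow, removal, storage, b, deposition, scenario.deposition_constant
        )
        newly = (~done) & (storage <= goal_storage)
        years[newly] = t
        done |= newly
    return years


def simulate_batch_states(
    budgets: pd.DataFrame, b, years: int, scenario: ScenarioConfig
) -> dict[str, np.ndarray]:
    """State vectors after exactly ``years`` annual steps, per lake."""
    n = len(budgets)
    loading = budgets["loading"].to_numpy(dtype=float).copy()
    outflow = budgets["outflow"].to_numpy(dtype=float).copy()
    removal = budgets["removal_flux"].to_numpy(dtype=float).copy()
    storage = budgets["storage"].to_numpy(dtype=float).copy()
    deposition = budgets["loading_deposition"].to_numpy(dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), (n,))
    for _ in range(years):
        loading, outflow, removal, storage = _batch_step(
            loading, outflow, removal, storage, b, deposition, scenario.deposition_constant
        )
    return {"loading": loading, "outflow": outflow, "removal": removal, "storage": storage}
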