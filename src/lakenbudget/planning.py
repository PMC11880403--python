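"""Management planning: inverse solving, lake classification, efficiency.

Three questions are answered per lake:

* what constant annual watershed-input reduction ``b`` reaches the
  water-quality goal within a deadline (bisection on the monotone
  goal-year response);
* which management type the lake belongs to — Type I needs no action
  (goal already met, or removal ratio > 1 so the lake self-purifies),
  Type II can reach the goal within the planning horizon with some
  feasible reduction, Type III cannot even with a 100% reduction;
* how efficiently a loading reduction converts into a storage (water
  quality) improvement, and the cumulative improvement curve obtained by
  targeting the most efficient watersheds first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .n_budget import NBudget, budget_from_row
from .trajectory_sim import (
    SCENARIOS,
    ScenarioConfig,
    Trajectory,
    goal_years_batch,
    simulate,
    simulate_batch_states,
    years_to_goal,
)

__all__ = [
    "ManagementPlan",
    "INFEASIBLE",
    "required_reduction",
    "required_reduction_batch",
    "classify_lake",
    "classify_batch",
    "improvement_efficiency",
    "cumulative_improvement_curve",
    "make_plans",
]

#: Sentinel for "no constant reduction, not even 100%, meets the deadline".
INFEASIBLE = math.inf

#: Bisection tolerance on b and the iteration cap.
B_TOL = 1e-4
_MAX_BISECT = 32

LAKE_TYPES = ("I_meets_goal", "I_self_purifying", "II", "III")


@dataclass
class ManagementPlan:
    """Per-lake management summary."""

    lake_id: str
    lake_type: str
    required_b: float  # INFEASIBLE (inf) for Type III at the horizon
    required_nani_reduction: float  # first-year NANI intensity decrement, kg N km⁻² yr⁻¹
    goal_year_at_scenarios: dict[str, int | None] = field(default_factory=dict)
    improvement_efficiency: float | None = None


def _scenario_with(scenario: ScenarioConfig, **kw) -> ScenarioConfig:
    base = dict(
        b=scenario.b,
        goal_conc=scenario.goal_conc,
        max_years=scenario.max_years,
        deposition_constant=scenario.deposition_constant,
        horizon=scenario.horizon,
    )
    base.update(kw)
    return ScenarioConfig(**base)


def required_reduction(
    budget: NBudget, deadline: int, scenario: ScenarioConfig
) -> float:
    """Smallest constant annual ``b`` reaching the goal within ``deadline``.

    Bisection on [0, 1] to tolerance 1e-4, exploiting that the goal year
    is non-increasing in ``b``. Returns 0 when no reduction is needed
    (goal already met, or a self-purifying lake that drifts to the goal
    unaided within the deadline) and :data:`INFEASIBLE` when even a full
    reduction (b = 1) misses the deadline.
    """
    if deadline < 1:
        raise InputError("deadline must be at least 1 year")
    sc = _scenario_with(scenario, max_years=deadline)

    def reaches(b: float) -> bool:
        return years_to_goal(budget, b, sc) is not None

    if budget.conc <= scenario.goal_conc or reaches(0.0):
        return 0.0
    if not reaches(1.0):
        return INFEASIBLE
    lo, hi = 0.0, 1.0  # lo fails, hi succeeds
    for _ in range(_MAX_BISECT):
        if hi - lo <= B_TOL:
            break
        mid = 0.5 * (lo + hi)
        if reaches(mid):
            hi = mid
        else:
            lo = mid
    return hi


def required_reduction_batch(
    budgets: pd.DataFrame, deadline: int, scenario: ScenarioConfig
) -> np.ndarray:
    """Vectorised :func:`required_reduction` over a budgets table.

    Runs the same bisection for all lakes simultaneously, one simulated
    year being one numpy operation. Returns an array with ``inf`` for
    infeasible lakes.
    """
    if deadline < 1:
        raise InputError("deadline must be at least 1 year")
    n = len(budgets)
    sc = _scenario_with(scenario, max_years=deadline)

    def reaches(b_vec: np.ndarray) -> np.ndarray:
        return ~np.isnan(goal_years_batch(budgets, b_vec, sc))

    at_goal = budgets["storage"].to_numpy() * 1000.0 / budgets["water_volume"].to_numpy() <= scenario.goal_conc
    ok0 = reaches(np.zeros(n))
    ok1 = reaches(np.ones(n))
    out = np.full(n, np.nan)
    out[at_goal | ok0] = 0.0
    out[~ok1 & ~(at_goal | ok0)] = INFEASIBLE

    active = np.isnan(out)
    lo = np.zeros(n)
    hi = np.ones(n)
    for _ in range(_MAX_BISECT):
        if not active.any() or np.all(hi[active] - lo[active] <= B_TOL):
            break
        mid = 0.5 * (lo + hi)
        ok = reaches(mid)
        hi = np.where(active & ok, mid, hi)
        lo = np.where(active & ~ok, mid, lo)
    out[active] = hi[active]
    return out


def classify_lake(
    budget: NBudget, scenario: ScenarioConfig, sdg_horizon: int = 20
) -> str:
    """Assign the management type of one lake.

    Decision flow: goal already met → ``I_meets_goal``; removal ratio
    strictly above 1 → ``I_self_purifying`` (water quality improves with
    no action); otherwise ``II`` when some constant reduction reaches
    the goal within ``sdg_horizon`` years, else ``III``. A lake with
    zero loading has an undefined ratio and cannot be classified.
    """
    if budget.conc <= scenario.goal_conc:
        return "I_meets_goal"
    if math.isnan(budget.removal_ratio):
        raise InputError(f"lake {budget.lake_id}: removal ratio undefined (zero loading)")
    if budget.removal_ratio > 1.0:
        return "I_self_purifying"
    if math.isfinite(required_reduction(budget, sdg_horizon, scenario)):
        return "II"
    return "III"


def classify_batch(
    budgets: pd.DataFrame, scenario: ScenarioConfig, sdg_horizon: int = 20
) -> pd.Series:
    """Vectorised classification; NaN-ratio lakes get type 'undefined'."""
    conc = budgets["storage"].to_numpy() * 1000.0 / budgets["water_volume"].to_numpy()
    ratio = budgets["removal_ratio"].to_numpy(dtype=float)
    sc = _scenario_with(scenario, max_years=sdg_horizon)
    feasible = ~np.isnan(goal_years_batch(budgets, 1.0, sc))
    types = np.where(
        conc <= scenario.goal_conc,
        "I_meets_goal",
        np.where(
            np.isnan(ratio),
            "undefined",
            np.where(ratio > 1.0, "I_self_purifying", np.where(feasible, "II", "III")),
        ),
    )
    return pd.Series(types, index=budgets.index, name="lake_type")


def improvement_efficiency(trajectory: Trajectory, horizon: int) -> float:
    """Storage reduction achieved per unit loading reduction over ``horizon``.

    ``(storage_0 − storage_h) / (loading_0 − loading_h)``; dimensionless.
    Undefined (raises) when the loading did not decrease, e.g. b = 0.
    """
    if horizon < 1 or horizon >= len(trajectory.years):
        raise InputError("horizon must lie within the simulated trajectory")
    dl = trajectory.loading[0] - trajectory.loading[horizon]
    if dl <= 0:
        raise InputError("improvement efficiency undefined: loading did not decrease")
    return (trajectory.storage[0] - trajectory.storage[horizon]) / dl


def cumulative_improvement_curve(
    plans: list[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative storage improvement as loading reductions are targeted
    at the most efficient lakes first.

    ``plans`` holds per-lake ``(loading_reduction, storage_reduction)``
    pairs. Lakes are sorted by efficiency (storage/loading reduction)
    descending; running sums are normalised by the totals. The curve
    starts at (0, 0), ends at (1, 1), is non-decreasing and concave, and
    coincides with the diagonal when all efficiencies are equal.
    """
    if len(plans) == 0:
        raise InputError("cumulative curve needs at least one lake")
    arr = np.asarray(plans, dtype=float)
    lr, sr = arr[:, 0], arr[:, 1]
    if np.any(lr < 0) or np.any(sr < 0):
        raise InputError("reductions must be non-negative")
    if lr.sum() <= 0 or sr.sum() <= 0:
        raise InputError("total reductions must be positive")
    with np.errstate(divide="ignore"):
        eff = np.where(lr > 0, sr / np.where(lr > 0, lr, 1.0), np.inf)
    order = np.argsort(-eff, kind="stable")
    x = np.concatenate([[0.0], np.cumsum(lr[order]) / lr.sum()])
    y = np.concatenate([[0.0], np.cumsum(sr[order]) / sr.sum()])
    return x, y


def make_plans(
    budgets: pd.DataFrame,
    scenario: ScenarioConfig,
    deadlines: tuple[int, ...] = (10, 20, 30, 40),
    sdg_horizon: int = 20,
    efficiency_b: float = SCENARIOS["SC2"],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full planning sweep over a budgets table.

    Returns ``(plans, types)``. ``plans`` has one row per lake per
    deadline with the required reduction and its NANI-intensity
    equivalent (first-year decrement ``b × nani_intensity``); ``types``
    has one row per lake with the classification, the goal years under
    the three named scenarios, and the improvement efficiency evaluated
    at the intermediate scenario over the planning horizon.
    """
    rows = []
    for d in deadlines:
        req = required_reduction_batch(budgets, d, scenario)
        nani = budgets["nani_intensity"].to_numpy(dtype=float) if "nani_intensity" in budgets else np.full(len(budgets), np.nan)
        finite_req = np.where(np.isinf(req), 0.0, req)
        rows.append(
            pd.DataFrame(
                {
                    "lake_id": budgets["lake_id"].to_numpy(),
                    "deadline": d,
                    "required_b": req,
                    "required_nani_reduction": np.where(
                        np.isinf(req), np.inf, finite_req * np.maximum(nani, 0.0)
                    ),
                }
            )
        )
    plans = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    types = pd.DataFrame({"lake_id": budgets["lake_id"].to_numpy()})
    types["lake_type"] = classify_batch(budgets, scenario, sdg_horizon).to_numpy()
    for name, b in SCENARIOS.items():
        types[f"goal_year_{name}"] = goal_years_batch(budgets, b, scenario)
    end = simulate_batch_states(budgets, efficiency_b, sdg_horizon, scenario)
    dl = budgets["loading"].to_numpy() - end["loading"]
    ds = budgets["storage"].to_numpy() - end["storage"]
    with np.errstate(divide="ignore", invalid="ignore"):
        types["improvement_efficiency"] = np.where(dl > 0, ds / np.where(dl > 0, dl, 1.0), np.nan)
    types["loading_reduction"] = np.maximum(dl, 0.0)
    types["storage_reduction"] = np.maximum(ds, 0.0)
    return plans, types
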