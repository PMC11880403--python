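"""Monte Carlo propagation of input uncertainty through the budget chain.

Three inputs carry quantified uncertainty: the chlorophyll-a / water
temperature matchup feeding the removal model, and the river loading
coefficient *a*. Per draw, chlorophyll-a is perturbed multiplicatively
with a mean-one lognormal factor (strictly positive, right-skewed, a
natural error model for a skewed concentration variable), temperature
additively with a zero-mean normal, and *a* is drawn uniformly over its
literature range (0.3–0.5 by default). Each draw re-runs the full
budget → simulate → invert chain; central 95% intervals are the
2.5th/97.5th percentiles of the draw vector.

Draws are deterministic given ``(seed, draw_index, lake_id)``, so runs
reproduce bit-identically and lakes can be processed in any order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .n_budget import LakeRecord, assemble_budget
from .planning import INFEASIBLE, required_reduction
from .removal_model import RemovalModelParams, wt_from_latitude
from .trajectory_sim import ScenarioConfig, years_to_goal

__all__ = ["UncertaintySpec", "IntervalResult", "sample_inputs", "monte_carlo", "monte_carlo_table"]

QUANTITIES = ("removal_flux", "loading", "goal_year", "required_b")


@dataclass(frozen=True)
class UncertaintySpec:
    """Distributions and size of the Monte Carlo ensemble.

    chla_cv is the relative (coefficient-of-variation) error of the
    chlorophyll-a retrieval; wt_sd the additive temperature error in °C.
    Defaults (0.2, 1.0) are typical matchup errors for satellite-derived
    lake products.
    """

    n_draws: int = 1000
    a_low: float = 0.3
    a_high: float = 0.5
    chla_cv: float = 0.2
    wt_sd: float = 1.0
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ConfigError("n_draws must be at least 2")
        if not 0.0 <= self.a_low <= self.a_high <= 1.0:
            raise ConfigError("need 0 <= a_low <= a_high <= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.chla_cv < 0 or self.wt_sd < 0:
            raise ConfigError("error scales must be non-negative")


@dataclass(frozen=True)
class IntervalResult:
    """Point estimate plus central credible interval for one quantity.

    ``point`` comes from the unperturbed central-parameter run and need
    not lie inside [lo, hi]. ``undefined_freq`` is the fraction of draws
    where the quantity was undefined (goal not reached / reduction
    infeasible); such draws are excluded from the percentiles, and when
    all draws are undefined lo and hi are NaN.
    """

    lake_id: str
    quantity: str
    point: float
    lo: float
    hi: float
    undefined_freq: float = 0.0


def _rng_for(spec: UncertaintySpec, draw_index: int, lake_id: str) -> np.random.Generator:
    tag = zlib.crc32(str(lake_id).encode("utf-8"))
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, draw_index, tag])


def sample_inputs(
    record: LakeRecord, spec: UncertaintySpec, draw_index: int
) -> tuple[float, float, float]:
    """One perturbed ``(chla, wt, a)`` triple, deterministic per draw.

    The chlorophyll factor is lognormal with mean exactly 1 and
    coefficient of variation ``chla_cv``; zero error scales reproduce
    the inputs exactly.
    """
    rng = _rng_for(spec, draw_index, record.lake_id)
    if spec.chla_cv > 0:
        sigma2 = math.log1p(spec.chla_cv**2)
        chla = record.chla * rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2))
    else:
        chla = record.chla
    wt0 = record.wt
    if wt0 is None or (isinstance(wt0, float) and math.isnan(wt0)):
        raise ConfigError("record needs a resolved water temperature before sampling")
    wt = wt0 + rng.normal(0.0, spec.wt_sd) if spec.wt_sd > 0 else wt0
    a = rng.uniform(spec.a_low, spec.a_high) if spec.a_high > spec.a_low else spec.a_low
    return float(chla), float(wt), float(a)


def _resolve_wt(record: LakeRecord, params: RemovalModelParams) -> LakeRecord:
    wt = record.wt
    if wt is None or (isinstance(wt, float) and math.isnan(wt)):
        return replace(record, wt=wt_from_latitude(record.latitude, params))
    return record


def _interval(draws: np.ndarray, spec: UncertaintySpec) -> tuple[float, float]:
    alpha = (1.0 - spec.ci_level) / 2.0
    return (
        float(np.quantile(draws, alpha)),
        float(np.quantile(draws, 1.0 - alpha)),
    )


def monte_carlo(
    record: LakeRecord,
    params: RemovalModelParams,
    scenario: ScenarioConfig,
    spec: UncertaintySpec,
    deadline: int = 20,
    quantities: tuple[str, ...] = QUANTITIES,
) -> list[IntervalResult]:
    """Propagate input uncertainty through the full chain for one lake.

    Per draw the budget is reassembled with the perturbed inputs; when
    requested, the goal year under the scenario's reduction and the
    required reduction for ``deadline`` are recomputed by simulation.
    The point estimate uses the unperturbed inputs with *a* at the
    midpoint of its range.
    """
    unknown = set(quantities) - set(QUANTITIES)
    if unknown:
        raise ConfigError(f"unknown quantities: {sorted(unknown)}")
    record = _resolve_wt(record, params)
    a_mid = 0.5 * (spec.a_low + spec.a_high)
    need_sim = "goal_year" in quantities or "required_b" in quantities

    def evaluate(chla: float, wt: float, a: float) -> dict[str, float]:
        b = assemble_budget(replace(record, chla=chla, wt=wt), params, a)
        out = {"removal_flux": b.removal_flux, "loading": b.loading}
        if need_sim:
            if "goal_year" in quantities:
                y = years_to_goal(b, float(np.atleast_1d(scenario.b)[0]), scenario)
                out["goal_year"] = math.nan if y is None else float(y)
            if "required_b" in quantities:
                r = required_reduction(b, deadline, scenario)
                out["required_b"] = math.nan if r == INFEASIBLE else r
        return out

    point = evaluate(record.chla, record.wt, a_mid)
    draws: dict[str, list[float]] = {q: [] for q in quantities}
    for i in range(spec.n_draws):
        vals = evaluate(*sample_inputs(record, spec, i))
        for q in quantities:
            draws[q].append(vals[q])

    results = []
    for q in quantities:
        vec = np.asarray(draws[q], dtype=float)
        defined = vec[~np.isnan(vec)]
        freq = 1.0 - defined.size / vec.size
        if defined.size:
            lo, hi = _interval(defined, spec)
        else:
            lo = hi = math.nan
        results.append(
            IntervalResult(
                lake_id=record.lake_id,
                quantity=q,
                point=point[q],
                lo=lo,
                hi=hi,
                undefined_freq=freq,
            )
        )
    return results


def monte_carlo_table(
    lakes: pd.DataFrame,
    params: RemovalModelParams,
    scenario: ScenarioConfig,
    spec: UncertaintySpec,
    deadline: int = 20,
    quantities: tuple[str, ...] = QUANTITIES,
    max_lakes: int | None = None,
) -> pd.DataFrame:
    """Interval table over (optionally the first ``max_lakes`` of) a
    lakes frame; lakes that fail budget assembly are skipped."""
    from .errors import InputError, LakeNotApplicable

    rows = []
    subset = lakes if max_lakes is None else lakes.head(max_lakes)
    for _, r in subset.iterrows():
        try:
            rec = _record_from_row(r)
            for res in monte_carlo(rec, params, scenario, spec, deadline, quantities):
                rows.append(res.__dict__)
        except (ValueError, TypeError, LakeNotApplicable, InputError):
            continue
    return pd.DataFrame(
        rows, columns=["lake_id", "quantity", "point", "lo", "hi", "undefined_freq"]
    )


def _record_from_row(r) -> LakeRecord:
    rec = LakeRecord(
        lake_id=str(r["lake_id"]),
        latitude=float(r["latitude"]),
        longitude=float(r["longitude"]),
        surface_area=float(r["surface_area"]),
        mean_depth=float(r["mean_depth"]),
        water_volume=float(r["water_volume"]),
        chla=float(r["chla"]),
        wt=None if pd.isna(r["wt"]) else float(r["wt"]),
        tn_conc=float(r["tn_conc"]),
        nani_intensity=float(r["nani_intensity"]),
        watershed_area=float(r["watershed_area"]),
        deposition_rate=float(r["deposition_rate"]),
    )
    rec.validate()
    return rec
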