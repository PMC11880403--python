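"""Steady-state nitrogen budget assembly for individual lakes.

A lake's annual N budget balances loading against outputs:

    loading  = inflow (NANI × watershed area × a) + direct deposition
    outflow  = max(loading − removal, 0)
    removal  = areal removal rate × surface area
    storage  = concentration × water volume

The removal ratio (removal / loading) may exceed 1: such lakes remove
more N than they receive and drain their standing stock — the
"self-purifying" regime. In that regime the steady-state outflow is
clamped at zero and the surplus removal is interpreted as net storage
drawdown, which the dynamic simulator resolves explicitly.

All masses are kg N; concentrations in mg N L⁻¹ (= g N m⁻³) convert to
storage via ``conc × volume / 1000``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, LakeNotApplicable
from .removal_model import (
    RemovalModelParams,
    areal_removal_rate,
    is_applicable,
    wt_from_latitude,
)

__all__ = [
    "LakeRecord",
    "NBudget",
    "LAKE_COLUMNS",
    "loading_inflow",
    "loading_deposition",
    "removal_flux",
    "removal_ratio",
    "assemble_budget",
    "assemble_budgets",
    "read_lakes_csv",
    "write_budgets_csv",
]

#: Required columns of a lakes CSV, one row per lake. ``wt`` may be empty
#: (estimated from latitude); everything else must parse as a number.
LAKE_COLUMNS = [
    "lake_id",
    "latitude",
    "longitude",
    "surface_area",
    "mean_depth",
    "water_volume",
    "chla",
    "wt",
    "tn_conc",
    "nani_intensity",
    "watershed_area",
    "deposition_rate",
]


@dataclass(frozen=True)
class LakeRecord:
    """Raw observable attributes of one lake and its watershed.

    Units: surface_area and watershed_area km²; mean_depth m;
    water_volume m³; chla µg L⁻¹; wt °C (None when unobserved);
    tn_conc mg N L⁻¹; nani_intensity and deposition_rate kg N km⁻² yr⁻¹.
    nani_intensity may be negative (net-export watershed).
    """

    lake_id: str
    latitude: float
    longitude: float
    surface_area: float
    mean_depth: float
    water_volume: float
    chla: float
    wt: float | None
    tn_conc: float
    nani_intensity: float
    watershed_area: float
    deposition_rate: float

    def validate(self) -> None:
        if not (self.surface_area > 0 and self.mean_depth > 0 and self.water_volume > 0):
            raise InputError(f"lake {self.lake_id}: geometry must be positive")
        if self.watershed_area < self.surface_area:
            raise InputError(f"lake {self.lake_id}: watershed area smaller than lake area")
        if self.tn_conc < 0 or self.chla < 0 or self.deposition_rate < 0:
            raise InputError(f"lake {self.lake_id}: negative concentration or deposition")
        if abs(self.latitude) > 90:
            raise InputError(f"lake {self.lake_id}: latitude out of range")


@dataclass(frozen=True)
class NBudget:
    """Assembled steady-state budget of one lake (kg N, kg N yr⁻¹).

    ``water_volume`` (m³) is carried alongside the mass terms because
    every concentration evaluation downstream needs it.
    ``removal_ratio`` is NaN when loading is zero (undefined).
    """

    lake_id: str
    loading_inflow: float
    loading_deposition: float
    loading: float
    removal_flux: float
    outflow: float
    storage: float
    removal_ratio: float
    a_coeff: float
    water_volume: float

    @property
    def conc(self) -> float:
        """Water-column TN concentration, mg N L⁻¹."""
        return self.storage * 1000.0 / self.water_volume


def loading_inflow(nani_intensity: float, watershed_area: float, a: float) -> float:
    """River + groundwater N load to the lake, kg N yr⁻¹.

    ``max(0, nani_intensity × watershed_area) × a`` — the river loading
    coefficient *a* is the fraction of watershed soil N input that reaches
    the lake (literature range 0.3–0.5). Net-export watersheds (negative
    NANI) contribute zero inflow.
    """
    if not 0.0 <= a <= 1.0:
        raise ConfigError(f"river loading coefficient a must lie in [0, 1], got {a}")
    if watershed_area <= 0:
        raise InputError("watershed area must be positive")
    return max(0.0, nani_intensity * watershed_area) * a


def loading_deposition(deposition_rate: float, surface_area: float) -> float:
    """Direct atmospheric N deposition onto the lake surface, kg N yr⁻¹."""
    if deposition_rate < 0:
        raise InputError("deposition rate must be non-negative")
    return deposition_rate * surface_area


def removal_flux(areal_rate: float, surface_area: float) -> float:
    """Whole-lake permanent N removal, kg N yr⁻¹ (areal rate × area)."""
    if areal_rate < 0:
        raise InputError("areal removal rate must be non-negative")
    return areal_rate * surface_area


def removal_ratio(removal: float, loading: float) -> float:
    """Removal flux as a fraction of loading; NaN when loading is zero.

    Values above 1 are legal and mark the self-purifying regime in which
    stored N, not only incoming N, feeds the removal process.
    """
    if loading < 0:
        raise InputError("loading must be non-negative")
    if loading == 0:
        return math.nan
    return removal / loading


def assemble_budget(record: LakeRecord, params: RemovalModelParams, a: float = 0.4) -> NBudget:
    """Build the steady-state budget for one lake.

    Raises :class:`LakeNotApplicable` for stratified lakes (mean depth
    above the thermocline depth). Water temperature falls back to the
    latitude regression when the record carries none.
    """
    record.validate()
    if not is_applicable(record.mean_depth, record.surface_area, params):
        raise LakeNotApplicable(
            f"lake {record.lake_id}: mean depth exceeds thermocline depth (stratified)"
        )
    wt = record.wt
    if wt is None or (isinstance(wt, float) and math.isnan(wt)):
        wt = wt_from_latitude(record.latitude, params)
    rate = areal_removal_rate(record.chla, wt, params)
    inflow = loading_inflow(record.nani_intensity, record.watershed_area, a)
    dep = loading_deposition(record.deposition_rate, record.surface_area)
    loading = inflow + dep
    removal = removal_flux(rate, record.surface_area)
    outflow = max(loading - removal, 0.0)
    storage = record.tn_conc * record.water_volume / 1000.0
    return NBudget(
        lake_id=record.lake_id,
        loading_inflow=inflow,
        loading_deposition=dep,
        loading=loading,
        removal_flux=removal,
        outflow=outflow,
        storage=storage,
        removal_ratio=removal_ratio(removal, loading),
        a_coeff=a,
        water_volume=record.water_volume,
    )


# ---------------------------------------------------------------------------
# table-level assembly


def read_lakes_csv(path) -> pd.DataFrame:
    """Read a lakes CSV, checking the required header."""
    df = pd.read_csv(path)
    missing = [c for c in LAKE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"lakes table missing required columns: {missing}")
    return df


def _row_problem(row: pd.Series) -> str | None:
    """Reason a raw row cannot enter the budget, or None if it can."""
    numeric = [
        "latitude", "longitude", "surface_area", "mean_depth", "water_volume",
        "chla", "tn_conc", "nani_intensity", "watershed_area", "deposition_rate",
    ]
    for col in numeric:
        v = row[col]
        if pd.isna(v) or not np.isfinite(v):
            return f"missing or non-numeric {col}"
    if row["surface_area"] <= 0 or row["mean_depth"] <= 0 or row["water_volume"] <= 0:
        return "non-positive lake geometry"
    if row["watershed_area"] < row["surface_area"]:
        return "watershed area smaller than lake area"
    if row["tn_conc"] < 0 or row["chla"] < 0 or row["deposition_rate"] < 0:
        return "negative concentration or deposition"
    if abs(row["latitude"]) > 90:
        return "latitude out of range"
    return None


def assemble_budgets(
    lakes: pd.DataFrame,
    params: RemovalModelParams,
    a: float = 0.4,
    a_column: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised budget assembly over a lakes table.

    Returns ``(budgets, exclusions)``. Every input row lands in exactly
    one of the two frames: malformed rows and stratified (deep) lakes go
    to ``exclusions`` with a reason; the rest get budgets. The budgets
    frame carries the NBudget fields plus ``water_volume``, ``tn_conc``
    and ``nani_intensity`` so downstream stages need no join back.

    ``a_column`` names an optional per-lake column overriding the scalar
    river loading coefficient ``a``.
    """
    if not 0.0 <= a <= 1.0:
        raise ConfigError(f"river loading coefficient a must lie in [0, 1], got {a}")
    for col in LAKE_COLUMNS:
        if col not in lakes.columns:
            raise InputError(f"lakes table missing required column: {col}")

    df = lakes.copy().reset_index(drop=True)
    coerce = [c for c in LAKE_COLUMNS if c != "lake_id"]
    df[coerce] = df[coerce].apply(pd.to_numeric, errors="coerce")

    reasons = df.apply(_row_problem, axis=1)
    bad = reasons.notna()

    ok = df[~bad].copy()
    excl = [
        {"lake_id": df.loc[i, "lake_id"], "row": int(i), "reason": reasons[i]}
        for i in df.index[bad]
    ]

    if len(ok):
        deep = ~is_applicable(ok["mean_depth"].to_numpy(), ok["surface_area"].to_numpy(), params)
        for i in ok.index[deep]:
            excl.append(
                {"lake_id": ok.loc[i, "lake_id"], "row": int(i),
                 "reason": "stratified: mean depth exceeds thermocline depth"}
            )
        ok = ok[~deep]

    if len(ok) == 0:
        budgets = pd.DataFrame(
            columns=["lake_id", "loading_inflow", "loading_deposition", "loading",
                     "removal_flux", "outflow", "storage", "removal_ratio",
                     "a_coeff", "water_volume", "tn_conc", "nani_intensity"]
        )
    else:
        wt = ok["wt"].to_numpy(dtype=float)
        lat = ok["latitude"].to_numpy(dtype=float)
        wt = np.where(np.isnan(wt), wt_from_latitude(lat, params), wt)
        rate = areal_removal_rate(ok["chla"].to_numpy(), wt, params)
        a_vec = (
            ok[a_column].to_numpy(dtype=float) if a_column is not None
            else np.full(len(ok), a)
        )
        if np.any((a_vec < 0) | (a_vec > 1)):
            raise ConfigError("per-lake river loading coefficients must lie in [0, 1]")
        inflow = np.maximum(0.0, ok["nani_intensity"].to_numpy() * ok["watershed_area"].to_numpy()) * a_vec
        dep = ok["deposition_rate"].to_numpy() * ok["surface_area"].to_numpy()
        loading = inflow + dep
        removal = rate * ok["surface_area"].to_numpy()
        outflow = np.maximum(loading - removal, 0.0)
        storage = ok["tn_conc"].to_numpy() * ok["water_volume"].to_numpy() / 1000.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(loading > 0, removal / np.where(loading > 0, loading, 1.0), np.nan)
        budgets = pd.DataFrame(
            {
                "lake_id": ok["lake_id"].to_numpy(),
                "loading_inflow": inflow,
                "loading_deposition": dep,
                "loading": loading,
                "removal_flux": removal,
                "outflow": outflow,
                "storage": storage,
                "removal_ratio": ratio,
                "a_coeff": a_vec,
                "water_volume": ok["water_volume"].to_numpy(dtype=float),
                "tn_conc": ok["tn_conc"].to_numpy(dtype=float),
                "nani_intensity": ok["nani_intensity"].to_numpy(dtype=float),
            }
        )

    exclusions = pd.DataFrame(excl, columns=["lake_id", "row", "reason"])
    return budgets.reset_index(drop=True), exclusions


def write_budgets_csv(budgets: pd.DataFrame, path) -> None:
    budgets.to_csv(path, index=False)


def budget_from_row(row) -> NBudget:
    """Rehydrate an :class:`NBudget` from one budgets-table row."""
    return NBudget(
        lake_id=str(row["lake_id"]),
        loading_inflow=float(row["loading_inflow"]),
        loading_deposition=float(row["loading_deposition"]),
        loading=float(row["loading"]),
        removal_flux=float(row["removal_flux"]),
        outflow=float(row["outflow"]),
        storage=float(row["storage"]),
        removal_ratio=float(row["removal_ratio"]),
        a_coeff=float(row["a_coeff"]),
        water_volume=float(row["water_volume"]),
    )
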