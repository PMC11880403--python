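"""Areal lake nitrogen removal from chlorophyll-a and water temperature.

The removal model treats denitrification (permanent N₂ loss) as an
additive function of algal biomass and temperature: a quadratic response
to chlorophyll-a — low-level algae supplies substrate and favourable
sediment conditions, excessive algal decay depletes oxygen and inhibits
the nitrification–denitrification couple — plus a linear increase with
water temperature. The model applies to well-mixed lakes only; deep
stratified lakes are screened out by comparing mean depth with the
thermocline depth predicted from surface area.

Units: areal removal rates in kg N km⁻² yr⁻¹, chlorophyll-a in µg L⁻¹,
temperature in °C, surface area in km², depths in m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "RemovalModelParams",
    "areal_removal_rate",
    "thermocline_depth",
    "is_applicable",
    "wt_from_latitude",
]


@dataclass(frozen=True)
class RemovalModelParams:
    """Coefficients of the removal model and its auxiliary regressions.

    The beta defaults are plausible placeholder values on the published
    scale of lake denitrification (a few g N m⁻² yr⁻¹ for eutrophic
    shallow lakes); they are not a fitted parameterisation and any
    quantitative application should supply site-calibrated coefficients
    through a config file.

    Attributes
    ----------
    beta0 : float
        Intercept, kg N km⁻² yr⁻¹.
    beta1 : float
        Linear chlorophyll-a coefficient, kg N km⁻² yr⁻¹ per µg L⁻¹.
    beta2 : float
        Quadratic chlorophyll-a coefficient, kg N km⁻² yr⁻¹ per (µg L⁻¹)²;
        must be negative (unimodal response).
    beta3 : float
        Temperature coefficient, kg N km⁻² yr⁻¹ per °C; must be positive.
    ther_slope, ther_intercept : float
        Constants of the log₁₀–log₁₀ thermocline-depth regression on
        surface area (127-lake empirical fit: slope 0.185, intercept 0.842).
    wt_lat_intercept : float
        Annual mean surface water temperature at the equator, °C.
    wt_lat_slope : float
        Temperature decrease per degree of absolute latitude, °C deg⁻¹.
    """

    beta0: float = 500.0
    beta1: float = 144.0
    beta2: float = -1.2
    beta3: float = 120.0
    ther_slope: float = 0.185
    ther_intercept: float = 0.842
    wt_lat_intercept: float = 28.0
    wt_lat_slope: float = 0.35

    def __post_init__(self) -> None:
        if not self.beta2 < 0:
            raise ConfigError(f"beta2 must be negative (unimodal Chl-a response), got {self.beta2}")
        if not self.beta3 > 0:
            raise ConfigError(f"beta3 must be positive (removal increases with temperature), got {self.beta3}")
        if not self.ther_slope > 0:
            raise ConfigError(f"ther_slope must be positive, got {self.ther_slope}")


def areal_removal_rate(chla, wt, params: RemovalModelParams):
    """Areal N removal rate, kg N km⁻² yr⁻¹.

    ``max(0, beta0 + beta1*chla + beta2*chla**2 + beta3*wt)`` — the
    polynomial's negative tails are clamped to zero since a removal rate
    cannot be negative. Accepts scalars or arrays.
    """
    chla = np.asarray(chla, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if np.any(chla < 0):
        raise InputError("chlorophyll-a concentration must be non-negative")
    if not np.all(np.isfinite(wt)):
        raise InputError("water temperature must be finite")
    rate = params.beta0 + params.beta1 * chla + params.beta2 * chla**2 + params.beta3 * wt
    out = np.maximum(rate, 0.0)
    return float(out) if out.ndim == 0 else out


def thermocline_depth(surface_area, params: RemovalModelParams | None = None):
    """Thermocline depth (m) from lake surface area (km²).

    log₁₀ THER = slope · log₁₀ SA + intercept, with the empirical
    constants 0.185 and 0.842 by default.
    """
    p = params if params is not None else RemovalModelParams()
    sa = np.asarray(surface_area, dtype=float)
    if np.any(sa <= 0):
        raise InputError("surface area must be positive")
    out = 10.0 ** (p.ther_slope * np.log10(sa) + p.ther_intercept)
    return float(out) if out.ndim == 0 else out


def is_applicable(mean_depth, surface_area, params: RemovalModelParams | None = None):
    """True for well-mixed lakes (mean depth ≤ predicted thermocline depth).

    Lakes deeper than the thermocline are stratified — incomplete mixing
    of nutrients, temperature and oxygen — and fall outside the removal
    model's domain. The boundary case (depth exactly equal) is kept.
    """
    depth = np.asarray(mean_depth, dtype=float)
    if np.any(depth <= 0):
        raise InputError("mean depth must be positive")
    out = depth <= thermocline_depth(surface_area, params)
    return bool(out) if out.ndim == 0 else out


def wt_from_latitude(latitude, params: RemovalModelParams):
    """Annual mean surface water temperature (°C) estimated from latitude.

    Clamped linear decline with absolute latitude, symmetric about the
    equator; used as a fallback when no temperature observation exists.
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise InputError("latitude must lie in [-90, 90]")
    out = np.maximum(0.0, params.wt_lat_intercept - params.wt_lat_slope * np.abs(lat))
    return float(out) if out.ndim == 0 else out
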