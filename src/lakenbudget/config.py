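"""Run configuration: plain-text INI (key: value) parsing and validation.

Sections map onto the package's parameter types:

    [removal_model]   all eight coefficients, required as a block
    [budget]          a_coeff
    [scenario]        b, goal_conc, max_years, deposition_constant, horizon
    [uncertainty]     n_draws, a_low, a_high, chla_cv, wt_sd, ci_level
    [run]             seed, deadlines, sdg_horizon, uncertainty_max_lakes,
                      log_level

A missing section falls back to the package defaults, but a *present*
[removal_model] section must spell out every coefficient — partially
specified removal models are rejected rather than silently mixed with
defaults.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .removal_model import RemovalModelParams
from .trajectory_sim import ScenarioConfig
from .uncertainty_mc import UncertaintySpec

__all__ = ["RunConfig", "load_run_config", "removal_params_from_config", "config_hash"]

_REMOVAL_FIELDS = (
    "beta0", "beta1", "beta2", "beta3",
    "ther_slope", "ther_intercept", "wt_lat_intercept", "wt_lat_slope",
)


@dataclass
class RunConfig:
    """Validated bundle of everything one pipeline run needs."""

    params: RemovalModelParams = field(default_factory=RemovalModelParams)
    a_coeff: float = 0.4
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec)
    deadlines: tuple[int, ...] = (10, 20, 30, 40)
    sdg_horizon: int = 20
    seed: int = 0
    uncertainty_max_lakes: int = 25
    log_level: str = "INFO"
    source_text: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_coeff <= 1.0:
            raise ConfigError(f"a_coeff must lie in [0, 1], got {self.a_coeff}")
        if any(d < 1 for d in self.deadlines):
            raise ConfigError("deadlines must be at least 1 year")
        if self.sdg_horizon < 1:
            raise ConfigError("sdg_horizon must be at least 1 year")


def removal_params_from_config(section) -> RemovalModelParams:
    """Build removal-model coefficients from a config section mapping.

    Every one of the eight fields must be present — no silent defaults
    when a config supplies the section.
    """
    missing = [k for k in _REMOVAL_FIELDS if k not in section]
    if missing:
        raise ConfigError(f"[removal_model] missing required fields: {missing}")
    try:
        vals = {k: float(section[k]) for k in _REMOVAL_FIELDS}
    except ValueError as exc:
        raise ConfigError(f"[removal_model] non-numeric coefficient: {exc}") from exc
    return RemovalModelParams(**vals)


def _get(section, key, cast, default):
    if key not in section:
        return default
    raw = section[key]
    try:
        if cast is bool:
            return str(raw).strip().lower() in ("1", "true", "yes", "on")
        return cast(raw)
    except ValueError as exc:
        raise ConfigError(f"bad value for {key!r}: {raw!r}") from exc


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate an INI run config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    cp = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse config: {exc}") from exc

    params = (
        removal_params_from_config(cp["removal_model"])
        if cp.has_section("removal_model")
        else RemovalModelParams()
    )

    bsec = cp["budget"] if cp.has_section("budget") else {}
    a_coeff = _get(bsec, "a_coeff", float, 0.4)

    ssec = cp["scenario"] if cp.has_section("scenario") else {}
    scenario = ScenarioConfig(
        b=_get(ssec, "b", float, 0.02),
        goal_conc=_get(ssec, "goal_conc", float, 1.0),
        max_years=_get(ssec, "max_years", int, 500),
        deposition_constant=_get(ssec, "deposition_constant", bool, False),
        horizon=_get(ssec, "horizon", int, 20),
    )

    usec = cp["uncertainty"] if cp.has_section("uncertainty") else {}
    rsec = cp["run"] if cp.has_section("run") else {}
    seed = _get(rsec, "seed", int, 0)
    uspec = UncertaintySpec(
        n_draws=_get(usec, "n_draws", int, 1000),
        a_low=_get(usec, "a_low", float, 0.3),
        a_high=_get(usec, "a_high", float, 0.5),
        chla_cv=_get(usec, "chla_cv", float, 0.2),
        wt_sd=_get(usec, "wt_sd", float, 1.0),
        seed=seed,
        ci_level=_get(usec, "ci_level", float, 0.95),
    )

    deadlines = tuple(
        int(x) for x in str(_get(rsec, "deadlines", str, "10,20,30,40")).split(",") if x.strip()
    )
    return RunConfig(
        params=params,
        a_coeff=a_coeff,
        scenario=scenario,
        uncertainty=uspec,
        deadlines=deadlines,
        sdg_horizon=_get(rsec, "sdg_horizon", int, 20),
        seed=seed,
        uncertainty_max_lakes=_get(rsec, "uncertainty_max_lakes", int, 25),
        log_level=str(_get(rsec, "log_level", str, "INFO")),
        source_text=text,
    )


def config_hash(config: RunConfig) -> str:
    """Stable digest of the effective configuration (for the manifest)."""
    if config.source_text:
        basis = config.source_text
    else:
        basis = repr(
            (
                dataclasses.astuple(config.params),
                config.a_coeff,
                dataclasses.astuple(config.scenario),
                dataclasses.astuple(config.uncertainty),
                config.deadlines,
                config.sdg_horizon,
                config.seed,
            )
        )
    return hashlib.sha256(basis.encode("utf-8")).hexdigest()[:16]
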