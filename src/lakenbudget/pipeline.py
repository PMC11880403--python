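"""End-to-end pipeline: filter → budget → scenarios → planning → Monte Carlo.

Reads one lakes CSV, writes budgets, exclusions, per-scenario goal
years, required reductions per deadline, lake types and uncertainty
intervals as CSVs, plus a JSON manifest recording the config hash,
seed, package version and per-stage row counts. Deterministic: the same
config and input produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .errors import InputError
from .n_budget import LAKE_COLUMNS, assemble_budgets
from .planning import make_plans
from .uncertainty_mc import monte_carlo_table

__all__ = ["run_pipeline"]

log = logging.getLogger("lakenbudget")


def run_pipeline(config: RunConfig, lakes_csv: str | Path, out_dir: str | Path) -> dict:
    """Execute every stage and write the artifact set under ``out_dir``.

    Returns the manifest dict. Malformed rows are diverted to the
    exclusions file and the run continues; a missing required column
    aborts before any computation.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lakes = pd.read_csv(lakes_csv)
    missing = [c for c in LAKE_COLUMNS if c not in lakes.columns]
    if missing:
        raise InputError(f"lakes table missing required columns: {missing}")
    log.info("input: %d lakes", len(lakes))

    budgets, exclusions = assemble_budgets(lakes, config.params, config.a_coeff)
    log.info("budgets: %d applicable, %d excluded", len(budgets), len(exclusions))
    budgets.to_csv(out / "budgets.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)

    plans, types = make_plans(
        budgets,
        config.scenario,
        deadlines=config.deadlines,
        sdg_horizon=config.sdg_horizon,
    )
    plans.to_csv(out / "plans.csv", index=False)
    types.to_csv(out / "types.csv", index=False)
    if len(types):
        counts = types["lake_type"].value_counts().to_dict()
        log.info("classification: %s", counts)
    else:
        counts = {}

    mc_lakes = lakes.head(config.uncertainty_max_lakes)
    intervals = monte_carlo_table(
        mc_lakes,
        config.params,
        config.scenario,
        config.uncertainty,
        deadline=config.sdg_horizon,
    )
    intervals.to_csv(out / "intervals.csv", index=False)
    log.info("uncertainty: %d lakes × %d draws", len(mc_lakes), config.uncertainty.n_draws)

    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "counts": {
            "input_rows": int(len(lakes)),
            "budgets": int(len(budgets)),
            "exclusions": int(len(exclusions)),
            "plan_rows": int(len(plans)),
            "uncertainty_lakes": int(intervals["lake_id"].nunique()) if len(intervals) else 0,
            "types": {k: int(v) for k, v in counts.items()},
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if len(lakes) == 0:
        log.warning("empty lake table: outputs are empty")
    return manifest
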