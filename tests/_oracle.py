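"""Independent brute-force references used across test modules.

These re-implement the annual budget update as a plain straight-line
loop, deliberately sharing no code with the package, so agreement
between the two is a meaningful check.
"""

from __future__ import annotations


def oracle_run(loading, outflow, removal, storage, wv, b, goal, max_years=500,
               deposition=0.0, deposition_constant=False):
    """Straight-loop annual simulation; returns (series, goal_year).

    series is a list of (loading, outflow, removal, storage) tuples
    starting at year 0; goal_year is the first year with concentration
    at or below goal, or None.
    """
    series = [(loading, outflow, removal, storage)]
    goal_year = 0 if storage * 1000.0 / wv <= goal else None
    t = 0
    while t < max_years and goal_year is None:
        t += 1
        if deposition_constant:
            loading_next = (loading - deposition) * (1.0 - b) + deposition
        else:
            loading_next = loading * (1.0 - b)
        outflow_next = outflow * (1.0 - b)
        storage_next = storage + loading_next - outflow_next - removal
        if storage_next < 0.0:
            storage_next = 0.0
        pool = loading + storage
        removal_next = removal * ((loading_next + storage_next) / pool) if pool > 0 else 0.0
        loading, outflow, removal, storage = loading_next, outflow_next, removal_next, storage_next
        series.append((loading, outflow, removal, storage))
        if storage * 1000.0 / wv <= goal:
            goal_year = t
    return series, goal_year


def oracle_goal_year(budget, b, goal=1.0, max_years=500):
    """Goal year for an assembled budget object, via the straight loop."""
    _, gy = oracle_run(
        budget.loading, budget.outflow, budget.removal_flux, budget.storage,
        budget.water_volume, b, goal, max_years,
    )
    return gy
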