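import math

import numpy as np
import pandas as pd
import pytest

from lakenbudget import (
    INFEASIBLE,
    InputError,
    NBudget,
    ScenarioConfig,
    classify_lake,
    cumulative_improvement_curve,
    improvement_efficiency,
    required_reduction,
    simulate,
    years_to_goal,
)
from lakenbudget.planning import (
    B_TOL,
    classify_batch,
    make_plans,
    required_reduction_batch,
)

from ._oracle import oracle_goal_year


def scaled_budget(base: NBudget, **kw) -> NBudget:
    d = dict(base.__dict__)
    d.update(kw)
    return NBudget(**d)


class TestRequiredReduction:
    def test_lake_already_at_goal_needs_nothing(self, worked_budget, scenario):
        easy = ScenarioConfig(goal_conc=5.0)
        assert required_reduction(worked_budget, 10, easy) == 0.0

    def test_worked_lake_deadline_13(self, worked_budget, scenario):
        req = required_reduction(worked_budget, 13, scenario)
        # frozen from the exact-arithmetic brute-force scan: b* ≈ 0.09698
        assert req == pytest.approx(0.0970, abs=1e-3)
        # and well inside the bisection bracket around the true threshold
        assert years_to_goal(worked_budget, req, scenario) <= 13
        assert (
            oracle_goal_year(worked_budget, req - 10 * B_TOL, max_years=13) is None
        )

    def test_self_purifying_lake_needs_nothing_given_time(self, worked_budget):
        # removal strong enough that the no-action equilibrium sits below
        # the goal (with ratio exactly 1.5 the equilibrium is 1.0 mg/L,
        # approached asymptotically but never crossed)
        b = scaled_budget(
            worked_budget, removal_flux=180_000.0, outflow=0.0, removal_ratio=1.8
        )
        sc = ScenarioConfig()
        assert years_to_goal(b, 0.0, sc) is not None
        assert required_reduction(b, 500, sc) == 0.0

    def test_infeasible_when_even_full_reduction_misses(self, worked_budget, scenario):
        # immense storage, weak removal: b=1 cannot drain it in 5 years
        b = scaled_budget(worked_budget, storage=5e6, removal_flux=1000.0, outflow=99_000.0)
        assert required_reduction(b, 5, scenario) is INFEASIBLE

    def test_monotone_in_deadline(self, worked_budget, scenario):
        reqs = [required_reduction(worked_budget, d, scenario) for d in (10, 20, 30, 40)]
        assert all(x >= y for x, y in zip(reqs, reqs[1:]))

    def test_batch_matches_scalar(self, budgets, scenario):
        sub = budgets.head(40)
        got = required_reduction_batch(sub, 15, scenario)
        from lakenbudget.n_budget import budget_from_row

        for i, (_, row) in enumerate(sub.iterrows()):
            expected = required_reduction(budget_from_row(row), 15, scenario)
            if expected is INFEASIBLE:
                assert np.isinf(got[i])
            else:
                assert got[i] == pytest.approx(expected, abs=1e-12)


class TestClassification:
    def test_goal_met(self, worked_budget, scenario):
        b = scaled_budget(worked_budget, storage=80_000.0)  # 0.8 mg/L
        assert classify_lake(b, scenario) == "I_meets_goal"

    def test_self_purifying(self, worked_budget, scenario):
        b = scaled_budget(
            worked_budget, removal_flux=150_000.0, outflow=0.0, removal_ratio=1.5
        )
        assert classify_lake(b, scenario) == "I_self_purifying"

    def test_type_ii_vs_iii_straddle(self, worked_budget, scenario):
        manageable = scaled_budget(worked_budget)  # reaches goal at b=0.1 in 13 y
        assert classify_lake(manageable, scenario, sdg_horizon=20) == "II"
        hopeless = scaled_budget(
            worked_budget, storage=5e7, removal_flux=1000.0, outflow=99_000.0,
            removal_ratio=0.01,
        )
        assert classify_lake(hopeless, scenario, sdg_horizon=20) == "III"

    def test_undefined_ratio_rejected(self, worked_budget, scenario):
        b = scaled_budget(
            worked_budget, loading=0.0, loading_inflow=0.0, loading_deposition=0.0,
            outflow=0.0, removal_flux=0.0, removal_ratio=math.nan,
        )
        with pytest.raises(InputError):
            classify_lake(b, scenario)

    def test_partition_and_batch_agreement(self, budgets, scenario):
        types = classify_batch(budgets, scenario, sdg_horizon=20)
        assert set(types.unique()) <= {"I_meets_goal", "I_self_purifying", "II", "III"}
        assert len(types) == len(budgets)
        from lakenbudget.n_budget import budget_from_row

        sub = budgets.head(50)
        for i, (_, row) in enumerate(sub.iterrows()):
            assert types.iloc[i] == classify_lake(budget_from_row(row), scenario, 20)


class TestImprovementEfficiency:
    def test_worked_lake_value_from_series(self, worked_budget):
        traj = simulate(worked_budget, ScenarioConfig(b=0.1), stop_at_goal=False)
        eff = improvement_efficiency(traj, 13)
        expected = (traj.storage[0] - traj.storage[13]) / (traj.loading[0] - traj.loading[13])
        assert eff == pytest.approx(expected, rel=1e-12)
        assert eff > 0

    def test_no_reduction_is_undefined(self, worked_budget):
        traj = simulate(worked_budget, ScenarioConfig(b=0.0, max_years=20), stop_at_goal=False)
        with pytest.raises(InputError):
            improvement_efficiency(traj, 10)

    def test_efficiency_increases_with_removal_ratio(self, worked_budget):
        sc = ScenarioConfig(b=0.05, max_years=25)
        effs, ratios = [], []
        for flux in np.linspace(5_000, 95_000, 10):
            b = scaled_budget(
                worked_budget,
                removal_flux=float(flux),
                outflow=100_000.0 - float(flux),
                removal_ratio=float(flux) / 100_000.0,
            )
            traj = simulate(b, sc, stop_at_goal=False)
            effs.append(improvement_efficiency(traj, 20))
            ratios.append(b.removal_ratio)
        rho = np.corrcoef(np.argsort(np.argsort(ratios)), np.argsort(np.argsort(effs)))[0, 1]
        assert rho > 0


class TestCumulativeCurve:
    def test_identical_efficiencies_give_diagonal(self):
        x, y = cumulative_improvement_curve([(10.0, 5.0)] * 6)
        assert np.allclose(x, y)
        assert x[0] == 0.0 and x[-1] == pytest.approx(1.0)

    def test_two_lake_hand_case(self):
        x, y = cumulative_improvement_curve([(10.0, 90.0), (90.0, 10.0)])
        assert x[1] == pytest.approx(0.1)
        assert y[1] == pytest.approx(0.9)

    def test_concave_nondecreasing_dominates_diagonal(self):
        rng = np.random.default_rng(9)
        plans = list(zip(rng.uniform(1, 100, 50), rng.uniform(1, 100, 50)))
        x, y = cumulative_improvement_curve(plans)
        assert np.all(np.diff(y) >= -1e-12)
        slopes = np.diff(y) / np.diff(x)
        assert np.all(np.diff(slopes) <= 1e-9)  # concave: slopes non-increasing
        assert np.all(y >= x - 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            cumulative_improvement_curve([])


class TestMakePlans:
    def test_outputs_cover_every_lake_and_deadline(self, budgets, scenario):
        sub = budgets.head(30)
        plans, types = make_plans(sub, scenario, deadlines=(10, 20))
        assert len(plans) == 2 * len(sub)
        assert len(types) == len(sub)
        finite = plans[np.isfinite(plans["required_b"])]
        assert ((finite["required_b"] >= 0) & (finite["required_b"] <= 1)).all()
        assert (finite["required_nani_reduction"] >= 0).all()
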