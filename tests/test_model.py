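"""MILP construction and solving on small instances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from herdplan import (
    InfeasibleModelError,
    Product,
    SolverOptions,
    VariableIndex,
    objective_value,
    solve,
    verify_solution,
)
from herdplan.model import MilpBuilder, build_model

from .conftest import make_animal, make_instance, tiny_economics

EXACT = SolverOptions(mip_gap=0.0)


class TestVariableCounts:
    def test_two_animals_one_facility_one_period(self):
        inst = make_instance([make_animal("a"), make_animal("b")])
        counts = MilpBuilder(inst).build_variables().counts()
        assert counts["binary"] == 6
        assert (counts["z"], counts["y"], counts["gamma"]) == (2, 2, 2)

    def test_single_animal_many_facilities(self):
        inst = make_instance([make_animal("a")], n_facilities=2)
        counts = MilpBuilder(inst).build_variables().counts()
        assert counts["binary"] == 2
        assert counts.get("z", 0) == 0 and counts.get("y", 0) == 0

    @given(
        cohorts=st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=4),
        m=st.integers(min_value=1, max_value=3),
    )
    def test_binary_count_matches_closed_form(self, cohorts, m):
        animals = [
            make_animal(f"a{t}_{k}", period=t + 1)
            for t, n in enumerate(cohorts)
            for k in range(n)
        ]
        inst = make_instance(animals, n_facilities=m, n_periods=len(cohorts))
        counts = MilpBuilder(inst).build_variables().counts()
        assert counts["binary"] == VariableIndex.binary_count_formula(cohorts, m)


class TestSeparation:
    def test_forced_shared_facility_enforces_gap(self):
        # both animals pinned to the one facility; sep(1200) = 1 + 2 = 3h
        animals = [make_animal("a", due=8.0), make_animal("b", due=8.0)]
        inst = make_instance(animals, demand={("P1", 1): 2400})
        fixed = {("gamma", (a.id, "F1", 1)): 1.0 for a in animals}
        sol = solve(inst, EXACT, fixed=fixed)
        gap = abs(sol.x[("b", 1)] - sol.x[("a", 1)])
        assert gap >= inst.separation_hours(animals[0]) - 1e-6
        assert verify_solution(inst, sol).feasible

    def test_overloaded_facility_is_infeasible(self):
        # four 3-hour separations cannot fit an 8-hour horizon
        animals = [make_animal(f"a{i}") for i in range(4)]
        inst = make_instance(animals, demand={("P1", 1): 4800})
        fixed = {("gamma", (a.id, "F1", 1)): 1.0 for a in animals}
        with pytest.raises(InfeasibleModelError) as err:
            solve(inst, EXACT, fixed=fixed)
        assert "separation" in err.value.families


class TestDeviationTightness:
    def test_inside_window_no_penalty(self):
        inst = make_instance([make_animal("a", ready=2.0, due=6.0)])
        sol = solve(inst, EXACT)
        assert sol.alpha[("a", 1)] == 0.0
        assert sol.beta[("a", 1)] == 0.0

    def test_forced_late_slaughter_measured_in_days(self):
        # x pinned 16 working hours after the due time -> 2 days late
        a = make_animal("a", period=1, ready=2.0, due=6.0)
        inst = make_instance([a], n_periods=3, demand={("P1", t): 1200 for t in (1, 2, 3)})
        fixed = {("gamma", ("a", "F1", 1)): 1.0, ("x", ("a", 1)): 22.0}
        sol = solve(inst, EXACT, fixed=fixed)
        assert sol.beta[("a", 1)] == pytest.approx(2.0, abs=1e-9)
        assert sol.alpha[("a", 1)] == 0.0

    def test_forced_early_slaughter(self):
        a = make_animal("a", ready=6.0, due=8.0)
        inst = make_instance([a])
        fixed = {("gamma", ("a", "F1", 1)): 1.0, ("x", ("a", 1)): 2.0}
        sol = solve(inst, EXACT, fixed=fixed)
        assert sol.alpha[("a", 1)] == pytest.approx(0.5, abs=1e-9)


class TestObjective:
    def test_zero_demand_zero_penalties_gives_zero(self):
        eco = tiny_economics(penalty_early_per_day=0.0, penalty_late_per_day=0.0)
        inst = make_instance([make_animal("a")], demand={("P1", 1): 0}, economics=eco)
        sol = solve(inst, EXACT)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        assert not sol.slaughters()

    def test_unserved_demand_costs_loss_of_opportunity(self):
        # inventory cap 0 and a worthless product: serving is impossible
        prod = Product("P1", price=0.0, meat_per_unit=1.0, holding_cost=0.1, inventory_cap=0.0)
        eco = tiny_economics(penalty_early_per_day=0.0, penalty_late_per_day=0.0)
        inst = make_instance(
            [make_animal("a")], demand={("P1", 1): 500}, products=[prod], economics=eco
        )
        sol = solve(inst, EXACT)
        assert not sol.slaughters()
        assert sol.objective == pytest.approx(-eco.loss_of_opportunity * 500)

    def test_reported_objective_matches_arithmetic_recomputation(self):
        inst = make_instance(
            [make_animal("a"), make_animal("b", twa=800.0)],
            n_facilities=2,
            demand={("P1", 1): 2000},
        )
        sol = solve(inst, EXACT)
        assert sol.objective == pytest.approx(objective_value(inst, sol), abs=1e-9)
        assert sol.objective == pytest.approx(sol.solver_objective, abs=1e-6)


class TestSolveProperties:
    def test_determinism_across_runs(self):
        inst = make_instance(
            [make_animal("a"), make_animal("b"), make_animal("c", period=2, ready=10, due=14)],
            n_facilities=2,
            n_periods=2,
            demand={("P1", 1): 2400, ("P1", 2): 1200},
        )
        q1 = solve(inst, EXACT).objective
        q2 = solve(inst, EXACT).objective
        assert q1 == pytest.approx(q2, abs=1e-6)

    def test_higher_lateness_penalty_never_increases_total_lateness(self):
        # one facility, two animals due early: separation forces lateness
        animals = [
            make_animal("a", ready=0.0, due=1.0),
            make_animal("b", ready=0.0, due=1.0),
        ]
        betas = []
        for p_late in (1.0, 50.0):
            eco = tiny_economics(penalty_late_per_day=p_late)
            inst = make_instance(animals, demand={("P1", 1): 2400}, economics=eco)
            fixed = {("gamma", (a.id, "F1", 1)): 1.0 for a in animals}
            sol = solve(inst, EXACT, fixed=fixed)
            betas.append(sum(sol.beta.values()))
        assert betas[1] <= betas[0] + 1e-9

    def test_larger_inventory_cap_never_decreases_objective(self):
        qs = []
        for cap in (0.0, 600.0):
            prod = Product("P1", price=3.0, meat_per_unit=1.0, holding_cost=0.1,
                           inventory_cap=cap)
            inst = make_instance(
                [make_animal("a"), make_animal("b")],
                n_facilities=2,
                demand={("P1", 1): 600},
                products=[prod],
            )
            qs.append(solve(inst, EXACT).objective)
        assert qs[1] >= qs[0] - 1e-9

    def test_sliding_window_serves_adjacent_period_demand(self):
        # the period-1 slaughter enters both the period-1 and period-2
        # balances, so its edible weight serves demand in both
        a = make_animal("a", ready=2.0, due=6.0, period=1)
        inst = make_instance(
            [a], n_periods=2, demand={("P1", 1): 600, ("P1", 2): 600}
        )
        sol = solve(inst, EXACT)
        assert sol.slaughters()
        assert sol.reqserv[("P1", 2)] == pytest.approx(600.0)
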