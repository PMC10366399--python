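"""Batch baseline construction and forage/methane/weight savings accounting."""

import pytest

from herdplan import GrowthParameters, SolverOptions, batch_schedule, compute_savings, solve, verify_solution
from herdplan.baseline import trajectory_weight

from .conftest import make_animal, make_instance, tiny_economics

EXACT = SolverOptions(mip_gap=0.0)


def month_instance(animals, **kw):
    """30-day periods (the real calendar convention) with generous demand."""
    eco = tiny_economics(days_per_period=30)
    demand = {
        ("P1", t): 20_000 for t in range(1, kw.get("n_periods", 3) + 1)
    }
    from herdplan import Product

    prod = Product("P1", price=3.0, meat_per_unit=1.0, holding_cost=0.05, inventory_cap=5000)
    return make_instance(
        animals,
        n_facilities=kw.get("n_facilities", 2),
        n_periods=kw.get("n_periods", 3),
        demand=demand,
        products=[prod],
        economics=eco,
    )


class TestBatchSchedule:
    def test_every_cohort_member_slaughtered_at_period_start(self):
        animals = [
            make_animal(f"a{i}", period=2, ready=300.0, due=420.0) for i in range(4)
        ]
        inst = month_instance(animals)
        sol = batch_schedule(inst, EXACT)
        sl = sol.slaughters()
        assert len(sl) == 4
        start = inst.period_start(2)
        for aid, (_fid, t, hour) in sl.items():
            assert t == 2
            assert hour >= start
            assert hour < start + 8.0  # first working day
        assert verify_solution(inst, sol).feasible

    def test_cohort_counts_per_period(self):
        animals = [
            make_animal(f"a{t}_{k}", period=t, ready=240.0 * (t - 1) + 8, due=240.0 * t)
            for t in (1, 2, 3)
            for k in range(3)
        ]
        inst = month_instance(animals)
        sol = batch_schedule(inst, EXACT)
        by_period = {}
        for _aid, (_f, t, _x) in sol.slaughters().items():
            by_period[t] = by_period.get(t, 0) + 1
        assert by_period == {1: 3, 2: 3, 3: 3}


class TestTrajectoryWeight:
    def test_flat_after_due(self):
        a = make_animal("a", ready=80.0, due=160.0)  # days 10 and 20
        assert trajectory_weight(a, 25.0, 8.0) == a.target_weight_lbs

    def test_linear_between_ready_and_due(self):
        a = make_animal("a", ready=80.0, due=160.0)
        p = GrowthParameters()
        w_mid = trajectory_weight(a, 15.0, 8.0, p)
        expected = a.target_weight_lbs * (p.ready_weight_fraction + (1 - p.ready_weight_fraction) / 2)
        assert w_mid == pytest.approx(expected)


class TestSavings:
    def _solutions_days_apart(self, days_earlier: int):
        """One animal; one schedule at the batch date, one earlier."""
        a = make_animal("a", period=2, ready=0.0, due=480.0)
        inst = month_instance([a], n_facilities=1)
        batch = batch_schedule(inst, EXACT)
        start = inst.period_start(2)
        fixed = {
            ("gamma", ("a", "F1", 2)): 1.0,
            ("x", ("a", 2)): start - 8.0 * days_earlier,
        }
        earlier = solve(inst, EXACT, fixed=fixed)
        return inst, earlier, batch

    def test_ten_days_earlier_reference_arithmetic(self):
        inst, earlier, batch = self._solutions_days_apart(10)
        rep = compute_savings(inst, earlier, batch)
        assert rep.forage_saved_lbs == pytest.approx(240.0)  # 24 lbs/day x 10
        assert rep.methane_saved_kg == pytest.approx(150.0 / 365.0 * 10, abs=1e-3)
        assert rep.animal_days_delta == 10

    def test_identical_schedules_zero_report(self):
        inst, _earlier, batch = self._solutions_days_apart(10)
        rep = compute_savings(inst, batch, batch)
        assert rep.forage_saved_lbs == 0.0
        assert rep.methane_saved_kg == 0.0
        assert rep.weight_delta_lbs == 0.0
        assert rep.animal_days_delta == 0.0

    def test_totals_equal_per_period_breakdown(self):
        inst, earlier, batch = self._solutions_days_apart(7)
        rep = compute_savings(inst, earlier, batch)
        assert rep.forage_saved_lbs == pytest.approx(
            sum(r["forage_lbs"] for r in rep.per_period.values()), abs=1e-6
        )
        assert rep.methane_saved_kg == pytest.approx(
            sum(r["methane_kg"] for r in rep.per_period.values()), abs=1e-6
        )
        assert rep.weight_delta_lbs == pytest.approx(
            sum(r["weight_lbs"] for r in rep.per_period.values()), abs=1e-6
        )

    def test_savings_scale_with_rates(self):
        inst, earlier, batch = self._solutions_days_apart(10)
        base = compute_savings(inst, earlier, batch, GrowthParameters())
        doubled_intake = compute_savings(
            inst, earlier, batch, GrowthParameters(intake_coeff=2 * 24.0 / 1200.0)
        )
        doubled_ch4 = compute_savings(
            inst, earlier, batch, GrowthParameters(methane_kg_per_cow_year=300.0)
        )
        assert doubled_intake.forage_saved_lbs == pytest.approx(2 * base.forage_saved_lbs)
        assert doubled_ch4.methane_saved_kg == pytest.approx(2 * base.methane_saved_kg)

    def test_mismatched_herds_error(self):
        inst, earlier, batch = self._solutions_days_apart(5)
        other = make_animal("zz", period=2, ready=0.0, due=480.0)
        inst2 = month_instance([other], n_facilities=1)
        foreign = batch_schedule(inst2, EXACT)
        with pytest.raises(ValueError):
            compute_savings(inst, earlier, foreign)
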