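import numpy as np
import pytest
from hypothesis import settings

from herdplan import AnimalRecord, Economics, Facility, PlanningInstance, Product
from herdplan.synthetic import DemandSeries

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_animal(
    aid: str,
    period: int = 1,
    ready: float = 0.0,
    due: float = 8.0,
    twa: float = 1200.0,
    sex: str = "male",
) -> AnimalRecord:
    """Animal with an explicit window (working hours) and target weight."""
    return AnimalRecord(
        id=aid,
        sex=sex,
        age_days=300,
        hip_height_in=45.0,
        frame_score=5.0,
        target_weight_lbs=twa,
        ready_time=ready,
        due_time=due,
        maturity_period=period,
    )


def tiny_economics(**overrides) -> Economics:
    """One-day periods of 8 working hours; integer separation times."""
    base = dict(
        live_price=0.2,
        penalty_early_per_day=16.0,
        penalty_late_per_day=24.0,
        loss_of_opportunity=1.0,
        processing_hours_per_lb=1.0 / 1200.0,
        cleaning_hours=2.0,
        big_m=3000.0,
        hours_per_day=8.0,
        days_per_period=1,
    )
    base.update(overrides)
    return Economics(**base)


def make_instance(
    animals,
    n_facilities: int = 1,
    n_periods: int = 1,
    demand: dict | None = None,
    products: list | None = None,
    economics: Economics | None = None,
) -> PlanningInstance:
    facilities = [
        Facility(f"F{i + 1}", slaughter_cost=50.0 + 5.0 * i) for i in range(n_facilities)
    ]
    if products is None:
        products = [
            Product("P1", price=3.0, meat_per_unit=1.0, holding_cost=0.1, inventory_cap=0.0)
        ]
    if demand is None:
        demand = {(g.id, t): 1200 for g in products for t in range(1, n_periods + 1)}
    return PlanningInstance(
        animals=animals,
        facilities=facilities,
        products=products,
        demand=DemandSeries(demand),
        n_periods=n_periods,
        economics=economics or tiny_economics(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
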