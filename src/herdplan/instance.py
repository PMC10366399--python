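"""The MILP input: animals, facilities, products, demands and economics.

Time convention
---------------
The planning horizon is ``n_periods`` months; each month provides 30 working
days of 8 working hours, so period t spans working hours
``[(t-1)*240, t*240)``.  Slaughter times x are continuous working hours on
this timeline; earliness/lateness are measured in days (hours / 8).

Each animal is *active* in exactly one scheduling period -- the period
containing its expected 22-month maturity -- which is what gives the herd of
90 animals/month its 90-animals-per-period decision structure.  Its slaughter
time may nonetheless land anywhere on the horizon timeline, so the optimizer
can pull a slaughter forward to the (earlier) ready time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

from .growth import AnimalRecord, GrowthParameters, Sex
from .synthetic import DemandSeries

__all__ = ["Facility", "Product", "Economics", "PlanningInstance"]


@dataclass(frozen=True)
class Facility:
    """A slaughter/processing facility with a per-animal usage cost ($)."""

    id: str
    slaughter_cost: float = 50.0

    def __post_init__(self) -> None:
        if self.slaughter_cost < 0:
            raise ValueError("slaughter_cost must be non-negative")


@dataclass(frozen=True)
class Product:
    """A meat product line.

    meat_per_unit is Prop_g: lbs of meat needed per unit of product (0.5 for
    the half-pound minced pack, 1.0 for the pound packs).  price and
    production_cost are $ per lb of meat served; holding_cost is $ per lb per
    period; inventory_cap is the meat-inventory ceiling in lbs.
    """

    id: str
    price: float
    meat_per_unit: float = 1.0
    production_cost: float = 0.0
    holding_cost: float = 0.05
    inventory_cap: float = 5000.0

    def __post_init__(self) -> None:
        if self.meat_per_unit <= 0:
            raise ValueError("meat_per_unit (Prop_g) must be positive")
        if min(self.price, self.production_cost, self.holding_cost, self.inventory_cap) < 0:
            raise ValueError("prices, costs and caps must be non-negative")

    @property
    def net_price(self) -> float:
        return self.price - self.production_cost


@dataclass
class Economics:
    """Scalar economics and model constants.

    Defaults are documented package choices (these figures are farm-specific
    in practice): live-sale price 0.25 $/lb; earliness penalty 30 $/day,
    lateness penalty 45 $/day (late slaughter also carries the environmental
    cost of a flat growth curve); loss-of-opportunity 1 $/unit of unmet
    demand; processing time 1/1500 working hours per lb plus a 0.2 h
    cleaning constant, i.e. a 1,200 lb animal occupies its facility for
    exactly one hour.  big_m (3000) must exceed the horizon length in
    working hours.
    """

    live_price: float = 0.25
    penalty_early_per_day: float = 30.0
    penalty_late_per_day: float = 45.0
    loss_of_opportunity: float = 1.0
    processing_hours_per_lb: float = 1.0 / 1500.0
    cleaning_hours: float = 0.2
    big_m: float = 3000.0
    hours_per_day: float = 8.0
    days_per_period: int = 30
    edible_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(
            self.live_price,
            self.penalty_early_per_day,
            self.penalty_late_per_day,
            self.loss_of_opportunity,
            self.processing_hours_per_lb,
            self.cleaning_hours,
        ) < 0:
            raise ValueError("economic parameters must be non-negative")

    @property
    def period_hours(self) -> float:
        return self.days_per_period * self.hours_per_day


@dataclass
class PlanningInstance:
    """Full optimisation input.

    ``animals`` must all have a maturity_period within 1..n_periods; use
    :meth:`from_herd` to filter a larger roster down to the horizon and clip
    window hours into it.
    """

    animals: list[AnimalRecord]
    facilities: list[Facility]
    products: list[Product]
    demand: DemandSeries
    n_periods: int
    economics: Economics = field(default_factory=Economics)

    def __post_init__(self) -> None:
        if not self.animals:
            raise ValueError("instance needs at least one animal")
        if not self.facilities or not self.products or self.n_periods < 1:
            raise ValueError("need >=1 facility, product and period")
        if self.economics.big_m <= self.horizon_hours:
            raise ValueError(
                f"big_m={self.economics.big_m} must exceed the horizon "
                f"({self.horizon_hours} working hours)"
            )
        ids = [a.id for a in self.animals]
        if len(set(ids)) != len(ids):
            raise ValueError("animal ids must be unique")
        for a in self.animals:
            if not (1 <= a.maturity_period <= self.n_periods):
                raise ValueError(
                    f"animal {a.id} maturity_period {a.maturity_period} outside horizon"
                )
        for g in self.demand.products:
            if g not in {p.id for p in self.products}:
                raise ValueError(f"demand references unknown product {g}")

    # -- derived geometry -------------------------------------------------
    @property
    def period_hours(self) -> float:
        return self.economics.period_hours

    @property
    def horizon_hours(self) -> float:
        return self.n_periods * self.period_hours

    def period_start(self, t: int) -> float:
        return (t - 1) * self.period_hours

    def active(self, t: int) -> list[AnimalRecord]:
        """Animals scheduled in period t."""
        return [a for a in self.animals if a.maturity_period == t]

    def separation_hours(self, animal: AnimalRecord) -> float:
        """Facility occupation after slaughtering this animal:
        processing time proportional to live weight plus cleaning."""
        eco = self.economics
        return eco.processing_hours_per_lb * animal.target_weight_lbs + eco.cleaning_hours

    def requirement(self, g: str, t: int) -> float:
        return float(self.demand.requirements.get((g, t), 0.0))

    def served_cap(self, product: Product, t: int) -> float:
        """Demand ceiling in lbs of meat: Prop_g x Req_{g,t}."""
        return product.meat_per_unit * self.requirement(product.id, t)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_herd(
        cls,
        herd: list[AnimalRecord],
        facilities: list[Facility],
        products: list[Product],
        demand: DemandSeries,
        n_periods: int,
        economics: Optional[Economics] = None,
    ) -> "PlanningInstance":
        """Keep animals maturing within the horizon; clip windows into it."""
        economics = economics or Economics()
        horizon_h = n_periods * economics.period_hours
        kept = []
        for a in herd:
            if not (1 <= a.maturity_period <= n_periods):
                continue
            ready = min(max(a.ready_time, 0.0), horizon_h - 1e-9)
            due = min(max(a.due_time, ready + 1e-6), horizon_h)
            kept.append(
                AnimalRecord(
                    id=a.id,
                    sex=a.sex,
                    age_days=a.age_days,
                    hip_height_in=a.hip_height_in,
                    frame_score=a.frame_score,
                    target_weight_lbs=a.target_weight_lbs,
                    ready_time=ready,
                    due_time=due,
                    maturity_period=a.maturity_period,
                    measured_age_days=a.measured_age_days,
                )
            )
        return cls(kept, facilities, products, demand, n_periods, economics)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_periods": self.n_periods,
            "economics": asdict(self.economics),
            "facilities": [asdict(f) for f in self.facilities],
            "products": [asdict(p) for p in self.products],
            "demand": [
                {"product": g, "period": t, "units": v}
                for (g, t), v in sorted(self.demand.requirements.items())
            ],
            "animals": [
                {**asdict(a), "sex": a.sex.value} for a in self.animals
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "PlanningInstance":
        demand = DemandSeries(
            {(r["product"], int(r["period"])): int(r["units"]) for r in d["demand"]}
        )
        return cls(
            animals=[AnimalRecord(**{**a, "sex": Sex(a["sex"])}) for a in d["animals"]],
            facilities=[Facility(**f) for f in d["facilities"]],
            products=[Product(**p) for p in d["products"]],
            demand=demand,
            n_periods=int(d["n_periods"]),
            economics=Economics(**d["economics"]),
        )

    @classmethod
    def from_json(cls, path) -> "PlanningInstance":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_products() -> list[Product]:
    """The three case-study product lines.

    P1: half-pound minced pack, P2: one-pound minced pack (deliberately the
    highest production cost, so it is deprioritised first under tight
    capacity), P3: one-pound boneless cut.
    """
    return [
        Product("P1", price=3.0, meat_per_unit=0.5, production_cost=0.1),
        Product("P2", price=3.0, meat_per_unit=1.0, production_cost=0.8),
        Product("P3", price=3.2, meat_per_unit=1.0, production_cost=0.2),
    ]


def default_facilities() -> list[Facility]:
    return [Facility("F1", slaughter_cost=50.0), Facility("F2", slaughter_cost=52.0)]
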