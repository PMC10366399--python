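"""Independent arithmetic re-check of a solution against every constraint family.

Deliberately does not touch the model builder or the solver: each family is
re-evaluated by direct arithmetic on the solution's variable values, so a
bug in the builder cannot hide itself.  Families:

==========================  ====================================================
separation                  big-M sequencing gaps at shared facilities
same_facility_symmetry      z_{a,b,t} == z_{b,a,t}
precedence_exclusivity      y_{a,b,t} + y_{b,a,t} <= 1
facility_sharing_link       z >= gamma_a + gamma_b - 1
single_slaughter            sum_{s,t} gamma_{a,s,t} <= 1
demand_cap                  Reqserv_{g,t} <= Prop_g * Req_{g,t}
meat_balance                sliding-window aggregate meat balance per period
inventory_cap               h_{g,t} <= INVcap_g
live_sales                  Remsold_{a,t} = TWA*(1 - sum_s gamma_{a,s,t-2})
closing_live_inventory      Reminv_{a,t} = TWA*(1 - sum_s gamma_{a,s,t})
weight_conservation         horizon-wide live-weight accounting identity
earliness / lateness        alpha/beta >= their max() definitions, >= 0
domain                      binaries integral, x within the horizon
==========================  ====================================================

A violation is flagged when it exceeds ``tol * max(1, scale)`` where scale is
the largest term magnitude in the constraint -- an absolute check for unit-
scale rows, relative for rows carrying tens of thousands of pounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .instance import PlanningInstance
from .model import Solution

__all__ = ["Violation", "ViolationReport", "verify_solution", "IncompleteSolutionError"]


class IncompleteSolutionError(KeyError):
    """The solution is missing variable values the instance requires."""


@dataclass(frozen=True)
class Violation:
    family: str
    key: tuple
    magnitude: float


@dataclass
class ViolationReport:
    feasible: bool
    tolerance: float
    violations: list = field(default_factory=list)
    max_by_family: dict = field(default_factory=dict)

    def families(self) -> set:
        return {v.family for v in self.violations}

    def worst(self, family: str) -> float:
        return self.max_by_family.get(family, 0.0)


class _Checker:
    def __init__(self, instance: PlanningInstance, sol: Solution, tol: float):
        self.inst = instance
        self.sol = sol
        self.tol = tol
        self.violations: list[Violation] = []
        self.max_by_family: dict = {}

    def flag(self, family: str, key: tuple, magnitude: float, scale: float = 1.0) -> None:
        self.max_by_family[family] = max(self.max_by_family.get(family, 0.0), magnitude)
        if magnitude > self.tol * max(1.0, abs(scale)):
            self.violations.append(Violation(family, key, magnitude))

    def get(self, mapping: dict, key: tuple, what: str) -> float:
        try:
            return mapping[key]
        except KeyError as exc:
            raise IncompleteSolutionError(f"missing {what}{key}") from exc


def _gamma_sum(chk: _Checker, animal, t: int) -> float:
    if t != animal.maturity_period or not (1 <= t <= chk.inst.n_periods):
        return 0.0
    return sum(
        chk.get(chk.sol.gamma, (animal.id, s.id, t), "gamma")
        for s in chk.inst.facilities
    )


def verify_solution(
    instance: PlanningInstance, sol: Solution, tol: float = 1e-6
) -> ViolationReport:
    """Evaluate every constraint family by direct arithmetic."""
    chk = _Checker(instance, sol, tol)
    inst, eco = instance, instance.economics
    M = eco.big_m
    hpd = eco.hours_per_day

    for t in range(1, inst.n_periods + 1):
        animals = inst.active(t)
        for a in animals:
            sep_a = inst.separation_hours(a)
            xa = chk.get(sol.x, (a.id, t), "x")
            for b in animals:
                if a.id == b.id:
                    continue
                xb = chk.get(sol.x, (b.id, t), "x")
                z = chk.get(sol.z, (a.id, b.id, t), "z")
                y_ba = chk.get(sol.y, (b.id, a.id, t), "y")
                lhs = xb - xa - sep_a * z + M * y_ba
                chk.flag("separation", (a.id, b.id, t), max(0.0, -lhs), scale=sep_a)
        ids = [a.id for a in animals]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                z_ab = chk.get(sol.z, (a, b, t), "z")
                z_ba = chk.get(sol.z, (b, a, t), "z")
                chk.flag("same_facility_symmetry", (a, b, t), abs(z_ab - z_ba))
                y_ab = chk.get(sol.y, (a, b, t), "y")
                y_ba = chk.get(sol.y, (b, a, t), "y")
                chk.flag("precedence_exclusivity", (a, b, t), max(0.0, y_ab + y_ba - 1.0))
        for i, a in enumerate(animals):
            for b in animals[i + 1:]:
                z_ab = chk.get(sol.z, (a.id, b.id, t), "z")
                for s in inst.facilities:
                    g_a = chk.get(sol.gamma, (a.id, s.id, t), "gamma")
                    g_b = chk.get(sol.gamma, (b.id, s.id, t), "gamma")
                    chk.flag(
                        "facility_sharing_link",
                        (a.id, b.id, s.id, t),
                        max(0.0, g_a + g_b - 1.0 - z_ab),
                    )

    for a in inst.animals:
        total = _gamma_sum(chk, a, a.maturity_period)
        chk.flag("single_slaughter", (a.id,), max(0.0, total - 1.0))

    ef = eco.edible_fraction
    for t in range(1, inst.n_periods + 1):
        supply = 0.0
        if t - 2 >= 1:
            supply += sum(chk.get(sol.h, (g.id, t - 2), "h") for g in inst.products)
        for tau in (t - 1, t, t + 1):
            if 1 <= tau <= inst.n_periods:
                for a in inst.active(tau):
                    supply += ef * a.target_weight_lbs * _gamma_sum(chk, a, tau)
        served = sum(chk.get(sol.reqserv, (g.id, t), "reqserv") for g in inst.products)
        held = sum(chk.get(sol.h, (g.id, t), "h") for g in inst.products)
        chk.flag("meat_balance", (t,), abs(supply - served - held), scale=supply)
        for g in inst.products:
            rs = chk.get(sol.reqserv, (g.id, t), "reqserv")
            cap = inst.served_cap(g, t)
            chk.flag("demand_cap", (g.id, t), max(0.0, rs - cap), scale=cap)
            hv = chk.get(sol.h, (g.id, t), "h")
            chk.flag("inventory_cap", (g.id, t), max(0.0, hv - g.inventory_cap),
                     scale=g.inventory_cap)

    conserved = 0.0
    for a in inst.animals:
        twa = a.target_weight_lbs
        for t in range(3, inst.n_periods + 1):
            rs = chk.get(sol.remsold, (a.id, t), "remsold")
            expect = twa * (1.0 - _gamma_sum(chk, a, t - 2))
            chk.flag("live_sales", (a.id, t), abs(rs - expect), scale=twa)
            conserved += rs
        for t in range(max(1, inst.n_periods - 1), inst.n_periods + 1):
            ri = chk.get(sol.reminv, (a.id, t), "reminv")
            expect = twa * (1.0 - _gamma_sum(chk, a, t))
            chk.flag("closing_live_inventory", (a.id, t), abs(ri - expect), scale=twa)
            conserved += ri
        conserved += twa * _gamma_sum(chk, a, a.maturity_period)
    total = sum(a.target_weight_lbs * inst.n_periods for a in inst.animals)
    chk.flag("weight_conservation", ("total",), abs(conserved - total), scale=total)

    H = inst.horizon_hours
    for a in inst.animals:
        t = a.maturity_period
        xv = chk.get(sol.x, (a.id, t), "x")
        chk.flag("domain", (a.id, "x", t), max(0.0, -xv, xv - H), scale=H)
        al = chk.get(sol.alpha, (a.id, t), "alpha")
        be = chk.get(sol.beta, (a.id, t), "beta")
        chk.flag("earliness", (a.id, t),
                 max(0.0, -al, (a.ready_time - xv) / hpd - al))
        chk.flag("lateness", (a.id, t),
                 max(0.0, -be, (xv - a.due_time) / hpd - be))
    for mapping in (sol.z, sol.y, sol.gamma):
        for key, val in mapping.items():
            chk.flag("domain", key, abs(val - round(val)) + max(0.0, -val, val - 1.0))

    return ViolationReport(
        feasible=not chk.violations,
        tolerance=tol,
        violations=chk.violations,
        max_by_family=chk.max_by_family,
    )
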