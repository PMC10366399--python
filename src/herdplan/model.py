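"""Sliding-time-window slaughter-scheduling MILP.

The model decides, for every animal in the planning horizon, whether / when /
where it is slaughtered, maximising

    Q =   sum Reqserv_gt * Pr_g            (meat revenue, net of production cost)
        + sum Remsold_at * Pr_live         (live sales of leftover animals)
        - sum (alpha_at * P- + beta_at * P+)   (earliness / lateness penalties)
        - sum h_gt * HC_g                  (inventory holding)
        - sum gamma_ast * c_s              (slaughter / processing cost)
        - LOC * sum (Req_gt - Reqserv_gt)  (loss of opportunity)

subject to per-facility separation times between consecutive slaughters
(big-M sequencing with same-facility indicators z and precedence indicators
y), at most one slaughter per animal, a per-period aggregate meat balance
with a three-period sliding window (meat slaughtered in t-1, t, t+1 serves
period t at the 50% edible fraction), demand and inventory caps, and the
live-animal leftover accounting.

The solver backend is HiGHS via :func:`scipy.optimize.milp`; the builder is
solver-agnostic (plain bounds / sparse rows) so another backend can be
plugged in behind :func:`solve`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .growth import AnimalRecord
from .instance import PlanningInstance

__all__ = [
    "VariableIndex",
    "MilpBuilder",
    "SolverOptions",
    "Solution",
    "InfeasibleModelError",
    "build_model",
    "solve",
    "objective_value",
]

BINARY_CLASSES = ("z", "y", "gamma")


class InfeasibleModelError(RuntimeError):
    """Raised when the assembled model has no feasible point.

    ``families`` lists constraint families whose removal restores
    feasibility (determined by relaxation probing on small models).
    """

    def __init__(self, message: str, families: Optional[list[str]] = None):
        super().__init__(message)
        self.families = families or []


@dataclass
class VariableIndex:
    """Flat indexing of every decision variable, with counts by class.

    Keys mirror the model's symbols: ``x/alpha/beta[(a, t)]`` for an animal
    and its scheduling period, ``z/y[(a, b, t)]`` over ordered pairs of
    animals active in t, ``gamma[(a, s, t)]``, ``h/reqserv[(g, t)]``,
    ``remsold[(a, t)]`` for t > 2 and ``reminv[(a, t)]`` for the last two
    periods.
    """

    index: dict = field(default_factory=dict)  # (cls, key) -> flat position
    lb: list = field(default_factory=list)
    ub: list = field(default_factory=list)
    integrality: list = field(default_factory=list)

    def add(self, cls: str, key: tuple, lo: float, hi: float, integer: bool) -> int:
        pos = len(self.lb)
        self.index[(cls, key)] = pos
        self.lb.append(lo)
        self.ub.append(hi)
        self.integrality.append(1 if integer else 0)
        return pos

    def __getitem__(self, cls_key: tuple) -> int:
        return self.index[cls_key]

    def keys(self, cls: str):
        return [k for (c, k) in self.index if c == cls]

    @property
    def n(self) -> int:
        return len(self.lb)

    def counts(self) -> dict:
        out: dict = {}
        for (cls, _key) in self.index:
            out[cls] = out.get(cls, 0) + 1
        out["binary"] = sum(out.get(c, 0) for c in BINARY_CLASSES)
        out["continuous"] = self.n - out["binary"]
        out["total"] = self.n
        return out

    @staticmethod
    def binary_count_formula(active_per_period: list[int], n_facilities: int) -> int:
        """Closed form: sum_t [2 n_t (n_t - 1) + n_t m] binaries."""
        return sum(2 * n * (n - 1) + n * n_facilities for n in active_per_period)


@dataclass
class Row:
    family: str
    key: tuple
    coeffs: dict  # flat index -> coefficient
    lb: float
    ub: float


class MilpBuilder:
    """Assembles the model in the order the formulation is stated."""

    def __init__(self, instance: PlanningInstance):
        self.inst = instance
        self.vars = VariableIndex()
        self.rows: list[Row] = []
        self.obj: Optional[np.ndarray] = None
        self.obj_const = 0.0
        self._active = {
            t: instance.active(t) for t in range(1, instance.n_periods + 1)
        }

    # -- variables --------------------------------------------------------
    def build_variables(self) -> VariableIndex:
        inst, v = self.inst, self.vars
        if not inst.animals:
            raise ValueError("no animals in instance")
        H = inst.horizon_hours
        for t, animals in self._active.items():
            ids = [a.id for a in animals]
            for a in ids:
                for b in ids:
                    if a != b:
                        v.add("z", (a, b, t), 0, 1, True)
            for a in ids:
                for b in ids:
                    if a != b:
                        v.add("y", (a, b, t), 0, 1, True)
            for a in animals:
                for s in inst.facilities:
                    v.add("gamma", (a.id, s.id, t), 0, 1, True)
            for a in animals:
                v.add("x", (a.id, t), 0.0, H, False)
                v.add("alpha", (a.id, t), 0.0, math.inf, False)
                v.add("beta", (a.id, t), 0.0, math.inf, False)
        for g in inst.products:
            for t in range(1, inst.n_periods + 1):
                v.add("h", (g.id, t), 0.0, g.inventory_cap, False)
                v.add("reqserv", (g.id, t), 0.0, inst.served_cap(g, t), False)
        for a in inst.animals:
            for t in range(3, inst.n_periods + 1):
                v.add("remsold", (a.id, t), 0.0, a.target_weight_lbs, False)
            for t in range(max(1, inst.n_periods - 1), inst.n_periods + 1):
                v.add("reminv", (a.id, t), 0.0, a.target_weight_lbs, False)
        return v

    # -- helpers ----------------------------------------------------------
    def _gamma_terms(self, animal: AnimalRecord, t: int) -> list[int]:
        """Flat indices of gamma_{a,s,t}; empty when the animal is not
        active in t (out-of-range terms contribute zero)."""
        if t != animal.maturity_period or not (1 <= t <= self.inst.n_periods):
            return []
        return [self.vars[("gamma", (animal.id, s.id, t))] for s in self.inst.facilities]

    def _row(self, family: str, key: tuple, coeffs: dict, lb: float, ub: float) -> None:
        self.rows.append(Row(family, key, coeffs, lb, ub))

    # -- constraint families ----------------------------------------------
    def add_separation_constraints(self) -> None:
        """Big-M sequencing: animals sharing a facility in a period must be
        separated by the predecessor's processing-plus-cleaning time."""
        inst, v = self.inst, self.vars
        M = inst.economics.big_m
        for t, animals in self._active.items():
            for a in animals:
                sep_a = inst.separation_hours(a)
                for b in animals:
                    if a.id == b.id:
                        continue
                    coeffs = {
                        v[("x", (b.id, t))]: 1.0,
                        v[("x", (a.id, t))]: -1.0,
                        v[("z", (a.id, b.id, t))]: -sep_a,
                        v[("y", (b.id, a.id, t))]: M,
                    }
                    self._row("separation", (a.id, b.id, t), coeffs, 0.0, math.inf)

    def add_structural_constraints(self) -> None:
        """Symmetry of z, exclusivity of y, facility-sharing linkage, and
        at most one slaughter per animal over all facilities and periods."""
        inst, v = self.inst, self.vars
        for t, animals in self._active.items():
            ids = [a.id for a in animals]
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    self._row(
                        "same_facility_symmetry",
                        (a, b, t),
                        {v[("z", (a, b, t))]: 1.0, v[("z", (b, a, t))]: -1.0},
                        0.0,
                        0.0,
                    )
                    self._row(
                        "precedence_exclusivity",
                        (a, b, t),
                        {v[("y", (a, b, t))]: 1.0, v[("y", (b, a, t))]: 1.0},
                        -math.inf,
                        1.0,
                    )
                    for s in inst.facilities:
                        self._row(
                            "facility_sharing_link",
                            (a, b, s.id, t),
                            {
                                v[("z", (a, b, t))]: -1.0,
                                v[("gamma", (a, s.id, t))]: 1.0,
                                v[("gamma", (b, s.id, t))]: 1.0,
                            },
                            -math.inf,
                            1.0,
                        )
        for a in inst.animals:
            coeffs = {
                v[("gamma", (a.id, s.id, a.maturity_period))]: 1.0
                for s in inst.facilities
            }
            self._row("single_slaughter", (a.id,), coeffs, -math.inf, 1.0)

    def add_demand_and_inventory(self) -> None:
        """Aggregate meat balance per period with the three-period sliding
        window; demand and inventory caps are enforced through variable
        bounds and re-checked by the independent verifier."""
        inst, v = self.inst, self.vars
        ef = inst.economics.edible_fraction
        for t in range(1, inst.n_periods + 1):
            coeffs: dict = {}
            if t - 2 >= 1:
                for g in inst.products:
                    coeffs[v[("h", (g.id, t - 2))]] = 1.0
            for tau in (t - 1, t, t + 1):
                if 1 <= tau <= inst.n_periods:
                    for a in self._active[tau]:
                        for idx in self._gamma_terms(a, tau):
                            coeffs[idx] = coeffs.get(idx, 0.0) + ef * a.target_weight_lbs
            for g in inst.products:
                coeffs[v[("reqserv", (g.id, t))]] = coeffs.get(
                    v[("reqserv", (g.id, t))], 0.0
                ) - 1.0
                coeffs[v[("h", (g.id, t))]] = coeffs.get(v[("h", (g.id, t))], 0.0) - 1.0
            self._row("meat_balance", (t,), coeffs, 0.0, 0.0)

    def add_leftover_and_conservation(self) -> None:
        """Live-sale leftovers (t > 2), closing live inventory (last two
        periods) and the weight-conservation identity over the horizon."""
        inst, v = self.inst, self.vars
        for a in inst.animals:
            twa = a.target_weight_lbs
            for t in range(3, inst.n_periods + 1):
                coeffs = {v[("remsold", (a.id, t))]: 1.0}
                for idx in self._gamma_terms(a, t - 2):
                    coeffs[idx] = twa
                self._row("live_sales", (a.id, t), coeffs, twa, twa)
            for t in range(max(1, inst.n_periods - 1), inst.n_periods + 1):
                coeffs = {v[("reminv", (a.id, t))]: 1.0}
                for idx in self._gamma_terms(a, t):
                    coeffs[idx] = twa
                self._row("closing_live_inventory", (a.id, t), coeffs, twa, twa)
        # conservation identity: sold + closing + slaughtered weight accounts
        # for every animal-period's target weight over the horizon
        total = sum(a.target_weight_lbs * inst.n_periods for a in inst.animals)
        coeffs = {}
        for a in inst.animals:
            for t in range(3, inst.n_periods + 1):
                coeffs[v[("remsold", (a.id, t))]] = 1.0
            for t in range(max(1, inst.n_periods - 1), inst.n_periods + 1):
                coeffs[v[("reminv", (a.id, t))]] = 1.0
            for idx in self._gamma_terms(a, a.maturity_period):
                coeffs[idx] = a.target_weight_lbs
        self._row("weight_conservation", ("total",), coeffs, total, total)

    def add_deviation_linearization(self) -> None:
        """alpha >= (R - x)/hours_per_day, beta >= (x - D)/hours_per_day,
        both >= 0; positive penalties make them tight at optimality."""
        inst, v = self.inst, self.vars
        hpd = inst.economics.hours_per_day
        for a in inst.animals:
            t = a.maturity_period
            self._row(
                "earliness",
                (a.id, t),
                {v[("x", (a.id, t))]: 1.0, v[("alpha", (a.id, t))]: hpd},
                a.ready_time,
                math.inf,
            )
            self._row(
                "lateness",
                (a.id, t),
                {v[("x", (a.id, t))]: 1.0, v[("beta", (a.id, t))]: -hpd},
                -math.inf,
                a.due_time,
            )

    def build_objective(self) -> np.ndarray:
        """Coefficient vector for maximisation plus the constant term."""
        inst, v = self.inst, self.vars
        eco = inst.economics
        c = np.zeros(v.n)
        for g in inst.products:
            for t in range(1, inst.n_periods + 1):
                c[v[("reqserv", (g.id, t))]] = g.net_price + eco.loss_of_opportunity
                c[v[("h", (g.id, t))]] = -g.holding_cost
        for a in inst.animals:
            t = a.maturity_period
            c[v[("alpha", (a.id, t))]] = -eco.penalty_early_per_day
            c[v[("beta", (a.id, t))]] = -eco.penalty_late_per_day
            for s in inst.facilities:
                c[v[("gamma", (a.id, s.id, t))]] = -s.slaughter_cost
            for tt in range(3, inst.n_periods + 1):
                c[v[("remsold", (a.id, tt))]] = eco.live_price
        self.obj_const = -eco.loss_of_opportunity * sum(
            inst.requirement(g.id, t)
            for g in inst.products
            for t in range(1, inst.n_periods + 1)
        )
        self.obj = c
        return c

    def build(self) -> "CompiledModel":
        self.build_variables()
        self.add_separation_constraints()
        self.add_structural_constraints()
        self.add_demand_and_inventory()
        self.add_leftover_and_conservation()
        self.add_deviation_linearization()
        self.build_objective()
        return CompiledModel(self.inst, self.vars, self.rows, self.obj, self.obj_const)


@dataclass
class CompiledModel:
    instance: PlanningInstance
    vars: VariableIndex
    rows: list
    obj: np.ndarray
    obj_const: float

    def constraint_matrix(self):
        data, ri, ci = [], [], []
        lb, ub = [], []
        for r, row in enumerate(self.rows):
            for j, coef in row.coeffs.items():
                ri.append(r)
                ci.append(j)
                data.append(coef)
            lb.append(row.lb)
            ub.append(row.ub)
        A = sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(self.rows), self.vars.n)
        )
        return A, np.array(lb), np.array(ub)


@dataclass
class SolverOptions:
    """Backend-agnostic solve settings.

    mip_gap is the relative optimality gap; time_limit is wall seconds
    (None = no limit); backend selects the MILP engine ("highs" is the
    only one shipped).
    """

    mip_gap: float = 1e-4
    time_limit: Optional[float] = None
    backend: str = "highs"
    diagnose_infeasibility: bool = True


@dataclass
class Solution:
    """All decision-variable values plus diagnostics.

    alpha/beta are in days.  ``btw`` is the per-animal diagnostic
    max(0, x - R, D - x) in days (the penalty-free leeway actually used).
    """

    x: dict
    z: dict
    y: dict
    gamma: dict
    h: dict
    reqserv: dict
    remsold: dict
    reminv: dict
    alpha: dict
    beta: dict
    objective: float
    status: str
    solver_objective: float = float("nan")
    mip_gap: Optional[float] = None
    btw: dict = field(default_factory=dict)

    def slaughters(self) -> dict:
        """animal id -> (facility id, period, working hour), slaughtered only."""
        out = {}
        for (a, s, t), val in self.gamma.items():
            if val >= 0.5:
                out[a] = (s, t, self.x[(a, t)])
        return out

    def total_served(self) -> float:
        return sum(self.reqserv.values())

    def to_dict(self) -> dict:
        def pack(d):
            return [[list(k), v] for k, v in sorted(d.items())]

        return {
            "objective": self.objective,
            "status": self.status,
            "solver_objective": self.solver_objective,
            "mip_gap": self.mip_gap,
            "x": pack(self.x),
            "z": pack(self.z),
            "y": pack(self.y),
            "gamma": pack(self.gamma),
            "h": pack(self.h),
            "reqserv": pack(self.reqserv),
            "remsold": pack(self.remsold),
            "reminv": pack(self.reminv),
            "alpha": pack(self.alpha),
            "beta": pack(self.beta),
            "btw": pack(self.btw),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Solution":
        def unpack(rows):
            return {tuple(k): v for k, v in rows}

        return cls(
            x=unpack(d["x"]),
            z=unpack(d["z"]),
            y=unpack(d["y"]),
            gamma=unpack(d["gamma"]),
            h=unpack(d["h"]),
            reqserv=unpack(d["reqserv"]),
            remsold=unpack(d["remsold"]),
            reminv=unpack(d["reminv"]),
            alpha=unpack(d["alpha"]),
            beta=unpack(d["beta"]),
            objective=d["objective"],
            status=d["status"],
            solver_objective=d.get("solver_objective", float("nan")),
            mip_gap=d.get("mip_gap"),
            btw=unpack(d.get("btw", [])),
        )


def build_model(instance: PlanningInstance) -> CompiledModel:
    return MilpBuilder(instance).build()


def objective_value(instance: PlanningInstance, sol: Solution) -> float:
    """Evaluate the six-term objective Q directly from a solution's values."""
    inst, eco = instance, instance.economics
    q = 0.0
    for g in inst.products:
        for t in range(1, inst.n_periods + 1):
            q += sol.reqserv[(g.id, t)] * g.net_price
            q -= sol.h[(g.id, t)] * g.holding_cost
            q -= eco.loss_of_opportunity * (
                inst.requirement(g.id, t) - sol.reqserv[(g.id, t)]
            )
    q += sum(v * eco.live_price for v in sol.remsold.values())
    for a in inst.animals:
        t = a.maturity_period
        q -= sol.alpha[(a.id, t)] * eco.penalty_early_per_day
        q -= sol.beta[(a.id, t)] * eco.penalty_late_per_day
        for s in inst.facilities:
            q -= sol.gamma[(a.id, s.id, t)] * s.slaughter_cost
    return q


def _extract(instance: PlanningInstance, model: CompiledModel, xvec, status: str,
             solver_obj: float, gap: Optional[float]) -> Solution:
    inst = instance
    hpd = inst.economics.hours_per_day
    sol = {cls: {} for cls in
           ("x", "z", "y", "gamma", "h", "reqserv", "remsold", "reminv", "alpha", "beta")}
    for (cls, key), pos in model.vars.index.items():
        val = float(xvec[pos])
        if cls in BINARY_CLASSES:
            val = float(round(val))
        elif cls in ("h", "reqserv"):
            val = min(max(val, model.vars.lb[pos]), model.vars.ub[pos])
        sol[cls][key] = val
    by_id = {a.id: a for a in inst.animals}
    # tighten alpha/beta to their max() definitions and re-derive the affine
    # leftover quantities from the rounded gammas
    for a in inst.animals:
        t = a.maturity_period
        xval = sol["x"][(a.id, t)]
        sol["alpha"][(a.id, t)] = max(0.0, (a.ready_time - xval) / hpd)
        sol["beta"][(a.id, t)] = max(0.0, (xval - a.due_time) / hpd)
        for tt in range(3, inst.n_periods + 1):
            g_sum = (
                sum(
                    sol["gamma"][(a.id, s.id, tt - 2)]
                    for s in inst.facilities
                )
                if tt - 2 == t
                else 0.0
            )
            sol["remsold"][(a.id, tt)] = a.target_weight_lbs * (1.0 - g_sum)
        for tt in range(max(1, inst.n_periods - 1), inst.n_periods + 1):
            g_sum = (
                sum(sol["gamma"][(a.id, s.id, tt)] for s in inst.facilities)
                if tt == t
                else 0.0
            )
            sol["reminv"][(a.id, tt)] = a.target_weight_lbs * (1.0 - g_sum)
    btw = {}
    for a in inst.animals:
        t = a.maturity_period
        xval = sol["x"][(a.id, t)]
        btw[a.id] = max(0.0, xval - a.ready_time, a.due_time - xval) / hpd
    solution = Solution(
        **sol,
        objective=0.0,
        status=status,
        solver_objective=solver_obj,
        mip_gap=gap,
        btw=btw,
    )
    solution.objective = objective_value(inst, solution)
    return solution


def solve(
    instance: PlanningInstance,
    options: Optional[SolverOptions] = None,
    fixed: Optional[dict] = None,
) -> Solution:
    """Build and solve the model; returns an optimal (or best-found within
    the gap/time limits, flagged in ``status``) :class:`Solution`.

    ``fixed`` pins variables -- e.g. ``{("gamma", (aid, fid, t)): 1.0}`` --
    by collapsing their bounds; the batch baseline uses this to evaluate a
    prescribed schedule under the same demand/inventory logic.

    Raises :class:`InfeasibleModelError` on infeasibility, with the
    offending constraint families identified by relaxation probing when the
    model is small enough.
    """
    options = options or SolverOptions()
    if options.backend != "highs":
        raise EnvironmentError(f"unknown solver backend {options.backend!r}")
    model = build_model(instance)
    lb = np.array(model.vars.lb, dtype=float)
    ub = np.array(model.vars.ub, dtype=float)
    if fixed:
        for (cls, key), val in fixed.items():
            pos = model.vars[(cls, key)]
            lb[pos] = ub[pos] = val
    res = _run_highs(model, lb, ub, options)
    if res.status == 2:
        families = None
        if options.diagnose_infeasibility and len(model.rows) <= 20000:
            families = _probe_infeasibility(model, lb, ub, options)
        raise InfeasibleModelError(
            "model infeasible"
            + (f"; removing any of {families} restores feasibility" if families else ""),
            families,
        )
    if res.x is None:
        raise RuntimeError(f"solver failed: {res.message}")
    status = "optimal" if res.status == 0 else "feasible_limit"
    gap = getattr(res, "mip_gap", None)
    return _extract(instance, model, res.x, status, -float(res.fun) + model.obj_const, gap)


def _run_highs(model: CompiledModel, lb, ub, options: SolverOptions):
    A, clb, cub = model.constraint_matrix()
    kw = {"mip_rel_gap": options.mip_gap, "disp": False, "presolve": True}
    if options.time_limit is not None:
        kw["time_limit"] = options.time_limit
    return milp(
        c=-model.obj,
        constraints=LinearConstraint(A, clb, cub),
        integrality=np.array(model.vars.integrality),
        bounds=Bounds(lb, ub),
        options=kw,
    )


def _probe_infeasibility(model: CompiledModel, lb, ub, options: SolverOptions) -> list[str]:
    """Name constraint families whose removal restores feasibility."""
    families = sorted({r.family for r in model.rows})
    culprits = []
    for fam in families:
        keep = [r for r in model.rows if r.family != fam]
        probe = CompiledModel(model.instance, model.vars, keep, model.obj, model.obj_const)
        res = _run_highs(probe, lb, ub, SolverOptions(mip_gap=0.1, time_limit=30.0))
        if res.status != 2:
            culprits.append(fam)
    return culprits
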