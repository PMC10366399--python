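"""Exhaustive-enumeration oracle for tiny scheduling instances.

Independent of the model builder and the MILP solver: enumerates every
facility assignment and every slaughter-time combination on an integer-hour
grid, evaluates the demand/inventory allocation per period by the greedy
closed form of the single-resource allocation LP, and returns the best
objective.  Only valid for horizons of at most two periods (no inventory
carry-over or live-sale rows exist there) and integer-valued time data, for
which the continuous-time MILP attains its optimum on the grid.
"""

from __future__ import annotations

import itertools


def _timing_penalty(inst, animal, x: float) -> float:
    eco = inst.economics
    early = max(0.0, (animal.ready_time - x) / eco.hours_per_day)
    late = max(0.0, (x - animal.due_time) / eco.hours_per_day)
    return eco.penalty_early_per_day * early + eco.penalty_late_per_day * late


def _best_group_penalty(inst, group, grid_hours: int = 1):
    """Minimal total earliness/lateness penalty for animals sharing one
    facility and period, subject to pairwise separation; None if no grid
    point combination is feasible."""
    H = int(round(inst.horizon_hours))
    xs_range = range(0, H + 1, grid_hours)
    if len(group) == 1:
        return min(_timing_penalty(inst, group[0], x) for x in xs_range)
    seps = [inst.separation_hours(a) for a in group]
    best = None
    for xs in itertools.product(xs_range, repeat=len(group)):
        feasible = True
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                gap_ij = xs[j] - xs[i] >= seps[i] - 1e-9
                gap_ji = xs[i] - xs[j] >= seps[j] - 1e-9
                if not (gap_ij or gap_ji):
                    feasible = False
                    break
            if not feasible:
                break
        if not feasible:
            continue
        total = sum(_timing_penalty(inst, a, x) for a, x in zip(group, xs))
        if best is None or total < best:
            best = total
    return best


def _allocation_value(inst, supply: float, t: int):
    """Greedy optimum of distributing `supply` lbs over served demand and
    inventory sinks in period t (mandatory: the balance is an equality);
    None if the sinks cannot absorb the supply."""
    eco = inst.economics
    sinks = []
    for g in inst.products:
        sinks.append((g.net_price + eco.loss_of_opportunity, inst.served_cap(g, t)))
        sinks.append((-g.holding_cost, g.inventory_cap))
    sinks.sort(key=lambda wc: -wc[0])
    value, remaining = 0.0, supply
    for weight, cap in sinks:
        take = min(remaining, cap)
        value += weight * take
        remaining -= take
    if remaining > 1e-9:
        return None
    return value


def brute_force_optimum(inst, grid_hours: int = 1) -> float:
    """Best objective over all assignments and grid timings."""
    if inst.n_periods > 2:
        raise ValueError("oracle limited to horizons of <= 2 periods")
    eco = inst.economics
    constant = -eco.loss_of_opportunity * sum(
        inst.requirement(g.id, t)
        for g in inst.products
        for t in range(1, inst.n_periods + 1)
    )
    best = None
    options = [[None] + list(inst.facilities) for _ in inst.animals]
    for combo in itertools.product(*options):
        value = constant
        for a, s in zip(inst.animals, combo):
            if s is not None:
                value -= s.slaughter_cost
        feasible = True
        for t in range(1, inst.n_periods + 1):
            supply = sum(
                eco.edible_fraction * a.target_weight_lbs
                for a, s in zip(inst.animals, combo)
                if s is not None and abs(a.maturity_period - t) <= 1
            )
            alloc = _allocation_value(inst, supply, t)
            if alloc is None:
                feasible = False
                break
            value += alloc
        if not feasible:
            continue
        groups: dict = {}
        for a, s in zip(inst.animals, combo):
            if s is not None:
                groups.setdefault((s.id, a.maturity_period), []).append(a)
        for group in groups.values():
            pen = _best_group_penalty(inst, group, grid_hours)
            if pen is None:
                feasible = False
                break
            value -= pen
        if not feasible:
            continue
        if best is None or value > best:
            best = value
    if best is None:
        raise RuntimeError("no feasible assignment found by enumeration")
    return best
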