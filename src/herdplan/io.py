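"""File formats: herd and demand CSV, solution/savings JSON, Gantt CSV.

Every artifact embeds provenance (seed and configuration hash) -- as a
leading ``#`` comment line in CSVs, or as top-level keys in JSON documents
-- so a run can be traced back to the exact configuration that produced it.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd

from .growth import (
    AnimalRecord,
    GrowthParameters,
    Sex,
    draw_window_months,
    frame_score,
    months_to_working_hours,
    target_weight_from_fs,
)
from .instance import PlanningInstance
from .model import Solution
from .synthetic import DemandSeries

HERD_COLUMNS = ["id", "sex", "age_days", "hip_height_in"]
HERD_EXTRA_COLUMNS = [
    "measured_age_days",
    "frame_score",
    "target_weight_lbs",
    "ready_time",
    "due_time",
    "maturity_period",
]


def _provenance_line(seed: Optional[int], config_hash: Optional[str]) -> str:
    parts = ["# herdplan"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts)


def write_herd_csv(
    herd: list[AnimalRecord],
    path,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> None:
    """Write the roster; required columns first, derived columns after, so
    the file remains readable as the minimal four-column schema."""
    rows = []
    for a in herd:
        rows.append(
            {
                "id": a.id,
                "sex": a.sex.value,
                "age_days": a.age_days,
                "hip_height_in": a.hip_height_in,
                "measured_age_days": a.measured_age_days,
                "frame_score": a.frame_score,
                "target_weight_lbs": a.target_weight_lbs,
                "ready_time": a.ready_time,
                "due_time": a.due_time,
                "maturity_period": a.maturity_period,
            }
        )
    df = pd.DataFrame(rows, columns=HERD_COLUMNS + HERD_EXTRA_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed, config_hash) + "\n")
        df.to_csv(fh, index=False)


def read_herd_csv(
    path, params: Optional[GrowthParameters] = None, seed: int = 0
) -> list[AnimalRecord]:
    """Read a herd roster.

    Minimal files carry id, sex, age_days, hip_height_in; the frame score is
    then evaluated at ``measured_age_days`` (column or the configured
    default) and window/maturity columns, when absent, are drawn from the
    seeded distributions.
    """
    params = params or GrowthParameters()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in HERD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"herd CSV missing required columns {missing}")
    rng = np.random.default_rng(seed)
    herd = []
    for r in df.itertuples(index=False):
        sex = Sex(str(r.sex))
        meas = int(getattr(r, "measured_age_days", params.measurement_age_days))
        fs = (
            float(r.frame_score)
            if hasattr(r, "frame_score")
            else frame_score(sex, float(r.hip_height_in), meas, params)
        )
        twa = (
            float(r.target_weight_lbs)
            if hasattr(r, "target_weight_lbs")
            else target_weight_from_fs(fs, sex, params)
        )
        if hasattr(r, "ready_time") and hasattr(r, "due_time"):
            ready_h, due_h = float(r.ready_time), float(r.due_time)
        else:
            ready_m, due_m = draw_window_months(params, rng)
            ready_h = months_to_working_hours(ready_m, int(r.age_days), params)
            due_h = months_to_working_hours(due_m, int(r.age_days), params)
        if hasattr(r, "maturity_period"):
            mat = int(r.maturity_period)
        else:
            mat_age = float(
                np.clip(
                    rng.normal(
                        params.maturity_mean_months * params.days_per_month,
                        params.maturity_sd_months * params.days_per_month,
                    ),
                    params.window_min_months * params.days_per_month,
                    params.window_max_months * params.days_per_month,
                )
            )
            mat = int((mat_age - int(r.age_days)) // params.days_per_month) + 1
        herd.append(
            AnimalRecord(
                id=str(r.id),
                sex=sex,
                age_days=int(r.age_days),
                hip_height_in=float(r.hip_height_in),
                frame_score=fs,
                target_weight_lbs=twa,
                ready_time=ready_h,
                due_time=due_h,
                maturity_period=mat,
                measured_age_days=meas,
            )
        )
    return herd


def write_demand_csv(
    demand: DemandSeries,
    path,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed, config_hash) + "\n")
        demand.to_frame().to_csv(fh, index=False)


def read_demand_csv(path) -> DemandSeries:
    return DemandSeries.from_frame(pd.read_csv(path, comment="#"))


def write_solution_json(
    sol: Solution, path, seed: Optional[int] = None, config_hash: Optional[str] = None
) -> None:
    doc = sol.to_dict()
    doc["provenance"] = {"seed": seed, "config": config_hash}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_solution_json(path) -> Solution:
    with open(path) as fh:
        return Solution.from_dict(json.load(fh))


def write_gantt_csv(
    instance: PlanningInstance,
    sol: Solution,
    path,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> None:
    """Schedule table: one row per slaughtered animal with its facility,
    start working hour, calendar day and occupation duration."""
    hpd = instance.economics.hours_per_day
    rows = []
    by_id = {a.id: a for a in instance.animals}
    for aid, (fid, t, hour) in sorted(sol.slaughters().items()):
        a = by_id[aid]
        rows.append(
            {
                "animal": aid,
                "facility": fid,
                "period": t,
                "start_working_hour": hour,
                "calendar_day": int(hour // hpd) + 1,
                "duration_hours": instance.separation_hours(a),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "animal",
            "facility",
            "period",
            "start_working_hour",
            "calendar_day",
            "duration_hours",
        ],
    )
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed, config_hash) + "\n")
        df.to_csv(fh, index=False)
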