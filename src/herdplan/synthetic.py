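"""Seeded synthetic herds and demand series.

Emulates the statistical structure of a commercial Angus operation with a
steady maturation flow: ``cohort_size`` animals reach their expected
22-month maturity in every month of the raising horizon (90/month over 22
months = 1,980 head by default).  Hip heights are drawn per sex so frame
scores land in a realistic 2-8 band; ready/due windows come from the growth
module.  Demand per product and period is Gaussian with a fixed mean and
scenario-dependent variance, rounded to the nearest multiple of ten (the
pack size) and floored at zero.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .growth import (
    AnimalRecord,
    GrowthParameters,
    Sex,
    draw_window_months,
    frame_score,
    hip_height_for_frame_score,
    months_to_working_hours,
    target_weight_from_fs,
)

__all__ = ["HerdSpec", "DemandSeries", "generate_herd", "generate_demand", "round_to_ten"]

# Default hip-height draw (inches) at the 5-month measurement age, per sex.
# SYNTHETIC: chosen so default frame scores land around 5 +/- 1 (band 2-8);
# the paper-grade herd would use real measurements.
DEFAULT_HIP_HEIGHT_MEAN = {Sex.MALE: 41.5, Sex.FEMALE: 41.3}
DEFAULT_HIP_HEIGHT_SD = 1.5


@dataclass
class HerdSpec:
    """Shape of the synthetic herd.

    cohort_size animals mature in each of horizon_months consecutive months;
    sex_ratio is the fraction of steers (males).
    """

    cohort_size: int = 90
    horizon_months: int = 22
    sex_ratio: float = 0.5
    seed: int = 0
    hip_height_mean: dict = field(
        default_factory=lambda: dict(DEFAULT_HIP_HEIGHT_MEAN)
    )
    hip_height_sd: float = DEFAULT_HIP_HEIGHT_SD

    def __post_init__(self) -> None:
        if self.cohort_size < 1 or self.horizon_months < 1:
            raise ValueError("cohort_size and horizon_months must be >= 1")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")


def round_to_ten(x: float) -> int:
    """Round to the nearest multiple of ten, ties away from zero."""
    if x >= 0:
        return int(10 * np.floor(x / 10.0 + 0.5))
    return -round_to_ten(-x)


@dataclass
class DemandSeries:
    """Per-product, per-period demand Req_{g,t} in product units.

    Entries are non-negative integers divisible by ten (post pack-size
    rounding).  Stored as a mapping (product_id, period) -> units.
    """

    requirements: dict

    def __post_init__(self) -> None:
        for (g, t), v in self.requirements.items():
            if v < 0 or v % 10 != 0:
                raise ValueError(f"demand Req[{g},{t}]={v} must be >=0 and a multiple of 10")

    @property
    def products(self) -> list:
        return sorted({g for g, _ in self.requirements})

    @property
    def periods(self) -> list:
        return sorted({t for _, t in self.requirements})

    def __getitem__(self, key) -> int:
        return self.requirements[key]

    def total(self, product=None) -> int:
        return sum(
            v for (g, _), v in self.requirements.items() if product is None or g == product
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"product": g, "period": t, "units": v}
            for (g, t), v in sorted(self.requirements.items())
        ]
        return pd.DataFrame(rows, columns=["product", "period", "units"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DemandSeries":
        req = {
            (str(r.product), int(r.period)): int(r.units) for r in df.itertuples()
        }
        return cls(req)


def _draw_maturity_age_days(
    params: GrowthParameters, rng: np.random.Generator
) -> float:
    """Maturity age ~ N(22, 0.5) months, resampled into the 21-24 month band."""
    lo = params.window_min_months * params.days_per_month
    hi = params.window_max_months * params.days_per_month
    mu = params.maturity_mean_months * params.days_per_month
    sd = params.maturity_sd_months * params.days_per_month
    for _ in range(1000):
        m = rng.normal(mu, sd)
        if lo < m <= hi:
            return float(m)
    return float(mu)


def generate_herd(
    spec: HerdSpec, params: Optional[GrowthParameters] = None
) -> list[AnimalRecord]:
    """Generate ``cohort_size * horizon_months`` animals with staggered ages.

    Exactly ``cohort_size`` animals hit their expected maturity in each
    period: for cohort t the 22-month point is placed uniformly inside
    period t's 30-day span and the age at the reference date follows.  Hip
    heights are drawn at the standard measurement age (young cohorts carry
    their projected measurement); the frame score, target weight and
    finishing window are attached per animal.
    """
    params = params or GrowthParameters()
    rng = np.random.default_rng(spec.seed)
    animals: list[AnimalRecord] = []
    meas_age = params.measurement_age_days
    fs_domain = {
        sex: (min(tbl), max(tbl)) for sex, tbl in params.fs_weight_table.items()
    }
    for t in range(1, spec.horizon_months + 1):
        for k in range(spec.cohort_size):
            sex = Sex.MALE if rng.random() < spec.sex_ratio else Sex.FEMALE
            maturity_age = _draw_maturity_age_days(params, rng)
            # place the 22-month point inside period t, keep age >= 1 day
            max_offset = min(
                t * params.days_per_month,
                maturity_age - 1.0,
            )
            min_offset = (t - 1) * params.days_per_month
            if max_offset <= min_offset:
                max_offset = min_offset + 1e-9
            offset = rng.uniform(min_offset, max_offset)
            age_days = int(max(1, round(maturity_age - offset)))

            lo_fs, hi_fs = fs_domain[sex]
            for _ in range(1000):
                h = rng.normal(spec.hip_height_mean[sex], spec.hip_height_sd)
                fs = frame_score(sex, h, meas_age, params)
                if lo_fs <= fs <= hi_fs:
                    break
            else:  # pragma: no cover - degenerate configuration
                fs = 0.5 * (lo_fs + hi_fs)
                h = hip_height_for_frame_score(sex, fs, meas_age, params)
            twa = target_weight_from_fs(fs, sex, params)

            ready_m, due_m = draw_window_months(params, rng)
            ready_h = months_to_working_hours(ready_m, age_days, params)
            due_h = months_to_working_hours(due_m, age_days, params)
            animals.append(
                AnimalRecord(
                    id=f"A{t:02d}-{k:03d}",
                    sex=sex,
                    age_days=age_days,
                    hip_height_in=float(h),
                    frame_score=float(fs),
                    target_weight_lbs=float(twa),
                    ready_time=ready_h,
                    due_time=due_h,
                    maturity_period=t,
                    measured_age_days=meas_age,
                )
            )
    return animals


def generate_demand(
    mean: float,
    sd: float,
    n_products: int = 3,
    n_periods: int = 7,
    seed: int = 0,
    product_ids: Optional[Iterable[str]] = None,
) -> DemandSeries:
    """Gaussian(mean, sd) demand per product and period, rounded to tens.

    Negative draws are floored at zero before rounding; with sd = 0 every
    entry is exactly the (rounded) mean.
    """
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be non-negative")
    rng = np.random.default_rng(seed)
    ids = list(product_ids) if product_ids is not None else [
        f"P{i + 1}" for i in range(n_products)
    ]
    req = {}
    for g in ids:
        for t in range(1, n_periods + 1):
            draw = rng.normal(mean, sd) if sd > 0 else float(mean)
            req[(g, t)] = round_to_ten(max(0.0, draw))
    return DemandSeries(req)
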