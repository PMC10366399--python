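"""Per-animal growth biology: frame scores, target weights and finishing windows.

Beef cattle are scheduled for slaughter inside an animal-specific *finishing
window*.  The window is anchored on the animal's skeletal size, summarised by
its frame score (FS) -- a 1-9 index computed once from hip height and age that
stays constant for the rest of the animal's life.  The FS maps (per sex) to an
expected live weight at maturity (the target weight, ``TWA``), and the window
endpoints are the *ready time* (growth-rate slowdown, ~21.5 months of age for
Angus) and the *due time* (near-zero differential gain, ~23 months), both
modelled as Gaussian draws clamped into the 21-24 month band.

The module also carries the simple resource-accounting primitives used by the
savings report: a linear forage-intake function (24 lbs/day for a 1,200 lb
animal by default), a per-day enteric+manure methane rate (150 kg/yr default)
and the feed conversion ratio (FCR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Sex",
    "GrowthParameters",
    "AnimalRecord",
    "FcrUndefinedError",
    "frame_score",
    "target_weight_from_fs",
    "daily_forage_intake",
    "methane_rate_per_day",
    "fcr",
    "draw_window_months",
    "finishing_window",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class FcrUndefinedError(ValueError):
    """Raised when the feed conversion ratio is undefined (weight gain <= 0).

    A near-zero or negative differential gain is precisely the biological
    signal for the *due time*: past it, feeding the animal buys no weight,
    so the ratio is reported as undefined rather than as a huge float.
    """


# Frame-score regressions on hip height H (inches) and age A (days),
# valid from 5 to 21 months of age.  Coefficient order:
# (H, A, A^2, H*A, intercept).
FS_COEFFS_MALE = (0.4878, -0.0289, 0.00001947, 0.0000334, -11.548)
FS_COEFFS_FEMALE = (0.4723, -0.0239, 0.0000146, 0.0000759, -11.7086)

MIN_FS_AGE_DAYS = 5 * 30
MAX_FS_AGE_DAYS = 21 * 30

# Default FS -> mature live weight (lbs) mapping.  SYNTHETIC STUB: the official
# Beef Improvement Federation tables are not redistributed here; this table is
# monotone and spans a realistic Angus range so the pipeline runs end to end.
# Supply the official table through GrowthParameters.fs_weight_table for
# production use.
DEFAULT_FS_WEIGHT_TABLE = {
    Sex.MALE: {fs: 900.0 + 100.0 * (fs - 1) for fs in range(1, 10)},
    Sex.FEMALE: {fs: 800.0 + 100.0 * (fs - 1) for fs in range(1, 10)},
}


@dataclass
class GrowthParameters:
    """Biological and accounting constants for the herd.

    Parameters
    ----------
    intake_coeff
        lbs of as-fed forage per lb of live weight per day.  Default
        24/1200 = 0.02 (a 1,200 lb cow eats 24 lbs/day).
    dry_matter_fraction
        Dry-matter share of the forage (0.88 default); informational.
    methane_kg_per_cow_year
        Enteric (130) plus manure (20) methane per head per year.
    replacement_heifer_kg_year
        Extra methane attributed to the replacement heifer; itemised
        separately in the savings report, never folded into the main rate.
    edible_fraction
        Share of live body weight that is saleable meat (0.5).
    maturity_mean_months / maturity_sd_months
        Gaussian age at which the target weight is reached (22 +/- 0.5 mo).
    ready_* / due_*
        Gaussian window endpoints; draws are clamped into
        [window_min_months, window_max_months] = [21, 24].
    ready_weight_fraction
        Live weight at ready time as a fraction of the target weight; the
        within-window trajectory is linear from that point to TWA at due time
        and flat afterwards.
    measurement_age_days
        Age at which hip height is measured (five months by default); frame
        scores are evaluated at this age.
    days_per_month / working_hours_per_day
        Calendar convention: 30-day months, 8 working hours per day.
    """

    fs_coeffs_male: tuple = FS_COEFFS_MALE
    fs_coeffs_female: tuple = FS_COEFFS_FEMALE
    intake_coeff: float = 24.0 / 1200.0
    dry_matter_fraction: float = 0.88
    methane_kg_per_cow_year: float = 150.0
    replacement_heifer_kg_year: float = 58.0
    edible_fraction: float = 0.5
    maturity_mean_months: float = 22.0
    maturity_sd_months: float = 0.5
    ready_mean_months: float = 21.5
    ready_sd_months: float = 0.5
    due_mean_months: float = 23.0
    due_sd_months: float = 0.5
    window_min_months: float = 21.0
    window_max_months: float = 24.0
    min_window_gap_months: float = 0.1
    ready_weight_fraction: float = 0.97
    measurement_age_days: int = 150
    days_per_month: int = 30
    working_hours_per_day: float = 8.0
    fs_weight_table: dict = field(
        default_factory=lambda: {
            sex: dict(tbl) for sex, tbl in DEFAULT_FS_WEIGHT_TABLE.items()
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.edible_fraction <= 1.0):
            raise ValueError("edible_fraction must be in (0, 1]")
        if self.intake_coeff <= 0:
            raise ValueError("intake_coeff must be positive")
        if self.methane_kg_per_cow_year < 0:
            raise ValueError("methane rate must be non-negative")
        for sex, table in self.fs_weight_table.items():
            fss = sorted(table)
            weights = [table[f] for f in fss]
            if any(b < a for a, b in zip(weights, weights[1:])):
                raise ValueError(f"fs_weight_table for {sex} must be monotone")

    @property
    def hours_per_month(self) -> float:
        return self.days_per_month * self.working_hours_per_day

    def with_overrides(self, **kwargs) -> "GrowthParameters":
        return replace(self, **kwargs)


@dataclass
class AnimalRecord:
    """One animal's biology and scheduling window.

    ``ready_time`` / ``due_time`` are expressed in working hours on the
    planning timeline (period t spans ``[(t-1)*240, t*240)`` working hours
    with the 30-day / 8-hour convention); ``maturity_period`` is the 1-based
    period containing the animal's expected 22-month maturity.
    """

    id: str
    sex: Sex
    age_days: int
    hip_height_in: float
    frame_score: float
    target_weight_lbs: float
    ready_time: float
    due_time: float
    maturity_period: int
    measured_age_days: int = 150

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if self.target_weight_lbs <= 0:
            raise ValueError("target_weight_lbs must be positive")
        if not self.ready_time < self.due_time:
            raise ValueError("ready_time must precede due_time")


def _coeffs_for(sex: Sex, params: Optional[GrowthParameters]) -> tuple:
    params = params or GrowthParameters()
    sex = Sex(sex)
    return params.fs_coeffs_male if sex is Sex.MALE else params.fs_coeffs_female


def frame_score(
    sex: Sex | str,
    hip_height_in: float,
    age_days: float,
    params: Optional[GrowthParameters] = None,
) -> float:
    """Frame score from hip height (inches) and age (days).

    Valid only for ages of 5 to 21 months (150-630 days with 30-day months);
    outside that range the regression is not applicable and a ValueError is
    raised.  The score is computed once per animal (at measurement) and is
    treated as constant for the rest of its life.
    """
    if hip_height_in <= 0:
        raise ValueError("hip_height_in must be positive")
    if not (MIN_FS_AGE_DAYS <= age_days <= MAX_FS_AGE_DAYS):
        raise ValueError(
            f"frame score regression valid for ages {MIN_FS_AGE_DAYS}-"
            f"{MAX_FS_AGE_DAYS} days, got {age_days}"
        )
    c_h, c_a, c_a2, c_ha, intercept = _coeffs_for(sex, params)
    h, a = float(hip_height_in), float(age_days)
    return c_h * h + c_a * a + c_a2 * a * a + c_ha * h * a + intercept


def hip_height_for_frame_score(
    sex: Sex | str,
    fs: float,
    age_days: float,
    params: Optional[GrowthParameters] = None,
) -> float:
    """Invert the frame-score regression for hip height at a given age.

    Used by the synthetic herd generator to draw heights that land in a
    target FS band.  Linear in H, so the inversion is exact.
    """
    if not (MIN_FS_AGE_DAYS <= age_days <= MAX_FS_AGE_DAYS):
        raise ValueError("age outside frame-score validity range")
    c_h, c_a, c_a2, c_ha, intercept = _coeffs_for(sex, params)
    a = float(age_days)
    return (fs - c_a * a - c_a2 * a * a - intercept) / (c_h + c_ha * a)


def target_weight_from_fs(
    fs: float, sex: Sex | str, params: Optional[GrowthParameters] = None
) -> float:
    """Expected mature live weight (lbs) for a frame score, by sex.

    Linear interpolation between tabulated rows; monotone non-decreasing in
    FS.  Raises if the score falls outside the configured table's domain.
    """
    params = params or GrowthParameters()
    table = params.fs_weight_table[Sex(sex)]
    xs = sorted(table)
    if not (xs[0] <= fs <= xs[-1]):
        raise ValueError(
            f"frame score {fs} outside table domain [{xs[0]}, {xs[-1]}]"
        )
    ys = [table[x] for x in xs]
    return float(np.interp(fs, xs, ys))


def daily_forage_intake(
    live_weight_lbs: float, params: Optional[GrowthParameters] = None
) -> float:
    """As-fed forage intake (lbs/head/day), linear in live body weight."""
    if live_weight_lbs < 0:
        raise ValueError("live weight must be non-negative")
    params = params or GrowthParameters()
    return params.intake_coeff * live_weight_lbs


def methane_rate_per_day(params: Optional[GrowthParameters] = None) -> float:
    """Methane emission rate in kg/head/day (annual rate / 365)."""
    params = params or GrowthParameters()
    return params.methane_kg_per_cow_year / 365.0


def fcr(total_feed_lbs: float, weight_gain_lbs: float) -> float:
    """Feed conversion ratio: total feed used per unit of weight gained.

    Raises :class:`FcrUndefinedError` for non-positive gain -- the due-time
    condition -- instead of returning infinity.
    """
    if total_feed_lbs < 0:
        raise ValueError("total feed must be non-negative")
    if weight_gain_lbs <= 0:
        raise FcrUndefinedError(
            "FCR undefined for non-positive weight gain (due-time condition)"
        )
    return total_feed_lbs / weight_gain_lbs


def draw_window_months(
    params: GrowthParameters, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw (ready, due) in months of age.

    ready ~ N(21.5, 0.5) and due ~ N(23.0, 0.5), both clamped into the
    [21, 24] band, with due forced strictly above ready by at least
    ``min_window_gap_months``.  Note the clamp at 21 sits one sigma below the
    ready mean, so the clamped ready-time mean is ~21.54, not 21.50.
    """
    lo, hi = params.window_min_months, params.window_max_months
    gap = params.min_window_gap_months
    ready = float(np.clip(rng.normal(params.ready_mean_months, params.ready_sd_months), lo, hi - gap))
    due = float(np.clip(rng.normal(params.due_mean_months, params.due_sd_months), lo, hi))
    due = min(max(due, ready + gap), hi)
    return ready, due


def months_to_working_hours(
    age_months: float, age_days_at_reference: float, params: GrowthParameters
) -> float:
    """Working hour (on the planning timeline) at which an animal reaches
    ``age_months`` months of age, given its age at the reference date."""
    day = age_months * params.days_per_month - age_days_at_reference
    return day * params.working_hours_per_day


def finishing_window(
    animal_age_days: float,
    params: GrowthParameters,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw an animal's (ready_time, due_time) in planning working hours.

    Accepts either an age in days or an :class:`AnimalRecord`.  Hours can be
    negative for animals already past their ready age at the reference date;
    instance construction clips to the horizon.
    """
    if isinstance(animal_age_days, AnimalRecord):
        animal_age_days = animal_age_days.age_days
    ready_m, due_m = draw_window_months(params, rng)
    ready_h = months_to_working_hours(ready_m, animal_age_days, params)
    due_h = months_to_working_hours(due_m, animal_age_days, params)
    return ready_h, due_h


def clamped_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """Closed-form mean of clip(N(mu, sd), lo, hi).

    Independent reference for the Monte-Carlo window tests:
    E[clip(X)] = mu + sd*(phi(a) - phi(b)) + (lo-mu)*Phi(a) + (hi-mu)*(1-Phi(b))
    with a, b the standardised bounds.
    """
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    phi = lambda z: math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    Phi = lambda z: 0.5 * (1 + math.erf(z / math.sqrt(2)))
    return mu + sd * (phi(a) - phi(b)) + (lo - mu) * Phi(a) + (hi - mu) * (1 - Phi(b))
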