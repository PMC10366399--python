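"""Frame scores, target weights, intake, methane, FCR and finishing windows."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from herdplan.growth import (
    FcrUndefinedError,
    GrowthParameters,
    Sex,
    daily_forage_intake,
    draw_window_months,
    fcr,
    frame_score,
    hip_height_for_frame_score,
    methane_rate_per_day,
    target_weight_from_fs,
)


class TestFrameScore:
    @pytest.mark.parametrize(
        "sex,expected",
        [("male", 2.997), ("female", 4.013)],
    )
    def test_regression_spot_values(self, sex, expected):
        assert frame_score(sex, 45.0, 365) == pytest.approx(expected, abs=1e-3)

    @given(
        h=st.floats(min_value=30, max_value=60),
        a=st.integers(min_value=150, max_value=630),
        sex=st.sampled_from(["male", "female"]),
    )
    def test_strictly_increasing_in_height(self, h, a, sex):
        assert frame_score(sex, h + 1.0, a) > frame_score(sex, h, a)

    @pytest.mark.parametrize("age", [100, 149, 631, 900])
    def test_age_outside_validity_range_errors(self, age):
        with pytest.raises(ValueError):
            frame_score("male", 45.0, age)

    def test_unknown_sex_errors(self):
        with pytest.raises(ValueError):
            frame_score("ox", 45.0, 365)

    @given(
        fs=st.floats(min_value=1, max_value=9),
        a=st.integers(min_value=150, max_value=630),
        sex=st.sampled_from(["male", "female"]),
    )
    def test_height_inversion_roundtrip(self, fs, a, sex):
        h = hip_height_for_frame_score(sex, fs, a)
        assert frame_score(sex, h, a) == pytest.approx(fs, abs=1e-9)


class TestTargetWeight:
    def test_boundary_lookup(self):
        p = GrowthParameters()
        lo = min(p.fs_weight_table[Sex.MALE])
        assert target_weight_from_fs(lo, "male", p) == p.fs_weight_table[Sex.MALE][lo]

    def test_midpoint_is_mean_of_neighbours(self):
        p = GrowthParameters()
        tbl = p.fs_weight_table[Sex.FEMALE]
        w = target_weight_from_fs(4.5, "female", p)
        assert w == pytest.approx(0.5 * (tbl[4] + tbl[5]))

    @given(
        fs1=st.floats(min_value=1, max_value=9),
        fs2=st.floats(min_value=1, max_value=9),
    )
    def test_monotone_in_frame_score(self, fs1, fs2):
        if fs1 > fs2:
            fs1, fs2 = fs2, fs1
        assert target_weight_from_fs(fs2, "male") >= target_weight_from_fs(fs1, "male")

    def test_outside_table_domain_errors(self):
        with pytest.raises(ValueError):
            target_weight_from_fs(0.5, "male")


class TestIntakeAndMethane:
    def test_reference_cow(self):
        assert daily_forage_intake(1200.0) == pytest.approx(24.0)

    def test_zero_and_linearity(self):
        assert daily_forage_intake(0.0) == 0.0
        assert daily_forage_intake(600.0) == pytest.approx(12.0)

    @given(w=st.floats(min_value=0, max_value=3000), k=st.floats(min_value=0.1, max_value=5))
    def test_homogeneous_degree_one(self, w, k):
        assert daily_forage_intake(k * w) == pytest.approx(k * daily_forage_intake(w))

    def test_negative_weight_errors(self):
        with pytest.raises(ValueError):
            daily_forage_intake(-1.0)

    def test_methane_rate(self):
        assert methane_rate_per_day() == pytest.approx(150.0 / 365.0, abs=1e-9)
        assert methane_rate_per_day(GrowthParameters(methane_kg_per_cow_year=0)) == 0.0
        assert methane_rate_per_day(GrowthParameters(methane_kg_per_cow_year=365)) == 1.0


class TestFcr:
    def test_ratio_and_zero_feed(self):
        assert fcr(600.0, 100.0) == pytest.approx(6.0)
        assert fcr(0.0, 50.0) == 0.0

    @pytest.mark.parametrize("gain", [0.0, -5.0])
    def test_non_positive_gain_is_undefined(self, gain):
        with pytest.raises(FcrUndefinedError):
            fcr(500.0, gain)


class TestFinishingWindow:
    def test_ordering_and_band(self):
        p = GrowthParameters()
        rng = np.random.default_rng(7)
        for _ in range(500):
            ready, due = draw_window_months(p, rng)
            assert ready < due
            assert p.window_min_months <= ready <= due <= p.window_max_months

    def test_seeded_draws_are_reproducible(self):
        p = GrowthParameters()
        a = [draw_window_months(p, np.random.default_rng(3)) for _ in range(10)]
        b = [draw_window_months(p, np.random.default_rng(3)) for _ in range(10)]
        assert a == b

    def test_ready_mean_matches_clamped_normal(self):
        # clamping N(21.5, 0.5) into the window band shifts the mean to
        # mu + sd*(phi(a)-phi(b)) + (lo-mu)*Phi(a) + (hi-mu)*(1-Phi(b))
        p = GrowthParameters()
        lo = p.window_min_months
        hi = p.window_max_months - p.min_window_gap_months
        a = (lo - p.ready_mean_months) / p.ready_sd_months
        b = (hi - p.ready_mean_months) / p.ready_sd_months
        expected = (
            p.ready_mean_months
            + p.ready_sd_months * (norm.pdf(a) - norm.pdf(b))
            + (lo - p.ready_mean_months) * norm.cdf(a)
            + (hi - p.ready_mean_months) * (1 - norm.cdf(b))
        )
        rng = np.random.default_rng(123)
        draws = [draw_window_months(p, rng)[0] for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(expected, abs=0.02)
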