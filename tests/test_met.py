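"""MET table, intensity classification and occupational energy expenditure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metshift import (
    EEAssumptions,
    EmploymentSeries,
    Gender,
    Intensity,
    Sector,
    activity_trend,
    classify_intensity,
    daily_occupational_ee,
    mean_met,
)
from metshift.errors import ConfigurationError, DomainError
from metshift.met import category_prevalence

SETTINGS = settings(max_examples=50, derandomize=True, deadline=None)


class TestMetTable:
    def test_covers_all_sectors_once(self, met_table):
        assert len(met_table) == 11
        assert {e.sector for e in met_table} == set(Sector)

    @pytest.mark.parametrize(
        "sector,median,lo,hi,category",
        [
            (Sector.CONSTRUCTION, 4.0, 1.5, 7.5, Intensity.MODERATE),
            (Sector.INFORMATION, 1.5, 1.5, 1.5, Intensity.SEDENTARY),
            (Sector.FARM, 3.0, 2.5, 4.5, Intensity.MODERATE),
            (Sector.MANUFACTURING, 3.0, 1.5, 4.0, Intensity.MODERATE),
            (Sector.TRADE_TRANSPORT_UTILITIES, 2.0, 1.5, 3.0, Intensity.LIGHT),
            (Sector.EDUCATION_HEALTH, 2.5, 1.5, 4.0, Intensity.LIGHT),
        ],
    )
    def test_published_assignments(self, met_table, sector, median, lo, hi, category):
        entry = next(e for e in met_table if e.sector is sector)
        assert (entry.met_median, entry.met_min, entry.met_max) == (median, lo, hi)
        assert entry.category is category

    def test_categories_consistent_with_medians(self, met_table):
        for e in met_table:
            assert e.category is classify_intensity(e.met_median)


class TestClassifyIntensity:
    @pytest.mark.parametrize(
        "met,expected",
        [
            (1.5, Intensity.SEDENTARY),
            (1.9999, Intensity.SEDENTARY),
            (2.0, Intensity.LIGHT),
            (2.5, Intensity.LIGHT),
            (2.9999, Intensity.LIGHT),
            (3.0, Intensity.MODERATE),
            (5.9, Intensity.MODERATE),
        ],
    )
    def test_half_open_boundaries(self, met, expected):
        assert classify_intensity(met) is expected

    @pytest.mark.parametrize("met", [0.0, -1.0, 6.0, 8.0])
    def test_out_of_domain(self, met):
        with pytest.raises(DomainError):
            classify_intensity(met)


class TestMeanMet:
    def test_single_sector(self, met_table):
        assert mean_met({Sector.MANUFACTURING: 1.0}, met_table) == 3.0

    def test_two_sector_weighted_mean(self, met_table):
        # 0.5 * 4.0 (construction) + 0.5 * 1.5 (financial)
        got = mean_met({Sector.CONSTRUCTION: 0.5, Sector.FINANCIAL: 0.5}, met_table)
        assert got == pytest.approx(2.75, abs=1e-12)

    def test_matches_dot_product_oracle(self, met_table, noiseless_series):
        from metshift import sector_prevalence

        prev = sector_prevalence(noiseless_series, 1960)
        medians = {e.sector: e.met_median for e in met_table}
        oracle = float(
            np.dot([prev[s] for s in Sector], [medians[s] for s in Sector])
        )
        assert mean_met(prev, met_table) == pytest.approx(oracle, abs=1e-12)

    def test_missing_sector_is_configuration_error(self, met_table):
        short = [e for e in met_table if e.sector is not Sector.FARM]
        with pytest.raises(ConfigurationError, match="farm"):
            mean_met({Sector.FARM: 1.0}, short)

    @SETTINGS
    @given(shift=st.floats(min_value=0.0, max_value=0.3))
    def test_shifting_mass_to_sedentary_never_raises_mean(self, met_table, shift):
        """Replacing moderate-sector mass with sedentary mass cannot raise the mean."""
        base = {s: 1.0 / 11 for s in Sector}
        moved = dict(base)
        moved[Sector.CONSTRUCTION] = base[Sector.CONSTRUCTION] - shift / 2
        moved[Sector.MANUFACTURING] = base[Sector.MANUFACTURING] - shift / 2
        moved[Sector.INFORMATION] = base[Sector.INFORMATION] + shift
        assert mean_met(moved, met_table) <= mean_met(base, met_table) + 1e-12


class TestDailyEE:
    def test_unit_met_reference_weight(self):
        assert daily_occupational_ee(1.0, EEAssumptions(), Gender.MEN) == pytest.approx(
            615.2
        )

    def test_arithmetic_oracle(self):
        got = daily_occupational_ee(2.57, EEAssumptions(), Gender.WOMEN)
        assert got == pytest.approx(8.0 * 2.57 * 64.9, abs=1e-9)

    def test_nonpositive_met_rejected(self):
        with pytest.raises(DomainError):
            daily_occupational_ee(0.0)

    def test_unknown_gender_rejected(self):
        with pytest.raises(ValueError):
            daily_occupational_ee(2.0, EEAssumptions(), "children")

    @SETTINGS
    @given(
        a=st.floats(min_value=0.1, max_value=3.0),
        met=st.floats(min_value=0.5, max_value=5.9),
        hours=st.floats(min_value=1.0, max_value=12.0),
        weight=st.floats(min_value=40.0, max_value=120.0),
    )
    def test_degree_one_homogeneity(self, a, met, hours, weight):
        """EE is linear in each of hours, mean MET, and body weight."""
        base = EEAssumptions(
            hours_per_workday=hours,
            reference_weight_kg={Gender.MEN: weight, Gender.WOMEN: weight},
        )
        scaled_weight = EEAssumptions(
            hours_per_workday=hours,
            reference_weight_kg={Gender.MEN: a * weight, Gender.WOMEN: a * weight},
        )
        e0 = daily_occupational_ee(met, base, Gender.MEN)
        assert daily_occupational_ee(a * met, base, Gender.MEN) == pytest.approx(a * e0)
        assert daily_occupational_ee(met, scaled_weight, Gender.MEN) == pytest.approx(
            a * e0
        )


class TestActivityTrend:
    def test_single_sector_year(self):
        series = EmploymentSeries({(1975, Sector.MANUFACTURING): 100.0})
        [row] = activity_trend(series)
        assert row.mean_met == 3.0
        assert row.category_prevalence[Intensity.MODERATE] == 1.0
        assert row.daily_ee_kcal[Gender.MEN] == pytest.approx(8 * 3.0 * 76.9)

    def test_anchored_moderate_share_endpoints(self, noiseless_trend):
        """Moderate-intensity share runs from 48% (1960) down to 20% (2008)."""
        first, last = noiseless_trend[0], noiseless_trend[-1]
        assert first.year == 1960 and last.year == 2008
        assert first.category_prevalence[Intensity.MODERATE] == pytest.approx(0.48, abs=0.005)
        assert last.category_prevalence[Intensity.MODERATE] == pytest.approx(0.20, abs=0.005)

    def test_gender_ee_ratio_is_weight_ratio(self, noiseless_trend):
        for row in noiseless_trend[:: len(noiseless_trend) // 4]:
            assert row.daily_ee_kcal[Gender.MEN] == pytest.approx(
                row.daily_ee_kcal[Gender.WOMEN] * 76.9 / 64.9, abs=1e-9
            )

    def test_category_prevalence_aggregates_sector_prevalence(
        self, noiseless_series, met_table, noiseless_trend
    ):
        from metshift import sector_prevalence

        cats = {e.sector: e.category for e in met_table}
        for row in noiseless_trend:
            prev = sector_prevalence(noiseless_series, row.year)
            for cat in Intensity:
                expected = sum(p for s, p in prev.items() if cats[s] is cat)
                assert row.category_prevalence[cat] == expected  # exact aggregation

    def test_category_prevalence_sums_to_one(self, noiseless_trend):
        for row in noiseless_trend:
            assert sum(row.category_prevalence.values()) == pytest.approx(1.0, abs=1e-9)

    def test_mean_met_bounded_by_table_medians(self, noiseless_trend, met_table):
        lo = min(e.met_median for e in met_table)
        hi = max(e.met_median for e in met_table)
        for row in noiseless_trend:
            assert lo <= row.mean_met <= hi


def test_category_prevalence_helper_matches_manual(met_table):
    prev = {s: 1.0 / 11 for s in Sector}
    out = category_prevalence(prev, met_table)
    assert out[Intensity.MODERATE] == pytest.approx(4 / 11)
    assert out[Intensity.SEDENTARY] == pytest.approx(3 / 11)
    assert out[Intensity.LIGHT] == pytest.approx(4 / 11)
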