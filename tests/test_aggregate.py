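"""Rollups, summary ratios, temporal change, and rankings.

The published national tables double as arithmetic oracles here: the
affected-population row is an exact integer sum of the five
non-overlapping endpoint rows, and the total-loss row is an exact sum of
all-cause mortality plus the four morbidity rows.
"""

import numpy as np
import pandas as pd
import pytest

from aqburden import reference
from aqburden.aggregate import (
    losses_to_frame,
    mean_annual_decline,
    rank_cities,
    rollup,
    summary_stats,
    yoy_changes,
)
from aqburden.endpoints import AFFECTED_TOTAL_ENDPOINTS
from aqburden.errors import AggregationError
from aqburden.exposure import impact_table
from aqburden.panel import CityPanel
from aqburden.valuation import loss_table, unit_cost_table


@pytest.fixture()
def both_bound_losses(small_synth_panel, endpoints, params):
    impacts = impact_table(small_synth_panel, endpoints, params)
    return pd.concat(
        [
            loss_table(
                impacts, unit_cost_table(small_synth_panel, endpoints, b, params)
            )
            for b in ("lower_AHC", "upper_VSL")
        ],
        ignore_index=True,
    )


class TestRollup:
    def test_total_is_mortality_plus_morbidity(
        self, both_bound_losses, endpoints
    ):
        city, national = rollup(both_bound_losses, endpoints)
        for r in city + national:
            assert r.ec_total == r.ec_mortality + r.ec_morbidity

    def test_cause_specific_mortality_reported_but_excluded_from_total(
        self, both_bound_losses, endpoints
    ):
        _, national = rollup(both_bound_losses, endpoints)
        r = national[0]
        assert "lung_cancer_mortality" in r.ec_by_endpoint
        included = r.ec_mortality + r.ec_morbidity
        everything = sum(r.ec_by_endpoint.values())
        assert everything > included  # cause-specific rows carry value

    def test_national_equals_sum_of_cities(self, both_bound_losses, endpoints):
        city, national = rollup(both_bound_losses, endpoints)
        for nat in national:
            total = sum(
                c.ec_total
                for c in city
                if c.year == nat.year and c.bound == nat.bound
            )
            assert nat.ec_total == pytest.approx(total, rel=1e-9)

    def test_affected_population_spans_five_endpoints(
        self, both_bound_losses, endpoints
    ):
        _, national = rollup(both_bound_losses, endpoints)
        flagged = set(endpoints.affected_total_names)
        grp = both_bound_losses[
            (both_bound_losses["bound"] == "upper_VSL")
            & both_bound_losses["endpoint"].isin(flagged)
        ]
        expected = grp.groupby("year")["attributable_cases"].sum()
        for r in national:
            assert r.affected_population == pytest.approx(
                expected.loc[r.year], rel=1e-9
            )

    def test_missing_endpoint_raises_named_gap(self, both_bound_losses, endpoints):
        broken = both_bound_losses.drop(both_bound_losses.index[0])
        with pytest.raises(AggregationError, match="missing endpoint"):
            rollup(broken, endpoints)

    def test_all_zero_losses_give_zero_total(
        self, small_synth_panel, endpoints, params
    ):
        frame = small_synth_panel.frame.copy()
        frame["concentration"] = params.baseline_concentration
        panel = CityPanel(frame)
        impacts = impact_table(panel, endpoints, params)
        losses = loss_table(
            impacts, unit_cost_table(panel, endpoints, "upper_VSL", params)
        )
        _, national = rollup(losses, endpoints)
        assert all(r.ec_total == 0.0 for r in national)

    def test_row_order_invariance(self, both_bound_losses, endpoints):
        shuffled = both_bound_losses.sample(frac=1.0, random_state=5)
        a = losses_to_frame(rollup(both_bound_losses, endpoints)[1])
        b = losses_to_frame(rollup(shuffled, endpoints)[1])
        pd.testing.assert_frame_equal(a, b)


class TestPublishedTableIdentities:
    def test_affected_population_is_sum_of_partition_rows(self):
        table = reference.national_health_impacts()
        partition = table.loc[sorted(AFFECTED_TOTAL_ENDPOINTS)]
        for year in (2014, 2015, 2016):
            assert partition[year].sum() == table.loc[reference.AFFECTED_ROW, year]

    def test_total_loss_is_all_cause_plus_morbidity(self):
        # component rows are printed at 2 decimals, so the identity holds
        # within the stacked rounding of five components (±0.025); the
        # 2016 lower-bound column is a known inconsistency in the printed
        # table (components sum to 267.57 against a printed 267.38)
        losses = reference.national_losses()
        rows = [
            "all_cause_mortality",
            "cardiovascular_hospitalization",
            "chronic_bronchitis",
            "acute_bronchitis",
            "asthma_attack",
        ]
        for col in losses.columns:
            residual = losses.loc[rows, col].sum() - losses.loc[reference.TEL_ROW, col]
            if col == (2016, "lower_AHC"):
                assert residual == pytest.approx(0.19, abs=0.005)
            else:
                assert abs(residual) <= 0.025


class TestSummaryStats:
    def test_published_2014_ratios(self):
        losses = reference.national_losses()
        tel_ahc = losses.loc[reference.TEL_ROW, (2014, "lower_AHC")]
        tel_vsl = losses.loc[reference.TEL_ROW, (2014, "upper_VSL")]
        assert round(100 * tel_ahc / tel_vsl) == 26
        mort_vsl = losses.loc["all_cause_mortality", (2014, "upper_VSL")]
        assert round(100 * mort_vsl / tel_vsl) == 95
        mort_ahc = losses.loc["all_cause_mortality", (2014, "lower_AHC")]
        assert 100 * mort_ahc / tel_ahc >= 80

    def test_equal_bounds_ratio_is_one(self, small_synth_panel, endpoints, params):
        impacts = impact_table(small_synth_panel, endpoints, params)
        upper = loss_table(
            impacts, unit_cost_table(small_synth_panel, endpoints, "upper_VSL", params)
        )
        mirrored = upper.copy()
        mirrored["bound"] = "lower_AHC"
        _, national = rollup(pd.concat([upper, mirrored]), endpoints)
        stats = summary_stats(national)
        assert np.allclose(stats["ahc_vsl_ratio"], 1.0)

    def test_pipeline_summary_has_both_bounds_and_sane_ratios(
        self, both_bound_losses, endpoints, small_synth_panel
    ):
        gdp = small_synth_panel.gdp_total_by_year()
        _, national = rollup(both_bound_losses, endpoints, gdp)
        stats = summary_stats(national, gdp)
        assert set(stats["year"]) == {2014, 2015, 2016}
        assert ((stats["ahc_vsl_ratio"] > 0) & (stats["ahc_vsl_ratio"] < 1)).all()
        assert stats["tel_gdp_ratio_upper_VSL"].notna().all()

    def test_missing_bound_is_an_error(self, both_bound_losses, endpoints):
        _, national = rollup(both_bound_losses, endpoints)
        only_upper = [r for r in national if r.bound == "upper_VSL"]
        with pytest.raises(AggregationError):
            summary_stats(only_upper)


class TestYoyChanges:
    def test_published_mortality_trend_truncates_to_11_8(self):
        table = reference.national_health_impacts()
        series = table.loc["all_cause_mortality", [2014, 2015, 2016]]
        # integer-arithmetic oracle for the two year-over-year declines
        d1 = 100 * (278_444 - 238_622) / 278_444
        d2 = 100 * (238_622 - 216_164) / 238_622
        assert d1 == pytest.approx(14.3016, abs=5e-5)
        assert d2 == pytest.approx(9.4115, abs=5e-5)
        assert mean_annual_decline(series) == 11.8
        assert mean_annual_decline(series, truncate_decimals=None) == pytest.approx(
            (d1 + d2) / 2
        )

    def test_constant_series_zero_changes(self):
        frame = pd.DataFrame({"year": [2014, 2015, 2016], "v": [5.0, 5.0, 5.0]})
        out = yoy_changes(frame, "v")
        assert (out["percent_change"] == 0.0).all()
        assert (out["absolute_change"] == 0.0).all()

    def test_single_year_gives_empty_table(self):
        frame = pd.DataFrame({"year": [2014], "v": [5.0]})
        assert yoy_changes(frame, "v").empty

    def test_opposite_trends_keep_signs_per_group(self):
        frame = pd.DataFrame(
            {
                "city": ["up", "up", "down", "down"],
                "year": [2014, 2015, 2014, 2015],
                "v": [10.0, 12.0, 10.0, 8.0],
            }
        )
        out = yoy_changes(frame, "v", ("city",)).set_index("city")
        assert out.loc["up", "percent_change"] == pytest.approx(20.0)
        assert out.loc["down", "percent_change"] == pytest.approx(-20.0)


class TestRankCities:
    def test_dominant_city_ranks_first(self, endpoints, params):
        rows = [
            ("big", 2014, 90.0, 10_000_000, 3000.0, 8000.0),
            ("small_a", 2014, 45.0, 1_000_000, 3000.0, 8000.0),
            ("small_b", 2014, 45.0, 1_000_000, 3000.0, 8000.0),
        ]
        panel = CityPanel(
            pd.DataFrame(
                rows,
                columns=[
                    "city_id", "year", "concentration",
                    "population", "income", "gdp_per_capita",
                ],
            )
        )
        impacts = impact_table(panel, endpoints, params)
        losses = loss_table(
            impacts, unit_cost_table(panel, endpoints, "upper_VSL", params)
        )
        city, _ = rollup(losses, endpoints)
        ranking = rank_cities(city, bound="upper_VSL")
        assert ranking.iloc[0]["city_id"] == "big"
        # identical cities tie; lexicographic order breaks the tie
        assert list(ranking["city_id"][1:]) == ["small_a", "small_b"]

    def test_matches_sort_oracle(self, both_bound_losses, endpoints):
        city, _ = rollup(both_bound_losses, endpoints)
        ranking = rank_cities(city, bound="upper_VSL")
        totals = {}
        for r in city:
            if r.bound == "upper_VSL":
                totals[r.scope] = totals.get(r.scope, 0.0) + r.ec_total
        oracle = sorted(totals, key=lambda c: (-totals[c], c))
        assert list(ranking["city_id"]) == oracle

    def test_invariant_to_input_order(self, both_bound_losses, endpoints):
        city, _ = rollup(both_bound_losses, endpoints)
        a = rank_cities(city, bound="lower_AHC")
        b = rank_cities(list(reversed(city)), bound="lower_AHC")
        pd.testing.assert_frame_equal(a, b)
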