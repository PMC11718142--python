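"""Water-balance surrogate: bucket arithmetic oracle, protocol contracts, bounds."""

import numpy as np
import pytest

from nlossrisk.synthetic import ScenarioConfig, generate_climate, soil_archetype
from nlossrisk.transport import (
    ClimateSeries,
    SlopeClass,
    SoilLayer,
    SoilProfile,
    TransportProtocolConfig,
    build_transport_table,
    monthly_transport_risk,
    simulate_water_balance,
)

from conftest import make_climate, random_soil, single_layer_profile


class TestSlopeClass:
    @pytest.mark.parametrize(
        "degrees,expected",
        [
            (0.0, SlopeClass.FLAT),
            (7.0, SlopeClass.FLAT),
            (7.1, SlopeClass.ROLLING),
            (15.0, SlopeClass.ROLLING),
            (15.1, SlopeClass.EASY),
            (25.0, SlopeClass.EASY),
            (25.1, SlopeClass.STEEP),
            (60.0, SlopeClass.STEEP),
        ],
    )
    def test_classification_total_and_unambiguous(self, degrees, expected):
        assert SlopeClass.from_degrees(degrees) is expected

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            SlopeClass.from_degrees(-1.0)


class TestSoilTypes:
    def test_layer_ordering_enforced(self):
        with pytest.raises(ValueError, match="wilting"):
            SoilLayer(100, 0.3, 0.35, 0.1, 0.5)  # fc > sat

    def test_profile_shallower_than_accounting_depth_rejected(self):
        shallow = SoilProfile("s", (SoilLayer(500, 0.4, 0.3, 0.1, 0.5),), 0.2)
        clim = make_climate(np.zeros(800))
        with pytest.raises(ValueError, match="accounting depth"):
            simulate_water_balance(shallow, clim)

    def test_negative_climate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_climate([-1.0, 0.0])

    def test_non_contiguous_dates_rejected(self):
        import pandas as pd

        dates = pd.DatetimeIndex(["2000-01-01", "2000-01-03"])
        with pytest.raises(ValueError, match="contiguous"):
            ClimateSeries(dates, np.zeros(2), np.zeros(2))


class TestWaterBalance:
    def test_zero_rain_gives_zero_runoff_and_drainage(self):
        soil = single_layer_profile()
        wb = simulate_water_balance(soil, make_climate(np.zeros(40)))
        assert np.all(wb.runoff_mm == 0)
        assert np.all(wb.drainage_mm == 0)

    def test_five_day_bucket_matches_hand_computation(self):
        # single 1000 mm layer (sat/fc/wp = 400/300/100 mm), k = 0.5, curve = 0.2,
        # start at field capacity, 50 mm rain on day 0, PET 0; values computed by
        # hand with exact rational arithmetic
        soil = single_layer_profile(k=0.5, curve=0.2)
        wb = simulate_water_balance(soil, make_climate([50, 0, 0, 0, 0]))
        np.testing.assert_allclose(wb.runoff_mm[0], 6.666666666666667, rtol=1e-12)
        np.testing.assert_allclose(
            wb.drainage_mm[:, -1],
            [21.666666666666668, 10.833333333333334, 5.416666666666667,
             2.7083333333333335, 1.3541666666666667],
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            wb.storage_mm,
            [321.6666666666667, 310.8333333333333, 305.4166666666667,
             302.7083333333333, 301.3541666666667],
            rtol=1e-12,
        )

    def test_full_drainage_coefficient_returns_storage_to_field_capacity(self):
        # k = 1: everything above field capacity leaves within the day
        soil = single_layer_profile(k=1.0)
        wb = simulate_water_balance(soil, make_climate([50, 0, 0]))
        total_out = wb.runoff_mm.sum() + wb.drainage_mm[:, -1].sum()
        assert total_out == pytest.approx(50.0, abs=1e-9)
        assert wb.storage_mm[-1] == pytest.approx(300.0, abs=1e-9)

    def test_mass_balance_closes_daily(self, rng):
        cfg = ScenarioConfig(seed=7, n_years=3)
        clim = generate_climate(cfg, np.random.default_rng(7))
        for name in ("stony_shallow", "deep_fine", "intermediate"):
            soil = soil_archetype(name)
            wb = simulate_water_balance(soil, clim, irrigated=True)
            res = wb.mass_balance_residual(clim.rain_mm, sum(l.fc_mm for l in soil.layers))
            assert np.abs(res).max() < 1e-6

    def test_irrigation_keeps_storage_above_trigger_in_dry_summer(self):
        # bone-dry January: irrigation must hold plant-available water at or
        # above the 50% refill trigger at the end of every day
        soil = single_layer_profile()
        clim = make_climate(np.zeros(60), pet=np.full(60, 6.0), start="2001-01-01")
        wb = simulate_water_balance(soil, clim, irrigated=True)
        wp_tot, fc_tot = 100.0, 300.0
        trigger = wp_tot + 0.5 * (fc_tot - wp_tot)
        assert wb.storage_mm.min() >= trigger - 1e-9
        assert wb.irrigation_mm.sum() > 0

    def test_runoff_only_on_rain_days(self, rng):
        clim = generate_climate(ScenarioConfig(seed=3, n_years=3), np.random.default_rng(3))
        wb = simulate_water_balance(soil_archetype("deep_fine"), clim)
        assert np.all(wb.runoff_mm[clim.rain_mm == 0] == 0)

    def test_runoff_scales_with_curve_parameter(self):
        rain = np.concatenate([np.zeros(5), [40.0], np.zeros(5)])
        low = single_layer_profile(curve=0.1)
        high = single_layer_profile(curve=0.4)
        r_low = simulate_water_balance(low, make_climate(rain)).runoff_mm.sum()
        r_high = simulate_water_balance(high, make_climate(rain)).runoff_mm.sum()
        assert r_high > r_low > 0


class TestMonthlyTransportRisk:
    def test_month_out_of_range_rejected(self):
        soil = single_layer_profile()
        clim = make_climate(np.zeros(800))
        with pytest.raises(ValueError, match="month"):
            monthly_transport_risk(soil, clim, SlopeClass.FLAT, False, 13)

    def test_short_climate_rejected(self):
        soil = single_layer_profile()
        with pytest.raises(ValueError, match="at least"):
            monthly_transport_risk(soil, make_climate(np.zeros(100)), SlopeClass.FLAT, False, 1)

    def test_impermeable_profile_leach_risk_zero(self):
        # drainage coefficient 0 and too little rain to overflow saturation
        soil = single_layer_profile(k=0.0)
        rain = np.zeros(800)
        rain[::30] = 5.0
        leach, _ = monthly_transport_risk(
            soil, make_climate(rain, pet=np.full(800, 2.0)), SlopeClass.FLAT, False, 1
        )
        assert leach == 0.0

    def test_complete_breakthrough_gives_leach_risk_one(self):
        # daily deluge with k = 1 flushes the whole profile: full 450/450
        soil = single_layer_profile(k=1.0, curve=0.05)
        leach, _ = monthly_transport_risk(
            soil, make_climate(np.full(800, 300.0)), SlopeClass.FLAT, False, 1
        )
        assert leach == 1.0

    def test_runoff_risk_is_window_sum_over_normalizer(self):
        # oracle: direct 30-day sum of the simulated runoff series / 200 mm
        soil = single_layer_profile(curve=0.6)
        rain = np.zeros(800)
        rain[14:17] = 120.0  # storm right after the day-15 application
        clim = make_climate(rain)
        wb = simulate_water_balance(soil, clim)
        expected = min(1.0, wb.runoff_mm[14:44].sum() / 200.0)
        _, runoff = monthly_transport_risk(soil, clim, SlopeClass.FLAT, False, 1)
        assert runoff == pytest.approx(expected, rel=1e-12)
        assert 0 < runoff < 1

    def test_storm_totalling_normalizer_caps_at_one(self):
        soil = single_layer_profile(k=1.0, curve=1.0)
        rain = np.zeros(800)
        rain[14:17] = 500.0
        clim = make_climate(rain)
        _, runoff = monthly_transport_risk(soil, clim, SlopeClass.FLAT, False, 1)
        assert runoff == 1.0

    def test_steeper_slope_never_reduces_runoff_risk(self):
        clim = generate_climate(ScenarioConfig(seed=11, n_years=3), np.random.default_rng(11))
        soil = soil_archetype("deep_fine")
        risks = [
            monthly_transport_risk(soil, clim, s, False, 7)[1]
            for s in (SlopeClass.FLAT, SlopeClass.ROLLING, SlopeClass.EASY, SlopeClass.STEEP)
        ]
        assert risks == sorted(risks)
        assert risks[-1] > risks[0]

    def test_wetter_climate_never_decreases_leach_risk(self):
        # scaling all rain by 1.2 must not lower the annual-mean leaching fraction
        base = generate_climate(ScenarioConfig(seed=5, n_years=3), np.random.default_rng(5))
        wetter = make_climate(base.rain_mm * 1.2, pet=base.pet_mm)
        soil = soil_archetype("intermediate")
        for month in (1, 4, 7, 10):
            dry_leach, _ = monthly_transport_risk(soil, base, SlopeClass.FLAT, False, month)
            wet_leach, _ = monthly_transport_risk(soil, wetter, SlopeClass.FLAT, False, month)
            assert wet_leach >= dry_leach - 1e-12


class TestTransportTable:
    def _loc(self, loc_id, seed=2, soil="intermediate"):
        clim = generate_climate(ScenarioConfig(seed=seed, n_years=3), np.random.default_rng(seed))
        return (loc_id, soil_archetype(soil, soil_id=f"{soil}-{loc_id}"), clim, SlopeClass.FLAT, False)

    def test_single_location_yields_twelve_rows(self):
        table = build_transport_table([self._loc("L1")])
        assert len(table) == 12
        assert sorted(table["month"]) == list(range(1, 13))

    def test_identical_locations_get_identical_risks(self):
        table = build_transport_table([self._loc("L1"), self._loc("L2")])
        a = table[table["location_id"] == "L1"].reset_index(drop=True)
        b = table[table["location_id"] == "L2"].reset_index(drop=True)
        assert a["leach_risk"].tolist() == b["leach_risk"].tolist()
        assert a["runoff_risk"].tolist() == b["runoff_risk"].tolist()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_transport_table([self._loc("L1"), self._loc("L1")])

    def test_empty_location_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            build_transport_table([])

    def test_all_risks_bounded(self):
        rng = np.random.default_rng(99)
        locs = [
            (f"L{i}", random_soil(rng),
             generate_climate(ScenarioConfig(seed=100 + i, n_years=3),
                              np.random.default_rng(100 + i)),
             SlopeClass.ROLLING, bool(i % 2))
            for i in range(3)
        ]
        table = build_transport_table(locs)
        assert ((table["leach_risk"] >= 0) & (table["leach_risk"] <= 1)).all()
        assert ((table["runoff_risk"] >= 0) & (table["runoff_risk"] <= 1)).all()
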