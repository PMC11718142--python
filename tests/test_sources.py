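"""Source calculations: excreta, fertilizer, residue, cultivation, erosion."""

import numpy as np
import pytest

from nlossrisk.sources import (
    BlockCalendar,
    CropRecord,
    CultivationEvent,
    ErosionContext,
    ExcretaRateTable,
    FertilizerApplication,
    LookupError_,
    MonthlySourceInputs,
    assemble_monthly_sources,
    cultivation_n,
    erosion_n,
    excreta_n,
    fertilizer_n,
    residue_n,
)

RATES = ExcretaRateTable({("sheep", "ewe", "any"): (1.0, 0.3)})


class TestExcreta:
    def test_empty_herd_gives_zero(self):
        assert excreta_n([], RATES, 50.0) == (0.0, 0.0, 0.0)

    def test_hand_multiplication_oracle(self):
        # 100 ewes at (1.0, 0.3) kg N/head/month on 50 ha
        urine, dung, effl = excreta_n([("sheep", "ewe", "any", 100.0)], RATES, 50.0)
        assert (urine, dung, effl) == (2.0, 0.6, 0.0)

    def test_doubled_area_halves_all_outputs(self):
        herd = [("sheep", "ewe", "any", 100.0)]
        a = excreta_n(herd, RATES, 50.0, milking_cow_count=10, effluent_n_kg_per_cow_month=0.5)
        b = excreta_n(herd, RATES, 100.0, milking_cow_count=10, effluent_n_kg_per_cow_month=0.5)
        assert all(x == pytest.approx(2 * y) for x, y in zip(a, b))

    def test_linear_in_head_counts(self, rng):
        for _ in range(20):
            h1, h2 = rng.uniform(0, 500, 2)
            one = excreta_n([("sheep", "ewe", "any", h1)], RATES, 20.0)
            two = excreta_n([("sheep", "ewe", "any", h2)], RATES, 20.0)
            both = excreta_n([("sheep", "ewe", "any", h1 + h2)], RATES, 20.0)
            assert both[0] == pytest.approx(one[0] + two[0], rel=1e-12)
            assert both[1] == pytest.approx(one[1] + two[1], rel=1e-12)

    def test_missing_stock_class_names_the_key(self):
        with pytest.raises(LookupError_, match="alpaca"):
            excreta_n([("alpaca", "adult", "any", 5)], RATES, 10.0)


class TestFertilizer:
    PRODUCTS = {"urea": 0.46, "dap": 0.18}

    def test_no_applications_gives_zero_every_month(self):
        out = fertilizer_n([], self.PRODUCTS)
        assert all(out[m] == 0.0 for m in range(1, 13))

    def test_mass_times_fraction_oracle(self):
        out = fertilizer_n([FertilizerApplication("urea", 100.0, 5)], self.PRODUCTS)
        assert out[5] == pytest.approx(46.0)

    def test_monthly_bucketing(self):
        apps = [
            FertilizerApplication("urea", 50.0, 3),
            FertilizerApplication("urea", 50.0, 3),
            FertilizerApplication("dap", 100.0, 9),
        ]
        out = fertilizer_n(apps, self.PRODUCTS)
        assert out[3] == pytest.approx(46.0)
        assert out[9] == pytest.approx(18.0)
        assert sum(v > 0 for v in out.values()) == 2

    def test_unknown_product_rejected(self):
        with pytest.raises(LookupError_, match="guano"):
            fertilizer_n([FertilizerApplication("guano", 10.0, 1)], self.PRODUCTS)


def crop(cn=20.0, rooting="intermediate", yield_t=10.0, harvest=3):
    return CropRecord("c", yield_t, harvest, 0.5, 4.0, 1.0, cn, rooting)


class TestResidue:
    def test_high_cn_immobilizes_everything(self):
        schedule = residue_n(crop(cn=30.0))
        assert all(v == (0.0, 0.0) for v in schedule.values())

    def test_cn_threshold_is_strict(self):
        assert all(v == (0.0, 0.0) for v in residue_n(crop(cn=25.0)).values())
        assert any(v != (0.0, 0.0) for v in residue_n(crop(cn=24.9)).values())

    @pytest.mark.parametrize("rooting,factor", [("shallow", 1.4), ("deep", 0.7), ("intermediate", 1.0)])
    def test_belowground_rooting_adjustment(self, rooting, factor):
        # belowground releasable N = 10 kg/ha before adjustment
        c = crop(cn=20.0, rooting=rooting)
        schedule = residue_n(c)
        bg_total = sum(bg for _, bg in schedule.values())
        assert bg_total == pytest.approx(10.0 * factor, rel=1e-12)

    def test_release_spread_over_three_months_after_harvest(self):
        schedule = residue_n(crop(harvest=3))
        months = [m for m, (ag, bg) in schedule.items() if ag > 0 or bg > 0]
        assert months == [4, 5, 6]
        ag_total = sum(ag for ag, _ in schedule.values())
        assert ag_total == pytest.approx(10.0 * 0.5 * 4.0, rel=1e-9)

    def test_release_wraps_around_december(self):
        schedule = residue_n(crop(harvest=11))
        months = sorted(m for m, (ag, _) in schedule.items() if ag > 0)
        assert months == [1, 2, 12]

    def test_zero_yield_gives_zero(self):
        assert all(v == (0.0, 0.0) for v in residue_n(crop(yield_t=0.0)).values())

    def test_monthly_sum_equals_adjusted_total(self, rng):
        for _ in range(25):
            c = CropRecord(
                "r", float(rng.uniform(0, 50)), int(rng.integers(1, 13)),
                float(rng.uniform(0, 1)), float(rng.uniform(0, 10)), float(rng.uniform(0, 5)),
                float(rng.uniform(5, 24)), ["shallow", "deep", "intermediate"][int(rng.integers(3))],
            )
            schedule = residue_n(c)
            factor = {"shallow": 1.4, "deep": 0.7, "intermediate": 1.0}[c.rooting_class]
            expected_bg = c.yield_t_ha * c.n_conc_bg_kg_t * factor
            assert sum(bg for _, bg in schedule.values()) == pytest.approx(expected_bg, abs=1e-9)


class TestCultivation:
    def test_no_event_gives_zero(self):
        assert all(v == 0.0 for v in cultivation_n(None).values())

    def test_long_term_releases_at_least_short_term(self):
        long = sum(cultivation_n(CultivationEvent("long_term", "dairy", 5)).values())
        short = sum(cultivation_n(CultivationEvent("short", "dairy", 5)).values())
        assert long >= short > 0

    def test_pool_conserved(self):
        total = sum(cultivation_n(CultivationEvent("long_term", "dairy", 2)).values())
        assert total == pytest.approx(300.0, rel=0.01)

    def test_fallow_extends_release_window(self):
        base = cultivation_n(CultivationEvent("short", "dairy", 1))
        fallow = cultivation_n(CultivationEvent("short", "dairy", 1, fallow_months=3))
        assert sum(v > 0 for v in fallow.values()) > sum(v > 0 for v in base.values())
        assert sum(fallow.values()) == pytest.approx(sum(base.values()), rel=0.01)


class TestErosion:
    def ctx(self, cover=0.1, mult=200.0, n_frac=0.003):
        return ErosionContext("cropping", "rolling", "winter", cover, mult, n_frac)

    def test_calibration_line_oracle(self):
        # estimated 20 t/ha, soil N 0.3% -> calibrated 0.92*20-15.7 = 2.7 -> 8.1 kg N/ha
        out = erosion_n(self.ctx(cover=0.1, mult=200.0, n_frac=0.003))
        assert sum(out.values()) == pytest.approx(8.1, rel=1e-9)
        # split equally over the season's three months
        assert out[6] == out[7] == out[8] == pytest.approx(2.7, rel=1e-9)

    def test_negative_calibration_floors_at_zero(self):
        # estimated 10 t/ha -> 0.92*10-15.7 < 0
        out = erosion_n(self.ctx(cover=0.05, mult=200.0))
        assert all(v == 0.0 for v in out.values())

    def test_zero_cover_factor_gives_zero(self):
        assert all(v == 0.0 for v in erosion_n(self.ctx(cover=0.0)).values())

    def test_monotone_in_cover_multiplier_and_n_fraction(self, rng):
        base = sum(erosion_n(self.ctx()).values())
        assert sum(erosion_n(self.ctx(cover=0.2)).values()) >= base
        assert sum(erosion_n(self.ctx(mult=400.0)).values()) >= base
        assert sum(erosion_n(self.ctx(n_frac=0.006)).values()) >= base


class TestAssemble:
    def test_empty_calendar_gives_all_zero(self):
        out = assemble_monthly_sources(BlockCalendar(area_ha=10.0))
        assert all(sum(s.as_dict().values()) == 0.0 for s in out.values())

    def test_fertilizer_only_calendar(self):
        cal = BlockCalendar(
            area_ha=10.0, fertilizer=[FertilizerApplication("urea", 100.0, 4)]
        )
        out = assemble_monthly_sources(cal, product_n_fraction={"urea": 0.46})
        assert out[4].fert_n == pytest.approx(46.0)
        nonzero = {c for s in out.values() for c, v in s.as_dict().items() if v > 0}
        assert nonzero == {"fert_n"}

    def test_additivity_against_component_recomputation(self):
        cal = BlockCalendar(
            area_ha=20.0,
            stock_by_month={m: [("sheep", "ewe", "any", 200.0)] for m in range(1, 13)},
            fertilizer=[FertilizerApplication("urea", 80.0, 9)],
            crops=[crop(harvest=2)],
            cultivation=CultivationEvent("short", "sheep_and_beef", 8),
            erosion=[ErosionContext("cropping", "flat", "winter", 0.1, 200.0, 0.003)],
        )
        out = assemble_monthly_sources(
            cal, excreta_rates=RATES, product_n_fraction={"urea": 0.46}
        )
        fert = fertilizer_n(list(cal.fertilizer), {"urea": 0.46})
        res = residue_n(cal.crops[0])
        cult = cultivation_n(cal.cultivation)
        eros = erosion_n(cal.erosion[0])
        for m in range(1, 13):
            urine, dung, _ = excreta_n(cal.stock_by_month[m], RATES, 20.0)
            assert out[m].urine_n == pytest.approx(urine, rel=1e-12)
            assert out[m].dung_n == pytest.approx(dung, rel=1e-12)
            assert out[m].fert_n == pytest.approx(fert[m], rel=1e-12)
            assert out[m].residue_ag_n == pytest.approx(res[m][0], rel=1e-12)
            assert out[m].residue_bg_n == pytest.approx(res[m][1], rel=1e-12)
            assert out[m].cultivation_n == pytest.approx(cult[m], rel=1e-12)
            assert out[m].erosion_n == pytest.approx(eros[m], rel=1e-12)

    def test_negative_source_rejected(self):
        with pytest.raises(ValueError):
            MonthlySourceInputs(urine_n=-1.0)

    def test_all_outputs_finite_and_nonnegative(self, rng):
        for _ in range(10):
            cal = BlockCalendar(
                area_ha=float(rng.uniform(1, 100)),
                stock_by_month={m: [("sheep", "ewe", "any", float(rng.uniform(0, 1000)))]
                                for m in range(1, 13)},
                fertilizer=[FertilizerApplication("urea", float(rng.uniform(0, 300)),
                                                  int(rng.integers(1, 13)))],
            )
            out = assemble_monthly_sources(cal, excreta_rates=RATES,
                                           product_n_fraction={"urea": 0.46})
            for s in out.values():
                for v in s.as_dict().values():
                    assert np.isfinite(v) and v >= 0
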