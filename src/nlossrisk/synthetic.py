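"""Synthetic scenario generator: weather, soils, farms and observation sets.

Everything the pipeline needs can be generated deterministically from a seed:

* daily weather from a two-state (wet/dry) Markov chain with gamma-distributed
  wet-day depths and a sinusoidal seasonal cycle in both wet-day probability
  and potential evapotranspiration (southern-hemisphere phase: PET peaks in
  January);
* contrasting soil archetypes — a stony, shallow, freely draining profile and a
  deep, fine-textured, slowly draining one, plus an intermediate — each with a
  layer boundary at the 1000 mm tracer accounting depth;
* block management calendars per land use that exercise every source category
  (stock, effluent, fertilizer, residues, cultivation, erosion);
* observation sets whose losses are a noisy monotone (proportional, lognormal
  multiplicative noise) function of true annual risk, with vegetable blocks
  attenuated in risk by a configured factor so the scale-factor diagnosis has a
  known answer to recover.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a seed
fixes every output bit-for-bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .index_engine import Block
from .sources import (
    BlockCalendar,
    CropRecord,
    CultivationEvent,
    ErosionContext,
    ExcretaRateTable,
    FertilizerApplication,
)
from .transport import ClimateSeries, SlopeClass, SoilLayer, SoilProfile
from .validation import ObservationRecord

__all__ = [
    "ScenarioConfig",
    "FixtureFarm",
    "default_excreta_rates",
    "default_products",
    "soil_archetype",
    "generate_climate",
    "generate_fixture_farm",
    "generate_observation_set",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic scenario.

    ``annual_rain_mm`` and ``storm_frequency`` (mean wet-day probability) set
    the climate regime; ``obs_noise_sd`` is the lognormal sigma of the
    multiplicative noise on the risk -> loss link; ``vegetable_attenuation`` is
    the known factor by which vegetable-block risk understates true risk.
    """

    seed: int = 0
    n_blocks: int = 12
    n_years: int = 4
    land_use_mix: tuple[str, ...] = (
        "dairy",
        "sheep_and_beef",
        "cropping",
        "vegetables",
        "horticulture",
        "forestry",
    )
    annual_rain_mm: float = 1100.0
    seasonality_amplitude: float = 0.35
    storm_frequency: float = 0.30
    obs_noise_sd: float = 0.5
    obs_link_slope: float = 1.5
    vegetable_attenuation: float = 6.0

    def __post_init__(self) -> None:
        if self.annual_rain_mm < 0 or self.storm_frequency < 0:
            raise ValueError("rain parameters must be >= 0")
        if self.vegetable_attenuation <= 0:
            raise ValueError("vegetable attenuation must be > 0")


def default_excreta_rates() -> ExcretaRateTable:
    """Illustrative per-head monthly excreta N rates (kg N head^-1 month^-1)."""
    return ExcretaRateTable(
        {
            ("dairy_cattle", "milking", "national"): (8.0, 4.0),
            ("dairy_cattle", "heifer", "national"): (4.0, 2.0),
            ("beef_cattle", "mixed", "national"): (4.5, 2.5),
            ("sheep", "ewe", "national"): (0.85, 0.35),
            ("sheep", "lamb", "national"): (0.35, 0.15),
            ("deer", "hind", "national"): (1.6, 0.8),
        }
    )


def default_products() -> dict[str, float]:
    """Fertilizer product N mass fractions."""
    return {"urea": 0.46, "dap": 0.18, "ammonium_sulphate": 0.21, "superphosphate": 0.0}


def soil_archetype(name: str, soil_id: str | None = None) -> SoilProfile:
    """One of the contrasting soil archetypes: stony_shallow, deep_fine, intermediate.

    Each profile places a layer boundary exactly at 1000 mm so tracer accounting
    is unambiguous.  The stony, shallow profile holds little water and drains
    fast; the deep, fine-textured one holds much and drains slowly.
    """
    soil_id = soil_id or name
    if name == "stony_shallow":
        layers = (
            SoilLayer(200, 0.36, 0.18, 0.08, 0.90),
            SoilLayer(400, 0.34, 0.16, 0.07, 0.92),
            SoilLayer(400, 0.32, 0.14, 0.06, 0.95),
        )
        return SoilProfile(soil_id, layers, runoff_curve_parameter=0.15,
                           total_n_fraction=0.0025, bulk_density=1.5)
    if name == "deep_fine":
        layers = (
            SoilLayer(300, 0.50, 0.38, 0.20, 0.15),
            SoilLayer(700, 0.48, 0.36, 0.19, 0.10),
            SoilLayer(500, 0.46, 0.34, 0.18, 0.08),
        )
        return SoilProfile(soil_id, layers, runoff_curve_parameter=0.45,
                           total_n_fraction=0.0045, bulk_density=1.2)
    if name == "intermediate":
        layers = (
            SoilLayer(250, 0.44, 0.28, 0.13, 0.45),
            SoilLayer(750, 0.42, 0.26, 0.12, 0.40),
            SoilLayer(300, 0.40, 0.24, 0.11, 0.40),
        )
        return SoilProfile(soil_id, layers, runoff_curve_parameter=0.30,
                           total_n_fraction=0.0035, bulk_density=1.35)
    raise ValueError(f"unknown soil archetype {name!r}")


SOIL_ARCHETYPES = ("stony_shallow", "deep_fine", "intermediate")


def generate_climate(
    config: ScenarioConfig,
    rng: np.random.Generator,
    start: str = "2000-01-01",
) -> ClimateSeries:
    """Daily weather from a seasonal two-state Markov chain.

    Wet-day probability follows a winter-peaking sinusoid around
    ``storm_frequency`` (amplitude ``seasonality_amplitude`` as a relative
    modulation), with wet-after-wet persistence.  Wet-day depths are gamma
    (shape 0.75) with the scale chosen so the expected annual total matches
    ``annual_rain_mm``.  PET is a summer-peaking sinusoid (3.0 +/- 2.2 mm/day)
    with small daily jitter.
    """
    n_days = int(config.n_years * 365)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.values

    # southern hemisphere: rain peaks mid-year (winter), PET peaks in January
    season = np.cos(2 * np.pi * (doy - 182) / 365.25)
    p_wet_base = config.storm_frequency * (1 + config.seasonality_amplitude * season)
    p_wet_base = np.clip(p_wet_base, 0.0, 0.95)

    persistence = 0.35  # extra wet probability after a wet day
    wet = np.zeros(n_days, dtype=bool)
    u = rng.random(n_days)
    prev = False
    for d in range(n_days):
        p = min(0.98, p_wet_base[d] + (persistence if prev else 0.0))
        wet[d] = u[d] < p
        prev = wet[d]

    rain = np.zeros(n_days)
    n_wet = int(wet.sum())
    if n_wet > 0 and config.annual_rain_mm > 0:
        shape = 0.75
        expected_wet_per_year = n_wet / config.n_years
        scale = config.annual_rain_mm / (expected_wet_per_year * shape)
        rain[wet] = rng.gamma(shape, scale, n_wet)

    pet_season = np.cos(2 * np.pi * (doy - 15) / 365.25)  # max mid-January
    pet = 3.0 + 2.2 * pet_season + rng.normal(0, 0.15, n_days)
    pet = np.clip(pet, 0.0, None)

    return ClimateSeries(dates, rain, pet)


def _calendar_for(land_use: str, area_ha: float, slope: str) -> BlockCalendar:
    """A management calendar exercising the sources typical of a land use."""
    grazing_months = range(1, 13)
    if land_use == "dairy":
        return BlockCalendar(
            area_ha=area_ha,
            stock_by_month={m: [("dairy_cattle", "milking", "national", 2.8 * area_ha)]
                            for m in grazing_months},
            milking_cows_by_month={m: 2.8 * area_ha for m in grazing_months},
            fertilizer=[FertilizerApplication("urea", 65.0, m) for m in (9, 10, 11, 3)],
            erosion=[ErosionContext(land_use, slope, "winter", 0.005, 100.0, 0.0045)],
        )
    if land_use == "sheep_and_beef":
        return BlockCalendar(
            area_ha=area_ha,
            stock_by_month={m: [("sheep", "ewe", "national", 9.0 * area_ha),
                                ("beef_cattle", "mixed", "national", 0.6 * area_ha)]
                            for m in grazing_months},
            fertilizer=[FertilizerApplication("dap", 120.0, 9)],
            erosion=[ErosionContext(land_use, slope, "winter", 0.01, 260.0, 0.0035),
                     ErosionContext(land_use, slope, "spring", 0.006, 260.0, 0.0035)],
        )
    if land_use == "cropping":
        return BlockCalendar(
            area_ha=area_ha,
            fertilizer=[FertilizerApplication("urea", 110.0, 9),
                        FertilizerApplication("urea", 80.0, 11)],
            crops=[CropRecord("wheat", 9.0, 2, 0.6, 6.5, 1.8, 80.0, "intermediate"),
                   CropRecord("peas", 5.0, 1, 0.5, 22.0, 6.0, 15.0, "shallow")],
            cultivation=CultivationEvent("long_term", "sheep_and_beef", 8),
            erosion=[ErosionContext(land_use, slope, "winter", 0.12, 150.0, 0.0030)],
        )
    if land_use == "vegetables":
        return BlockCalendar(
            area_ha=area_ha,
            fertilizer=[FertilizerApplication("urea", 130.0, m) for m in (9, 11, 1)],
            crops=[CropRecord("onions", 45.0, 2, 0.3, 2.8, 0.9, 14.0, "shallow"),
                   CropRecord("brassica", 30.0, 5, 0.5, 3.5, 1.1, 13.0, "shallow")],
            cultivation=CultivationEvent("short", "sheep_and_beef", 8),
            erosion=[ErosionContext(land_use, slope, "winter", 0.2, 180.0, 0.0030),
                     ErosionContext(land_use, slope, "autumn", 0.15, 180.0, 0.0030)],
        )
    if land_use == "horticulture":
        return BlockCalendar(
            area_ha=area_ha,
            fertilizer=[FertilizerApplication("ammonium_sulphate", 90.0, 9)],
            crops=[CropRecord("apples", 50.0, 4, 0.1, 1.5, 0.3, 22.0, "deep")],
            erosion=[ErosionContext(land_use, slope, "winter", 0.004, 80.0, 0.0030)],
        )
    if land_use == "forestry":
        return BlockCalendar(
            area_ha=area_ha,
            erosion=[ErosionContext(land_use, slope, "winter", 0.012, 500.0, 0.0025)],
        )
    if land_use == "deer":
        return BlockCalendar(
            area_ha=area_ha,
            stock_by_month={m: [("deer", "hind", "national", 4.0 * area_ha)]
                            for m in grazing_months},
            erosion=[ErosionContext(land_use, slope, "winter", 0.015, 300.0, 0.0035)],
        )
    raise ValueError(f"no calendar template for land use {land_use!r}")


@dataclass
class FixtureFarm:
    """A complete in-memory scenario."""

    blocks: list[Block]
    soils: dict[str, SoilProfile]
    climates: dict[str, ClimateSeries]
    calendars: dict[str, BlockCalendar]
    excreta_rates: ExcretaRateTable = field(default_factory=default_excreta_rates)
    products: dict[str, float] = field(default_factory=default_products)
    effluent_n_kg_per_cow_month: float = 0.6


def generate_fixture_farm(config: ScenarioConfig) -> FixtureFarm:
    """Generate blocks, soils, climates and calendars, deterministic under seed.

    At least one stony-shallow and one deep-fine soil are always present; the
    block land uses cycle through ``land_use_mix`` and their calendars cover
    every source category between them.  Two climate cells are generated: a
    wetter and a drier variant of the configured regime.
    """
    rng = np.random.default_rng(config.seed)
    soils = {name: soil_archetype(name) for name in SOIL_ARCHETYPES}
    climates = {
        "cell_wet": generate_climate(config, rng),
        "cell_dry": generate_climate(
            replace(config, annual_rain_mm=config.annual_rain_mm * 0.65), rng
        ),
    }
    slopes = [s.value for s in SlopeClass]
    blocks = []
    calendars = {}
    for i in range(config.n_blocks):
        land_use = config.land_use_mix[i % len(config.land_use_mix)]
        soil_id = SOIL_ARCHETYPES[i % len(SOIL_ARCHETYPES)]
        slope = slopes[i % len(slopes)] if land_use in ("sheep_and_beef", "deer", "forestry") else "flat"
        block = Block(
            block_id=f"B{i + 1:03d}",
            area_ha=float(np.round(rng.uniform(8, 60), 1)),
            land_use=land_use,
            soil_id=soil_id,
            slope=slope,
            climate_id="cell_wet" if i % 2 == 0 else "cell_dry",
            irrigated=bool(land_use in ("dairy", "vegetables") and i % 4 == 0),
        )
        blocks.append(block)
        calendars[block.block_id] = _calendar_for(land_use, block.area_ha, slope)
    return FixtureFarm(blocks=blocks, soils=soils, climates=climates, calendars=calendars)


def generate_observation_set(
    config: ScenarioConfig,
    true_risks: dict[str, float],
    land_use_by_block: dict[str, str],
    *,
    flow_path: str = "leaching",
) -> list[ObservationRecord]:
    """Observed losses as a noisy monotone function of true annual risk.

    loss = link_slope x risk_effective x exp(N(0, obs_noise_sd)), where
    risk_effective equals the block's true risk except for vegetable blocks,
    whose *reported* risk is understood to understate true risk by the
    configured attenuation factor — so their loss is generated from
    attenuation x risk.  Noise sd 0 gives a perfectly monotone (rank r^2 = 1)
    set; losses are always >= 0 by lognormal positivity.
    """
    rng = np.random.default_rng(config.seed + 1)
    records = []
    for block_id in sorted(true_risks):
        risk = true_risks[block_id]
        land_use = land_use_by_block[block_id]
        effective = risk * (config.vegetable_attenuation if land_use == "vegetables" else 1.0)
        noise = float(np.exp(rng.normal(0.0, config.obs_noise_sd))) if config.obs_noise_sd > 0 else 1.0
        loss = config.obs_link_slope * effective * noise
        records.append(
            ObservationRecord(
                obs_id=f"obs_{block_id}",
                land_use=land_use,
                flow_path=flow_path,
                loss_kg_ha_yr=loss,
                measured=True,
            )
        )
    return records
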