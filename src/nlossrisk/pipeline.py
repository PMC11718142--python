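"""End-to-end scoring: scenario -> transport table -> monthly source x transport scores."""

from __future__ import annotations

import pandas as pd

from .index_engine import RiskScore, score_block_month
from .sources import MonthlySourceInputs, assemble_monthly_sources
from .synthetic import FixtureFarm
from .transport import SlopeClass, TransportProtocolConfig, build_transport_table

__all__ = ["transport_key", "scenario_transport_table", "scenario_sources", "score_scenario"]


def transport_key(soil_id: str, climate_id: str, slope: str, irrigated: bool) -> str:
    """Location id for one (soil, climate, slope, irrigation) combination."""
    return f"{soil_id}|{climate_id}|{slope}|{int(irrigated)}"


def scenario_transport_table(
    farm: FixtureFarm, *, config: TransportProtocolConfig | None = None
) -> pd.DataFrame:
    """Transport fractions for every unique combination the farm's blocks use."""
    combos = {}
    for b in farm.blocks:
        key = transport_key(b.soil_id, b.climate_id, b.slope, b.irrigated)
        if key not in combos:
            combos[key] = (
                key,
                farm.soils[b.soil_id],
                farm.climates[b.climate_id],
                SlopeClass(b.slope),
                b.irrigated,
            )
    return build_transport_table(list(combos.values()), config=config)


def scenario_sources(farm: FixtureFarm) -> dict[str, dict[int, MonthlySourceInputs]]:
    """Monthly source vectors for every block."""
    return {
        b.block_id: assemble_monthly_sources(
            farm.calendars[b.block_id],
            excreta_rates=farm.excreta_rates,
            product_n_fraction=farm.products,
            effluent_n_kg_per_cow_month=farm.effluent_n_kg_per_cow_month,
        )
        for b in farm.blocks
    }


def score_scenario(
    farm: FixtureFarm,
    transport: pd.DataFrame,
    *,
    literal_equation: bool = False,
    sources: dict[str, dict[int, MonthlySourceInputs]] | None = None,
) -> list[RiskScore]:
    """Score every block-month of the farm against a transport table."""
    if sources is None:
        sources = scenario_sources(farm)
    lookup = transport.set_index(["location_id", "month"])[["leach_risk", "runoff_risk"]]
    scores = []
    for b in farm.blocks:
        key = transport_key(b.soil_id, b.climate_id, b.slope, b.irrigated)
        for month in range(1, 13):
            try:
                leach, runoff = lookup.loc[(key, month)]
            except KeyError:
                raise KeyError(
                    f"no transport row for block {b.block_id} "
                    f"(location {key!r}, month {month})"
                ) from None
            scores.append(
                score_block_month(
                    b.block_id,
                    month,
                    sources[b.block_id][month],
                    float(leach),
                    float(runoff),
                    literal_equation=literal_equation,
                )
            )
    return scores
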