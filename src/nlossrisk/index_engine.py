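"""Baseline monthly N loss risk indices: source x transport, summed over sources.

The leaching index multiplies the leaching transport fraction into every
leaching-eligible source (urine, dung, effluent, fertilizer, belowground
residues, cultivation mineralization); the runoff index multiplies the runoff
transport fraction into the runoff-eligible sources (eroded soil N, dung,
fertilizer, aboveground residues).  Urine is washed into the soil and is not
available to runoff.  Scores are unitless and comparable only as ranks — they
are not proxies for absolute losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .sources import MonthlySourceInputs

__all__ = [
    "Block",
    "RiskScore",
    "LEACH_SOURCES",
    "RUNOFF_SOURCES",
    "leaching_index",
    "runoff_index",
    "score_block_month",
    "aggregate_risk",
]

LAND_USES = (
    "cropping",
    "dairy",
    "deer",
    "sheep_and_beef",
    "forestry",
    "horticulture",
    "vegetables",
)

#: source categories entering the leaching index
LEACH_SOURCES = ("urine_n", "dung_n", "effluent_n", "fert_n", "residue_bg_n", "cultivation_n")
#: source categories entering the runoff index (urine and belowground residues excluded)
RUNOFF_SOURCES = ("erosion_n", "dung_n", "fert_n", "residue_ag_n")


@dataclass(frozen=True)
class Block:
    """A group of fields under similar management — the spatial scoring unit."""

    block_id: str
    area_ha: float
    land_use: str
    soil_id: str
    slope: str
    climate_id: str
    irrigated: bool = False

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("block area must be > 0")
        if self.land_use not in LAND_USES:
            raise ValueError(f"unknown land use {self.land_use!r}; expected one of {LAND_USES}")


@dataclass(frozen=True)
class RiskScore:
    block_id: str
    month: int
    leach_index: float
    runoff_index: float

    def __post_init__(self) -> None:
        if self.leach_index < 0 or self.runoff_index < 0:
            raise ValueError("risk indices must be >= 0")

    @property
    def total(self) -> float:
        return self.leach_index + self.runoff_index


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value}")


def leaching_index(sources: MonthlySourceInputs, leach_risk: float) -> float:
    """Monthly leaching risk index: leach fraction x sum of leachable sources.

    Linear in every source term and in the transport fraction.
    """
    _check_fraction("leach_risk", leach_risk)
    return leach_risk * sum(getattr(sources, c) for c in LEACH_SOURCES)


def runoff_index(
    sources: MonthlySourceInputs,
    runoff_risk: float,
    *,
    leach_risk: float | None = None,
    literal_equation: bool = False,
) -> float:
    """Monthly runoff risk index: runoff fraction x sum of runoff-eligible sources.

    With ``literal_equation=True`` the dung, fertilizer and aboveground-residue
    terms are weighted by the *leaching* fraction instead (the published equation
    prints those prefixes; the default treats them as a typographic slip and
    weights every term by the runoff fraction).  ``leach_risk`` is required in
    literal mode.
    """
    _check_fraction("runoff_risk", runoff_risk)
    if literal_equation:
        if leach_risk is None:
            raise ValueError("literal_equation mode requires leach_risk")
        _check_fraction("leach_risk", leach_risk)
        return runoff_risk * sources.erosion_n + leach_risk * (
            sources.dung_n + sources.fert_n + sources.residue_ag_n
        )
    return runoff_risk * sum(getattr(sources, c) for c in RUNOFF_SOURCES)


def score_block_month(
    block_id: str,
    month: int,
    sources: MonthlySourceInputs,
    leach_risk: float,
    runoff_risk: float,
    *,
    literal_equation: bool = False,
) -> RiskScore:
    """Convenience wrapper producing a RiskScore for one block-month."""
    return RiskScore(
        block_id=block_id,
        month=month,
        leach_index=leaching_index(sources, leach_risk),
        runoff_index=runoff_index(
            sources, runoff_risk, leach_risk=leach_risk, literal_equation=literal_equation
        ),
    )


def aggregate_risk(
    scores: Iterable[RiskScore],
    mode: Literal["annual", "farm", "pathway_shares"],
    *,
    block_area_ha: dict[str, float] | None = None,
) -> pd.DataFrame | dict[str, float]:
    """Aggregate block-month scores over time or space.

    ``annual``: per-block sum over months (one row per block).
    ``farm``: area-weighted mean of annual block totals (needs ``block_area_ha``).
    ``pathway_shares``: leaching and runoff shares of the summed total risk —
    the leaching share is the statistic reported as "leaching accounted for X%
    of N loss risk".
    """
    rows = [
        {
            "block_id": s.block_id,
            "month": s.month,
            "leach_index": s.leach_index,
            "runoff_index": s.runoff_index,
            "total": s.total,
        }
        for s in scores
    ]
    if not rows:
        raise ValueError("score set must be non-empty")
    frame = pd.DataFrame(rows)

    if mode == "annual":
        return frame.groupby("block_id", as_index=False)[
            ["leach_index", "runoff_index", "total"]
        ].sum()
    if mode == "farm":
        if block_area_ha is None:
            raise ValueError("farm aggregation needs block areas")
        annual = frame.groupby("block_id", as_index=False)[
            ["leach_index", "runoff_index", "total"]
        ].sum()
        areas = annual["block_id"].map(block_area_ha)
        if areas.isna().any():
            missing = annual.loc[areas.isna(), "block_id"].tolist()
            raise ValueError(f"missing areas for blocks {missing}")
        w = areas / areas.sum()
        return {
            col: float((annual[col] * w).sum())
            for col in ("leach_index", "runoff_index", "total")
        }
    if mode == "pathway_shares":
        leach_tot = float(frame["leach_index"].sum())
        runoff_tot = float(frame["runoff_index"].sum())
        total = leach_tot + runoff_tot
        if total <= 0:
            return {"leach_share": float("nan"), "runoff_share": float("nan")}
        return {"leach_share": leach_tot / total, "runoff_share": runoff_tot / total}
    raise ValueError(f"unknown aggregation mode {mode!r}")
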