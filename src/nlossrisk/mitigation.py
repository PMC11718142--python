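"""Mitigation of N loss risk: source deltas and multiplicative modifiers.

Two mitigation mechanisms exist.  *Source deltas* fractionally change a source
input (e.g. lower stocking rate reduces urine and dung N); baseline risk is then
recomputed through the index engine.  *Modifiers* (wetlands, denitrification
beds, ...) act after baseline risk is computed: each multiplies the pathway risk
score by (1 - effectiveness), applied in series from most to least effective, so
each subsequent modifier acts on the product of the previous one and absolute
reductions diminish down the chain.  A 20%-effective then a 10%-effective
modifier turn a score of 100 into 80 and then 72.  Modifiers are assumed
independent (no synergies or antagonisms) and optimally placed to intercept
flow before it leaves the block.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .index_engine import RiskScore
from .sources import SOURCE_CATEGORIES, MonthlySourceInputs

__all__ = [
    "SourceDelta",
    "Modifier",
    "BlockContext",
    "ModifierStep",
    "apply_source_deltas",
    "adjusted_effectiveness",
    "apply_modifiers",
]

logger = logging.getLogger(__name__)

PATHWAYS = ("leaching", "runoff", "both")


@dataclass(frozen=True)
class SourceDelta:
    """A fractional change to one source category.

    ``delta`` in [-1, inf): the targeted category is scaled by (1 + delta).
    Empty applicability collections mean "applies everywhere".
    """

    name: str
    source: str
    delta: float
    land_uses: frozenset[str] = frozenset()
    months: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.source not in SOURCE_CATEGORIES:
            raise ValueError(f"unknown source category {self.source!r}")
        if self.delta < -1.0:
            raise ValueError("delta must be >= -1 (cannot remove more than all of a source)")

    def applies(self, land_use: str, month: int) -> bool:
        if self.land_uses and land_use not in self.land_uses:
            return False
        if self.months and month not in self.months:
            return False
        return True


@dataclass(frozen=True)
class Modifier:
    """An edge-of-field mitigation multiplying a pathway risk score by 1 - e.

    Base effectiveness ``effectiveness`` in [0, 1] is adjusted multiplicatively
    for the block's climate, slope and soil class via the three factor tables
    (default factor 1.0 for unlisted classes); the adjusted effectiveness must
    remain within [0, 1].
    """

    name: str
    pathway: str
    effectiveness: float
    land_uses: frozenset[str] = frozenset()
    climate_factors: Mapping[str, float] = field(default_factory=dict)
    slope_factors: Mapping[str, float] = field(default_factory=dict)
    soil_factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"pathway must be one of {PATHWAYS}, got {self.pathway!r}")
        if not 0.0 <= self.effectiveness <= 1.0:
            raise ValueError("base effectiveness must be in [0, 1]")

    def applies(self, land_use: str) -> bool:
        return not self.land_uses or land_use in self.land_uses


@dataclass(frozen=True)
class BlockContext:
    """Block attributes modifiers are conditioned on."""

    land_use: str
    climate_class: str = ""
    slope_class: str = ""
    soil_class: str = ""


def apply_source_deltas(
    sources: MonthlySourceInputs,
    deltas: Sequence[SourceDelta],
    *,
    land_use: str,
    month: int,
) -> MonthlySourceInputs:
    """Apply source deltas in sequence; inapplicable deltas are skipped with a warning.

    Each applicable delta scales its target category by (1 + delta), floored at
    zero; sequential deltas on the same category compose multiplicatively.
    """
    values = sources.as_dict()
    for d in deltas:
        if not d.applies(land_use, month):
            logger.warning(
                "source delta %r not applicable to land use %r month %d; skipped",
                d.name,
                land_use,
                month,
            )
            continue
        values[d.source] = max(0.0, values[d.source] * (1.0 + d.delta))
    return MonthlySourceInputs(**values)


def adjusted_effectiveness(modifier: Modifier, context: BlockContext) -> float:
    """Effectiveness after climate/slope/soil adjustment; must stay in [0, 1]."""
    e = modifier.effectiveness
    e *= modifier.climate_factors.get(context.climate_class, 1.0)
    e *= modifier.slope_factors.get(context.slope_class, 1.0)
    e *= modifier.soil_factors.get(context.soil_class, 1.0)
    if not 0.0 <= e <= 1.0 or not math.isfinite(e):
        raise ValueError(
            f"adjusted effectiveness for {modifier.name!r} is {e}; must be in [0, 1]"
        )
    return e


@dataclass(frozen=True)
class ModifierStep:
    """One link of the modifier audit trail."""

    name: str
    pathway: str
    effectiveness: float
    leach_index_after: float
    runoff_index_after: float


def apply_modifiers(
    score: RiskScore,
    modifiers: Iterable[Modifier],
    context: BlockContext,
) -> tuple[RiskScore, list[ModifierStep]]:
    """Apply modifiers in series, most effective first, returning the audit trail.

    Modifiers are filtered to the block's land use, sorted by adjusted
    effectiveness descending (ties broken by name for a deterministic trail),
    and each multiplies the running score of its pathway by (1 - e).  The final
    score equals the baseline times the product of (1 - e_i) per pathway and is
    therefore independent of input order; only the audit trail reflects the
    prescribed most-to-least-effective sequence.
    """
    applicable = [
        (adjusted_effectiveness(m, context), m) for m in modifiers if m.applies(context.land_use)
    ]
    applicable.sort(key=lambda pair: (-pair[0], pair[1].name))

    leach = score.leach_index
    runoff = score.runoff_index
    trail: list[ModifierStep] = []
    for e, m in applicable:
        if m.pathway in ("leaching", "both"):
            leach *= 1.0 - e
        if m.pathway in ("runoff", "both"):
            runoff *= 1.0 - e
        trail.append(
            ModifierStep(
                name=m.name,
                pathway=m.pathway,
                effectiveness=e,
                leach_index_after=leach,
                runoff_index_after=runoff,
            )
        )
    final = replace(score, leach_index=leach, runoff_index=runoff)
    return final, trail
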