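"""Age-sex disaggregation of national-average food supplies.

National per-capita supplies are split into age-sex-specific supplies in one
of two ways.  Foods belonging to a dietary-database (GDD) food group are
scaled by the group's relative-intake factor for that country and stratum
(factor 1.0 = the national average).  Foods with no such group — or with a
group but no factor row for that country/stratum — are assumed to be eaten in
proportion to the stratum's average dietary energy requirement, i.e. scaled by
``requirement / national_calorie_supply``.  Each produced entry records which
route it took.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .errors import DomainError, FoodLookupError
from .food_data_io import (
    NATIONAL,
    EnergyTable,
    FoodCatalog,
    GDDFactorTable,
    SupplyTable,
    group_token,
)

__all__ = [
    "GDD_MATCHED",
    "ENERGY_FALLBACK",
    "DisaggregationResult",
    "gdd_scale",
    "energy_fallback_factor",
    "disaggregate",
]

GDD_MATCHED = "GDD_MATCHED"
ENERGY_FALLBACK = "ENERGY_FALLBACK"


@dataclass
class DisaggregationResult:
    """Group-level supplies plus the provenance route of every entry.

    ``provenance`` maps (country, food_id, group token) to ``GDD_MATCHED`` or
    ``ENERGY_FALLBACK``.
    """

    supply: SupplyTable
    provenance: dict[tuple[str, str, str], str]


def gdd_scale(national_supply: float, factor: float) -> float:
    """Scale a national supply (g/d) by a relative-intake factor."""
    if not math.isfinite(national_supply) or national_supply < 0:
        raise DomainError(f"national_supply must be >= 0, got {national_supply}")
    if not math.isfinite(factor) or factor <= 0:
        raise DomainError(f"relative-intake factor must be > 0, got {factor}")
    return national_supply * factor


def energy_fallback_factor(group_requirement: float, national_supply_kcal: float) -> float:
    """Ratio of a stratum's energy requirement to the national calorie supply."""
    if not math.isfinite(group_requirement) or group_requirement <= 0:
        raise DomainError(f"group_requirement must be > 0, got {group_requirement}")
    if not math.isfinite(national_supply_kcal) or national_supply_kcal <= 0:
        raise DomainError(
            f"national_supply_kcal must be > 0, got {national_supply_kcal}"
        )
    return group_requirement / national_supply_kcal


def disaggregate(
    national: SupplyTable,
    catalog: FoodCatalog,
    gdd: GDDFactorTable,
    energy: EnergyTable,
    groups: Iterable,
) -> DisaggregationResult:
    """Produce age-sex-specific supplies for every requested group.

    Only ``NATIONAL`` rows of ``national`` are consumed.  Every (country,
    food) pair present there yields exactly one entry per requested group.
    """
    tokens = [group_token(g) for g in groups]
    records: list[tuple[str, str, str, float]] = []
    provenance: dict[tuple[str, str, str], str] = {}
    for country, food_id, group, g_per_day in national.entries():
        if group != NATIONAL:
            continue
        record = catalog.get(food_id)
        if record is None:
            raise FoodLookupError(f"food {food_id!r} (country {country!r}) not in catalog")
        for token in tokens:
            factor_row = (
                gdd.lookup(country, record.gdd_group, token)
                if record.gdd_group is not None
                else None
            )
            if factor_row is not None:
                scaled = gdd_scale(g_per_day, factor_row.factor)
                route = GDD_MATCHED
            else:
                factor = energy_fallback_factor(
                    energy.requirement(country, token), energy.national(country)
                )
                scaled = g_per_day * factor
                route = ENERGY_FALLBACK
            records.append((country, food_id, token, scaled))
            provenance[(country, food_id, token)] = route
    return DisaggregationResult(SupplyTable.from_records(records), provenance)
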