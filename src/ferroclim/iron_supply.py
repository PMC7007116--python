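"""Dietary iron supply accounting and source-class decomposition.

Iron supply per food is ``g/day × mg-iron-per-100g / 100``.  Totals per
country/stratum are sums over foods.  For reporting, each total is decomposed
into three source classes: vegetal foods whose iron content declines under
elevated CO2 (C3 grains, legumes, maize), vegetal foods with no or unknown
effect, and animal-source foods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError
from .food_data_io import AFFECTED_CATEGORIES, ECO2Category, FoodCatalog, SupplyTable

__all__ = [
    "IronSupply",
    "iron_from_food",
    "compute_iron_supply",
    "source_decomposition",
    "SHARE_CLASSES",
]

#: Column names of the source-decomposition shares.
SHARE_CLASSES = ("affected_vegetal", "unaffected_vegetal", "animal")


def iron_from_food(supply_g_per_day: float, iron_density_mg_per_100g: float) -> float:
    """Iron (mg/day) delivered by one food's per-capita supply."""
    if not math.isfinite(supply_g_per_day) or supply_g_per_day < 0:
        raise DomainError(f"supply must be >= 0, got {supply_g_per_day}")
    if not math.isfinite(iron_density_mg_per_100g) or iron_density_mg_per_100g < 0:
        raise DomainError(f"iron density must be >= 0, got {iron_density_mg_per_100g}")
    return supply_g_per_day * iron_density_mg_per_100g / 100.0


@dataclass
class IronSupply:
    """Per-food and total dietary iron (mg/person/day) by country and group."""

    by_food: pd.DataFrame  # columns: country, group, food_id, iron_mg_per_day

    def vector(self, country: str, group: str) -> pd.Series:
        """One country/group's per-food iron as a Series indexed by food_id."""
        sub = self.by_food[
            (self.by_food["country"] == country) & (self.by_food["group"] == group)
        ]
        return pd.Series(
            sub["iron_mg_per_day"].to_numpy(),
            index=sub["food_id"].to_numpy(),
            name="iron_mg_per_day",
        )

    def total(self, country: str, group: str) -> float:
        return float(self.vector(country, group).sum())

    def totals(self) -> pd.DataFrame:
        out = (
            self.by_food.groupby(["country", "group"], as_index=False)["iron_mg_per_day"]
            .sum()
            .rename(columns={"iron_mg_per_day": "total_iron_mg_per_day"})
        )
        return out

    def units(self) -> list[tuple[str, str]]:
        """All (country, group) pairs present."""
        pairs = self.by_food[["country", "group"]].drop_duplicates()
        return sorted(map(tuple, pairs.to_numpy()))


def compute_iron_supply(supply: SupplyTable, catalog: FoodCatalog) -> IronSupply:
    """Convert a supply table (any mix of groups) into iron supplies."""
    rows = []
    for country, food_id, group, g_per_day in supply.entries():
        record = catalog[food_id]
        rows.append(
            (country, group, food_id, iron_from_food(g_per_day, record.iron_density))
        )
    frame = pd.DataFrame(
        rows, columns=["country", "group", "food_id", "iron_mg_per_day"]
    ).sort_values(["country", "group", "food_id"], kind="mergesort").reset_index(drop=True)
    return IronSupply(frame)


def _share_class(category: ECO2Category) -> str:
    if category is ECO2Category.ANIMAL:
        return "animal"
    if category in AFFECTED_CATEGORIES:
        return "affected_vegetal"
    return "unaffected_vegetal"


def source_decomposition(iron: IronSupply, catalog: FoodCatalog) -> pd.DataFrame:
    """Share of total iron from each source class, per country and group.

    Shares sum to 1 for every row; a country/group with zero total iron has no
    defined shares and raises :class:`DomainError`.
    """
    frame = iron.by_food.copy()
    frame["source_class"] = [
        _share_class(catalog[f].eco2_category) for f in frame["food_id"]
    ]
    rows = []
    for (country, group), sub in frame.groupby(["country", "group"], sort=True):
        total = sub["iron_mg_per_day"].sum()
        if total <= 0:
            raise DomainError(
                f"total iron for ({country!r}, {group!r}) is zero; shares undefined"
            )
        by_class = sub.groupby("source_class")["iron_mg_per_day"].sum()
        rows.append(
            (country, group)
            + tuple(float(by_class.get(c, 0.0)) / total for c in SHARE_CLASSES)
        )
    return pd.DataFrame(rows, columns=["country", "group", *SHARE_CLASSES])
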