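"""Vegetarian counterfactual and dietary-diversity statistics.

The vegetarian scenario removes every animal-source food from a country's
national-average diet and replaces the lost calories by inflating all
remaining vegetal supplies with one country-level scalar, so total dietary
energy is conserved.  The diversity statistic counts how many foods supply
99% of a country's dietary iron (dropping foods eaten in vanishing
proportions), and its association with anemia prevalence is summarised by an
ordinary least-squares fit of the count on log(anemia), optionally excluding
countries that rely heavily on wild-harvest foods missing from supply
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, ScenarioError
from .food_data_io import NATIONAL, AnemiaTable, FoodCatalog, SupplyTable, group_token
from .iron_supply import IronSupply

__all__ = [
    "ScenarioDiet",
    "DiversityPoint",
    "DiversityFit",
    "vegetarian_transform",
    "scenario_loss_delta",
    "diversity_count",
    "diversity_points",
    "diversity_anemia_fit",
    "income_iron_correlation",
]


@dataclass
class ScenarioDiet:
    """A counterfactual national diet plus the per-country inflation factors."""

    supply: SupplyTable
    factors: dict[str, float]


def vegetarian_transform(national: SupplyTable, catalog: FoodCatalog) -> ScenarioDiet:
    """Zero animal-source supplies, inflating vegetal ones to conserve energy.

    The inflation factor per country is ``total_energy / vegetal_energy``
    computed from the diet itself; a country whose vegetal foods supply no
    energy admits no such diet and raises :class:`ScenarioError`.
    Only ``NATIONAL`` rows are transformed (and returned).
    """
    records: list[tuple[str, str, str, float]] = []
    factors: dict[str, float] = {}
    for country in national.countries:
        vec = national.for_country_group(country, NATIONAL)
        if vec.empty:
            continue
        total_energy = 0.0
        vegetal_energy = 0.0
        for food_id, g_per_day in vec.items():
            energy = g_per_day * catalog[food_id].energy_density / 100.0
            total_energy += energy
            if not catalog[food_id].is_animal_source:
                vegetal_energy += energy
        if vegetal_energy <= 0:
            raise ScenarioError(
                f"country {country!r} derives no energy from vegetal foods; "
                "vegetarian scenario undefined"
            )
        factor = total_energy / vegetal_energy
        factors[country] = factor
        for food_id, g_per_day in vec.items():
            scaled = 0.0 if catalog[food_id].is_animal_source else g_per_day * factor
            records.append((country, food_id, NATIONAL, scaled))
    return ScenarioDiet(SupplyTable.from_records(records), factors)


def scenario_loss_delta(
    base_medians: Mapping[str, float], scenario_medians: Mapping[str, float]
) -> dict[str, float]:
    """Incremental loss (percentage points) of a scenario over the baseline.

    Both inputs map country to its median loss percentage, computed with
    identical draws and seed; the country sets must coincide.
    """
    base_countries = set(base_medians)
    scen_countries = set(scenario_medians)
    if base_countries != scen_countries:
        raise AlignmentError(
            f"country sets differ: only-base={sorted(base_countries - scen_countries)}, "
            f"only-scenario={sorted(scen_countries - base_countries)}"
        )
    return {c: scenario_medians[c] - base_medians[c] for c in sorted(base_countries)}


def diversity_count(iron_by_food: pd.Series | Mapping[str, float], threshold: float = 0.99) -> int:
    """Smallest number of foods whose iron adds up to ``threshold`` of the total.

    Foods are taken in decreasing order of iron contribution, ties broken by
    food_id so the count is deterministic.
    """
    if not 0 < threshold <= 1:
        raise DomainError(f"threshold must lie in (0, 1], got {threshold}")
    series = pd.Series(dict(iron_by_food) if not isinstance(iron_by_food, pd.Series) else iron_by_food)
    series = series[series > 0]
    total = float(series.sum())
    if total <= 0:
        raise DomainError("total iron is zero; diversity undefined")
    ordered = series.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )
    cumulative = np.cumsum(ordered.to_numpy()) / total
    # First index reaching the threshold (tolerate float round-off at 1.0).
    k = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    return min(k, len(ordered))


@dataclass(frozen=True)
class DiversityPoint:
    """One country's iron-source diversity paired with its anemia prevalence."""

    country: str
    n_iron_sources: int
    anemia_pct: float
    wild_harvest_flag: bool


def diversity_points(
    iron: IronSupply,
    national: SupplyTable,
    catalog: FoodCatalog,
    anemia: AnemiaTable,
    group,
    threshold: float = 0.99,
    wild_energy_share_threshold: float = 0.05,
) -> list[DiversityPoint]:
    """Diversity statistic per country for one age-sex group.

    The wild-harvest flag marks countries whose wild-flagged foods contribute
    more than ``wild_energy_share_threshold`` of national dietary energy —
    their supply statistics understate true diets, so the anemia fit can
    exclude them.
    """
    token = group_token(group)
    points = []
    for country in national.countries:
        vec = iron.vector(country, token)
        if vec.empty:
            continue
        n = diversity_count(vec, threshold)
        national_vec = national.for_country_group(country, NATIONAL)
        energies = np.array(
            [g * catalog[f].energy_density / 100.0 for f, g in national_vec.items()]
        )
        wild = np.array([catalog[f].is_wild_harvest for f in national_vec.index])
        total_energy = energies.sum()
        wild_share = energies[wild].sum() / total_energy if total_energy > 0 else 0.0
        points.append(
            DiversityPoint(
                country=country,
                n_iron_sources=n,
                anemia_pct=anemia.value(country, token),
                wild_harvest_flag=bool(wild_share > wild_energy_share_threshold),
            )
        )
    return points


@dataclass(frozen=True)
class DiversityFit:
    """OLS fit of iron-source counts against log anemia prevalence."""

    intercept: float
    slope: float
    n_points: int
    pearson_r: float


def diversity_anemia_fit(
    points: Sequence[DiversityPoint],
    exclude_wild: bool = False,
    log_counts: bool = False,
) -> DiversityFit:
    """Fit ``n_sources = a + b * log(anemia_pct)`` by ordinary least squares.

    With ``exclude_wild``, countries flagged for high wild-harvest consumption
    are dropped first.  ``log_counts`` fits ``log(n_sources)`` on anemia
    instead (the alternative reading of a logarithmic association).  Natural
    logarithms throughout.
    """
    kept = [p for p in points if not (exclude_wild and p.wild_harvest_flag)]
    if len(kept) < 3:
        raise DomainError(f"need >= 3 points for the fit, got {len(kept)}")
    for p in kept:
        if p.anemia_pct <= 0:
            raise DomainError(f"country {p.country!r}: anemia must be > 0 for the fit")
    if log_counts:
        x = np.array([p.anemia_pct for p in kept])
        y = np.array([math.log(p.n_iron_sources) for p in kept])
    else:
        x = np.array([math.log(p.anemia_pct) for p in kept])
        y = np.array([float(p.n_iron_sources) for p in kept], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return DiversityFit(float(intercept), float(slope), len(kept), r)


def income_iron_correlation(
    nonanimal_share: Mapping[str, float], gdp_per_capita: Mapping[str, float]
) -> float:
    """Pearson correlation of nonanimal iron share with log GDP per capita.

    A descriptive reporting statistic only; countries present in both
    mappings are used.
    """
    countries = sorted(set(nonanimal_share) & set(gdp_per_capita))
    if len(countries) < 3:
        raise DomainError(f"need >= 3 countries in common, got {len(countries)}")
    x = np.array([math.log(gdp_per_capita[c]) for c in countries])
    y = np.array([nonanimal_share[c] for c in countries])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
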