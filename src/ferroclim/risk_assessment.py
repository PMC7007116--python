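"""Risk stratification: crossing iron-loss estimates with anemia prevalence.

A country/stratum is placed in one of four categories from two axes: the
median percentage iron loss (tertile bands, default fixed cutoffs 3.1% and
3.8%) and the current anemia prevalence (threshold 20%):

* ``HIGH``     — loss above the upper cutoff and anemia above the threshold;
* ``MODERATE`` — loss in the middle band (inclusive) and anemia above;
* ``MILD``     — loss in the middle band and anemia at or below the
  threshold, and (by this package's convention, configurable) loss above the
  upper cutoff with anemia at or below the threshold;
* ``NONE``     — loss below the lower cutoff, regardless of anemia.

Boundary conventions: a loss exactly equal to either cutoff belongs to the
middle band; an anemia prevalence of exactly the threshold counts as "not
over" it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError
from .food_data_io import AnemiaTable, PopulationTable
from .iron_supply import IronSupply

__all__ = [
    "Category",
    "RiskConfig",
    "RiskAssessment",
    "classify",
    "tertile_cutoffs",
    "assess",
    "aggregate_population",
    "top_lost_sources",
]


class Category(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    MILD = "MILD"
    NONE = "NONE"


class TertileMode(str, enum.Enum):
    FIXED = "FIXED"
    RECOMPUTE = "RECOMPUTE"


@dataclass(frozen=True)
class RiskConfig:
    """Thresholds of the risk classification.

    Defaults reproduce the published rule set: 20% anemia threshold and the
    fixed loss tertile cutoffs 3.1%/3.8%.  ``tertile_mode=RECOMPUTE`` derives
    the cutoffs from the analysed countries' own loss distribution instead.
    ``high_loss_low_anemia`` names the category for the cell the published
    rules leave unstated (loss above the upper cutoff, anemia not over the
    threshold); MILD is the conservative default.
    """

    anemia_threshold: float = 20.0
    loss_cut_hi: float = 3.8
    loss_cut_lo: float = 3.1
    tertile_mode: TertileMode = TertileMode.FIXED
    high_loss_low_anemia: Category = Category.MILD

    def __post_init__(self) -> None:
        if not self.loss_cut_lo < self.loss_cut_hi:
            raise DomainError(
                f"loss_cut_lo ({self.loss_cut_lo}) must be < loss_cut_hi "
                f"({self.loss_cut_hi})"
            )
        if not 0 < self.anemia_threshold < 100:
            raise DomainError(
                f"anemia_threshold must lie in (0, 100), got {self.anemia_threshold}"
            )


def classify(loss_pct: float, anemia_pct: float, cfg: RiskConfig = RiskConfig()) -> Category:
    """Assign the risk category for one (loss, anemia) pair."""
    if not (np.isfinite(loss_pct) and np.isfinite(anemia_pct)):
        raise DomainError("loss and anemia must be finite")
    anemic = anemia_pct > cfg.anemia_threshold
    if loss_pct < cfg.loss_cut_lo:
        return Category.NONE
    if loss_pct <= cfg.loss_cut_hi:
        return Category.MODERATE if anemic else Category.MILD
    return Category.HIGH if anemic else cfg.high_loss_low_anemia


def tertile_cutoffs(losses) -> tuple[float, float]:
    """Empirical 33.33%/66.67% quantiles of per-country median losses."""
    values = np.asarray(list(losses), dtype=float)
    if values.size < 3:
        raise DomainError(f"need >= 3 countries for tertiles, got {values.size}")
    lo, hi = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    return float(lo), float(hi)


@dataclass
class RiskAssessment:
    """Per-(country, group) categories plus the thresholds actually used."""

    frame: pd.DataFrame  # country, group, median_loss_pct, anemia_pct, category
    config: RiskConfig
    cutoffs: tuple[float, float] = field(default=(3.1, 3.8))

    def category(self, country: str, group: str) -> Category:
        sub = self.frame[
            (self.frame["country"] == country) & (self.frame["group"] == group)
        ]
        if sub.empty:
            raise KeyError(f"no assessment for ({country!r}, {group!r})")
        return Category(sub.iloc[0]["category"])

    def units_in(self, category: Category) -> list[tuple[str, str]]:
        sub = self.frame[self.frame["category"] == category.value]
        return sorted(zip(sub["country"], sub["group"]))


def assess(
    median_losses: Mapping[tuple[str, str], float],
    anemia: AnemiaTable,
    cfg: RiskConfig = RiskConfig(),
) -> RiskAssessment:
    """Classify every (country, group) given its median loss and anemia.

    ``median_losses`` maps (country, group token) to the median percentage
    loss — typically ``LossDistribution.summary()`` reshaped.  With
    ``tertile_mode=RECOMPUTE`` one cutoff pair is derived from the pooled
    per-unit medians and applied to all groups.
    """
    if cfg.tertile_mode is TertileMode.RECOMPUTE:
        lo, hi = tertile_cutoffs(median_losses.values())
        cfg = RiskConfig(
            anemia_threshold=cfg.anemia_threshold,
            loss_cut_hi=hi,
            loss_cut_lo=lo,
            tertile_mode=TertileMode.RECOMPUTE,
            high_loss_low_anemia=cfg.high_loss_low_anemia,
        )
    rows = []
    for (country, group), loss in sorted(median_losses.items()):
        prevalence = anemia.value(country, group)
        rows.append(
            (country, group, loss, prevalence, classify(loss, prevalence, cfg).value)
        )
    frame = pd.DataFrame(
        rows, columns=["country", "group", "median_loss_pct", "anemia_pct", "category"]
    )
    return RiskAssessment(frame, cfg, (cfg.loss_cut_lo, cfg.loss_cut_hi))


def aggregate_population(
    assessment: RiskAssessment, populations: PopulationTable
) -> pd.DataFrame:
    """Headcount and share per risk category, by group and combined.

    Returns rows (group, category, persons, share_pct) where share_pct is
    relative to that group's total covered population; group ``ALL`` pools
    both study groups.  Raises ``KeyError`` when a classified unit has no
    population row.
    """
    frame = assessment.frame.copy()
    frame["persons"] = [
        populations.value(c, g) for c, g in zip(frame["country"], frame["group"])
    ]
    rows = []
    group_keys = sorted(frame["group"].unique()) + ["ALL"]
    for group in group_keys:
        sub = frame if group == "ALL" else frame[frame["group"] == group]
        total = sub["persons"].sum()
        for category in Category:
            persons = float(sub[sub["category"] == category.value]["persons"].sum())
            share = 100.0 * persons / total if total > 0 else 0.0
            rows.append((group, category.value, persons, share))
    return pd.DataFrame(rows, columns=["group", "category", "persons", "share_pct"])


def top_lost_sources(
    iron: IronSupply,
    expected_change_pct: Mapping[str, float],
    populations: PopulationTable,
    assessment: RiskAssessment,
) -> pd.DataFrame:
    """Aggregate iron lost per food (kg/day) across HIGH-risk populations.

    For each food, sums per-capita iron (mg/person/day) times its expected
    loss fraction times the headcount over every HIGH-classified
    (country, group), converted mg to kg.  Sorted by mass lost, descending;
    ties broken by food_id.
    """
    totals: dict[str, float] = {}
    for country, group in assessment.units_in(Category.HIGH):
        persons = populations.value(country, group)
        vec = iron.vector(country, group)
        for food_id, mg_per_day in vec.items():
            loss_fraction = -expected_change_pct.get(food_id, 0.0) / 100.0
            totals[food_id] = totals.get(food_id, 0.0) + (
                mg_per_day * loss_fraction * persons * 1e-6
            )
    out = pd.DataFrame(
        sorted(totals.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["food_id", "kg_per_day"],
    )
    out["rank"] = range(1, len(out) + 1)
    return out
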