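"""Core domain types and delimited-text I/O for the dietary-iron pipeline.

Every table travels as a comma-separated UTF-8 file with one header line and
"." as the decimal mark.  Countries are free-text opaque keys; age-sex groups
are encoded as ``SEX_AGELO_AGEHI`` tokens (for example ``F_15_49`` for women of
childbearing age) and the token ``NATIONAL`` denotes the national-average
population.  A food whose ``gdd_group`` column holds the literal token ``NONE``
has no dietary-database food group and is disaggregated through the
energy-requirement fallback.

Schemas
-------
foods.csv         food_id,food_name,genus_group,gdd_group,eco2_category,
                  iron_mg_per_100g,kcal_per_100g,is_animal,is_wild
supply.csv        country,food_id,group,g_per_day
gdd.csv           country,gdd_group,sex,age_lo,age_hi,factor,factor_sd
energy.csv        country,group,kcal_per_day        (group NATIONAL = supply)
anemia.csv        country,group,prevalence_pct
population.csv    country,group,persons
eco2_effects.csv  crop_or_category,level,mean_pct_change,ci_lo,ci_hi,
                  n_samples,p_value
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "NATIONAL",
    "GDD_ABSENT_TOKEN",
    "ECO2Category",
    "AFFECTED_CATEGORIES",
    "AgeSexGroup",
    "CHILDREN_1_5",
    "WOMEN_15_49",
    "STUDY_GROUPS",
    "FoodRecord",
    "FoodCatalog",
    "SupplyTable",
    "GDDFactor",
    "GDDFactorTable",
    "EnergyTable",
    "AnemiaTable",
    "PopulationTable",
    "ECO2Effect",
    "ECO2EffectTable",
    "TableBundle",
    "load_food_catalog",
    "save_food_catalog",
    "load_supply_table",
    "save_supply_table",
    "load_gdd_factors",
    "save_gdd_factors",
    "load_energy_profiles",
    "save_energy_profiles",
    "load_anemia",
    "save_anemia",
    "load_population",
    "save_population",
    "load_eco2_effects",
    "save_eco2_effects",
]

#: Group token for the national-average population.
NATIONAL = "NATIONAL"

#: Literal token marking the absence of a dietary-database food group.
GDD_ABSENT_TOKEN = "NONE"


class ECO2Category(str, enum.Enum):
    """Response class of a food's iron content to elevated CO2 (~550 ppm)."""

    C3_GRAIN = "C3_GRAIN"
    LEGUME = "LEGUME"
    MAIZE = "MAIZE"
    ZERO_EFFECT = "ZERO_EFFECT"
    ANIMAL = "ANIMAL"
    OTHER_VEGETAL = "OTHER_VEGETAL"


#: Categories whose iron content declines under elevated CO2.
AFFECTED_CATEGORIES = frozenset(
    {ECO2Category.C3_GRAIN, ECO2Category.LEGUME, ECO2Category.MAIZE}
)

_SEXES = ("F", "M", "BOTH")


@dataclass(frozen=True, order=True)
class AgeSexGroup:
    """A population stratum defined by sex and an inclusive age band in years."""

    sex: str
    age_lo: int
    age_hi: int

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.age_lo > self.age_hi:
            raise ValidationError(
                f"age_lo ({self.age_lo}) must not exceed age_hi ({self.age_hi})"
            )

    @property
    def token(self) -> str:
        return f"{self.sex}_{self.age_lo}_{self.age_hi}"

    @classmethod
    def from_token(cls, token: str) -> "AgeSexGroup":
        parts = token.split("_")
        if len(parts) != 3:
            raise ValidationError(f"malformed age-sex token {token!r}")
        sex, lo, hi = parts
        try:
            return cls(sex, int(lo), int(hi))
        except ValueError as exc:
            raise ValidationError(f"malformed age-sex token {token!r}") from exc

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


#: The two vulnerable strata the analysis targets.
CHILDREN_1_5 = AgeSexGroup("BOTH", 1, 5)
WOMEN_15_49 = AgeSexGroup("F", 15, 49)
STUDY_GROUPS = (CHILDREN_1_5, WOMEN_15_49)


def group_token(group) -> str:
    """Normalise a group given as token string or :class:`AgeSexGroup`."""
    if isinstance(group, AgeSexGroup):
        return group.token
    return str(group)


@dataclass(frozen=True)
class FoodRecord:
    """One food with its composition, CO2-response class and source flags.

    ``iron_density`` is mg iron per 100 g edible portion and ``energy_density``
    kcal per 100 g edible portion.  ``gdd_group`` is ``None`` for foods with no
    dietary-database group (they fall back to energy-requirement scaling).
    """

    food_id: str
    food_name: str
    genus_group: str
    gdd_group: str | None
    eco2_category: ECO2Category
    iron_density: float
    energy_density: float
    is_animal_source: bool = False
    is_wild_harvest: bool = False

    def __post_init__(self) -> None:
        for name, value in (
            ("iron_density", self.iron_density),
            ("energy_density", self.energy_density),
        ):
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"food {self.food_id!r}: {name} must be finite and >= 0, got {value}"
                )
        if (self.eco2_category is ECO2Category.ANIMAL) != self.is_animal_source:
            raise ValidationError(
                f"food {self.food_id!r}: eco2_category ANIMAL and is_animal_source "
                "must agree"
            )


class FoodCatalog:
    """An immutable collection of :class:`FoodRecord` keyed by ``food_id``."""

    def __init__(self, records: Iterable[FoodRecord]):
        self._records: dict[str, FoodRecord] = {}
        for rec in records:
            if rec.food_id in self._records:
                raise ValidationError(f"duplicate food_id {rec.food_id!r} in catalog")
            self._records[rec.food_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[FoodRecord]:
        return iter(self._records.values())

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._records

    def __getitem__(self, food_id: str) -> FoodRecord:
        try:
            return self._records[food_id]
        except KeyError:
            raise KeyError(f"food {food_id!r} not in catalog") from None

    def get(self, food_id: str, default=None):
        return self._records.get(food_id, default)

    @property
    def food_ids(self) -> list[str]:
        return sorted(self._records)


class SupplyTable:
    """Per-capita edible supply (g/person/day) keyed by (country, food, group)."""

    COLUMNS = ["country", "food_id", "group", "g_per_day"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.loc[:, self.COLUMNS].copy()
        frame["g_per_day"] = frame["g_per_day"].astype(float)
        bad = frame[~frame["g_per_day"].apply(math.isfinite) | (frame["g_per_day"] < 0)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"supply for ({row.country!r}, {row.food_id!r}, {row.group!r}) "
                f"must be finite and >= 0, got {row.g_per_day}"
            )
        keys = list(zip(frame["country"], frame["food_id"], frame["group"]))
        if len(set(keys)) != len(keys):
            seen: set = set()
            for key in keys:
                if key in seen:
                    raise ValidationError(f"duplicate supply key {key}")
                seen.add(key)
        self._frame = frame.sort_values(self.COLUMNS[:3], kind="mergesort").reset_index(
            drop=True
        )
        self._index: dict[tuple[str, str, str], float] = dict(
            zip(keys, frame["g_per_day"])
        )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, float]]
    ) -> "SupplyTable":
        frame = pd.DataFrame(list(records), columns=cls.COLUMNS)
        return cls(frame)

    def value(self, country: str, food_id: str, group) -> float:
        key = (country, food_id, group_token(group))
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"no supply entry for {key}") from None

    def get(self, country: str, food_id: str, group, default=None):
        return self._index.get((country, food_id, group_token(group)), default)

    @property
    def countries(self) -> list[str]:
        return sorted(self._frame["country"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self._frame["group"].unique())

    @property
    def food_ids(self) -> list[str]:
        return sorted(self._frame["food_id"].unique())

    def for_country_group(self, country: str, group) -> pd.Series:
        """Supplies of one country/group as a Series indexed by food_id."""
        token = group_token(group)
        sub = self._frame[
            (self._frame["country"] == country) & (self._frame["group"] == token)
        ]
        return pd.Series(
            sub["g_per_day"].to_numpy(), index=sub["food_id"].to_numpy(), name="g_per_day"
        )

    def entries(self) -> Iterator[tuple[str, str, str, float]]:
        return self._frame.itertuples(index=False, name=None)

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SupplyTable):
            return NotImplemented
        return self._frame.equals(other._frame)


@dataclass(frozen=True)
class GDDFactor:
    """Relative intake of one food group for one country and age-sex stratum.

    ``factor`` multiplies the national-average intake (1.0 = average);
    ``factor_sd`` is its standard deviation, consumed only by the Monte Carlo.
    """

    country: str
    gdd_group: str
    group: AgeSexGroup
    factor: float
    factor_sd: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.factor) or self.factor <= 0:
            raise ValidationError(
                f"GDD factor for ({self.country!r}, {self.gdd_group!r}, "
                f"{self.group.token}) must be > 0, got {self.factor}"
            )
        if not math.isfinite(self.factor_sd) or self.factor_sd < 0:
            raise ValidationError(
                f"GDD factor_sd for ({self.country!r}, {self.gdd_group!r}, "
                f"{self.group.token}) must be >= 0, got {self.factor_sd}"
            )


class GDDFactorTable:
    """Lookup of :class:`GDDFactor` by (country, gdd_group, group token)."""

    def __init__(self, factors: Iterable[GDDFactor]):
        self._index: dict[tuple[str, str, str], GDDFactor] = {}
        for f in factors:
            key = (f.country, f.gdd_group, f.group.token)
            if key in self._index:
                raise ValidationError(f"duplicate GDD factor key {key}")
            self._index[key] = f

    def lookup(self, country: str, gdd_group: str, group) -> GDDFactor | None:
        return self._index.get((country, gdd_group, group_token(group)))

    def __iter__(self) -> Iterator[GDDFactor]:
        return iter(
            sorted(self._index.values(), key=lambda f: (f.country, f.gdd_group, f.group))
        )

    def __len__(self) -> int:
        return len(self._index)


class _GroupKeyedTable:
    """Common machinery for tables keyed by (country, group token)."""

    VALUE_NAME = "value"

    def __init__(self, values: Mapping[tuple[str, str], float]):
        self._index = dict(values)
        for (country, token), value in self._index.items():
            self._validate(country, token, value)

    def _validate(self, country: str, token: str, value: float) -> None:
        if not math.isfinite(value):
            raise ValidationError(
                f"{self.VALUE_NAME} for ({country!r}, {token!r}) must be finite"
            )

    def value(self, country: str, group) -> float:
        key = (country, group_token(group))
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"no {self.VALUE_NAME} entry for {key}") from None

    def get(self, country: str, group, default=None):
        return self._index.get((country, group_token(group)), default)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(sorted(self._index.items()))

    @property
    def countries(self) -> list[str]:
        return sorted({country for country, _ in self._index})

    def __len__(self) -> int:
        return len(self._index)


class EnergyTable(_GroupKeyedTable):
    """Dietary energy (kcal/person/day): national supply and group requirements."""

    VALUE_NAME = "kcal_per_day"

    def _validate(self, country, token, value):
        super()._validate(country, token, value)
        if value <= 0:
            raise ValidationError(
                f"kcal_per_day for ({country!r}, {token!r}) must be > 0, got {value}"
            )

    def national(self, country: str) -> float:
        return self.value(country, NATIONAL)

    def requirement(self, country: str, group) -> float:
        return self.value(country, group)


class AnemiaTable(_GroupKeyedTable):
    """Anemia prevalence (percent of the stratum) by country and group."""

    VALUE_NAME = "prevalence_pct"

    def _validate(self, country, token, value):
        super()._validate(country, token, value)
        if not 0 <= value <= 100:
            raise ValidationError(
                f"prevalence_pct for ({country!r}, {token!r}) must lie in [0, 100], "
                f"got {value}"
            )


class PopulationTable(_GroupKeyedTable):
    """Headcounts (persons) by country and age-sex group."""

    VALUE_NAME = "persons"

    def _validate(self, country, token, value):
        super()._validate(country, token, value)
        if value < 0:
            raise ValidationError(
                f"persons for ({country!r}, {token!r}) must be >= 0, got {value}"
            )


class EffectLevel(str, enum.Enum):
    CROP = "CROP"
    CATEGORY = "CATEGORY"


@dataclass(frozen=True)
class ECO2Effect:
    """Percentage change in iron content under elevated CO2, with uncertainty.

    ``target`` is a ``food_id`` for crop-level rows or an
    :class:`ECO2Category` name for category-level rows.  ``ci_lo``/``ci_hi``
    bound the reported 95% interval, ``n_samples`` counts the crop samples
    behind the estimate, and ``p_value`` carries its significance.
    """

    target: str
    level: EffectLevel
    mean_pct_change: float
    ci_lo: float
    ci_hi: float
    n_samples: int
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.mean_pct_change <= self.ci_hi):
            raise ValidationError(
                f"effect {self.target!r}: interval [{self.ci_lo}, {self.ci_hi}] "
                f"must bracket the mean {self.mean_pct_change}"
            )
        if self.n_samples <= 0:
            raise ValidationError(
                f"effect {self.target!r}: n_samples must be > 0, got {self.n_samples}"
            )
        if not 0 <= self.p_value <= 1:
            raise ValidationError(
                f"effect {self.target!r}: p_value must lie in [0, 1], got {self.p_value}"
            )

    @property
    def is_zero_width(self) -> bool:
        return self.ci_lo == self.ci_hi


class ECO2EffectTable:
    """Crop- and category-level CO2 effects with convenience lookups."""

    def __init__(self, effects: Iterable[ECO2Effect]):
        self._effects = list(effects)
        seen: set[tuple[str, str]] = set()
        for e in self._effects:
            key = (e.target, e.level.value)
            if key in seen:
                raise ValidationError(f"duplicate effect row for {key}")
            seen.add(key)

    def crop(self, food_id: str) -> ECO2Effect | None:
        for e in self._effects:
            if e.level is EffectLevel.CROP and e.target == food_id:
                return e
        return None

    def category(self, category: ECO2Category | str) -> ECO2Effect | None:
        name = category.value if isinstance(category, ECO2Category) else category
        for e in self._effects:
            if e.level is EffectLevel.CATEGORY and e.target == name:
                return e
        return None

    def __iter__(self) -> Iterator[ECO2Effect]:
        return iter(self._effects)

    def __len__(self) -> int:
        return len(self._effects)


# ---------------------------------------------------------------------------
# CSV plumbing


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file {path} does not exist")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in frame.columns if c not in columns]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    return frame.loc[:, columns]


def _write_csv(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n")


def _as_float(value: str, context: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"{context}: cannot parse {value!r} as a number") from None


def _as_int(value: str, context: str) -> int:
    try:
        return int(float(value))
    except ValueError:
        raise ValidationError(f"{context}: cannot parse {value!r} as an integer") from None


def _as_flag(value: str, context: str) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise ValidationError(f"{context}: flag must be 0 or 1, got {value!r}")


FOODS_COLUMNS = [
    "food_id",
    "food_name",
    "genus_group",
    "gdd_group",
    "eco2_category",
    "iron_mg_per_100g",
    "kcal_per_100g",
    "is_animal",
    "is_wild",
]


def load_food_catalog(path) -> FoodCatalog:
    """Read ``foods.csv`` into a validated :class:`FoodCatalog`."""
    frame = _read_csv(path, FOODS_COLUMNS)
    records = []
    for row in frame.itertuples(index=False):
        ctx = f"food {row.food_id!r}"
        try:
            category = ECO2Category(row.eco2_category)
        except ValueError:
            raise ValidationError(
                f"{ctx}: unknown eco2_category {row.eco2_category!r}"
            ) from None
        records.append(
            FoodRecord(
                food_id=row.food_id,
                food_name=row.food_name,
                genus_group=row.genus_group,
                gdd_group=None if row.gdd_group == GDD_ABSENT_TOKEN else row.gdd_group,
                eco2_category=category,
                iron_density=_as_float(row.iron_mg_per_100g, ctx),
                energy_density=_as_float(row.kcal_per_100g, ctx),
                is_animal_source=_as_flag(row.is_animal, ctx),
                is_wild_harvest=_as_flag(row.is_wild, ctx),
            )
        )
    return FoodCatalog(records)


def save_food_catalog(catalog: FoodCatalog, path) -> None:
    rows = [
        (
            r.food_id,
            r.food_name,
            r.genus_group,
            GDD_ABSENT_TOKEN if r.gdd_group is None else r.gdd_group,
            r.eco2_category.value,
            float(r.iron_density),
            float(r.energy_density),
            int(r.is_animal_source),
            int(r.is_wild_harvest),
        )
        for r in sorted(catalog, key=lambda r: r.food_id)
    ]
    _write_csv(pd.DataFrame(rows, columns=FOODS_COLUMNS), path)


def load_supply_table(path) -> SupplyTable:
    frame = _read_csv(path, SupplyTable.COLUMNS)
    frame["g_per_day"] = [
        _as_float(v, f"supply row ({c!r}, {f!r}, {g!r})")
        for c, f, g, v in frame.itertuples(index=False)
    ]
    return SupplyTable(frame)


def save_supply_table(table: SupplyTable, path) -> None:
    _write_csv(table.to_frame(), path)


GDD_COLUMNS = ["country", "gdd_group", "sex", "age_lo", "age_hi", "factor", "factor_sd"]


def load_gdd_factors(path) -> GDDFactorTable:
    frame = _read_csv(path, GDD_COLUMNS)
    factors = []
    for row in frame.itertuples(index=False):
        ctx = f"GDD row ({row.country!r}, {row.gdd_group!r})"
        group = AgeSexGroup(row.sex, _as_int(row.age_lo, ctx), _as_int(row.age_hi, ctx))
        factors.append(
            GDDFactor(
                country=row.country,
                gdd_group=row.gdd_group,
                group=group,
                factor=_as_float(row.factor, ctx),
                factor_sd=_as_float(row.factor_sd, ctx),
            )
        )
    return GDDFactorTable(factors)


def save_gdd_factors(table: GDDFactorTable, path) -> None:
    rows = [
        (f.country, f.gdd_group, f.group.sex, f.group.age_lo, f.group.age_hi, f.factor, f.factor_sd)
        for f in table
    ]
    _write_csv(pd.DataFrame(rows, columns=GDD_COLUMNS), path)


def _load_group_keyed(path, value_column: str, cls):
    frame = _read_csv(path, ["country", "group", value_column])
    values: dict[tuple[str, str], float] = {}
    for row in frame.itertuples(index=False):
        key = (row.country, row.group)
        if key in values:
            raise ValidationError(f"duplicate {value_column} key {key}")
        values[key] = _as_float(getattr(row, value_column), f"{value_column} row {key}")
    return cls(values)


def _save_group_keyed(table: _GroupKeyedTable, path, value_column: str) -> None:
    rows = [(c, g, v) for (c, g), v in table.items()]
    _write_csv(pd.DataFrame(rows, columns=["country", "group", value_column]), path)


def load_energy_profiles(path) -> EnergyTable:
    return _load_group_keyed(path, "kcal_per_day", EnergyTable)


def save_energy_profiles(table: EnergyTable, path) -> None:
    _save_group_keyed(table, path, "kcal_per_day")


def load_anemia(path) -> AnemiaTable:
    return _load_group_keyed(path, "prevalence_pct", AnemiaTable)


def save_anemia(table: AnemiaTable, path) -> None:
    _save_group_keyed(table, path, "prevalence_pct")


def load_population(path) -> PopulationTable:
    return _load_group_keyed(path, "persons", PopulationTable)


def save_population(table: PopulationTable, path) -> None:
    _save_group_keyed(table, path, "persons")


EFFECTS_COLUMNS = [
    "crop_or_category",
    "level",
    "mean_pct_change",
    "ci_lo",
    "ci_hi",
    "n_samples",
    "p_value",
]


def load_eco2_effects(path) -> ECO2EffectTable:
    frame = _read_csv(path, EFFECTS_COLUMNS)
    effects = []
    for row in frame.itertuples(index=False):
        ctx = f"effect row {row.crop_or_category!r}"
        try:
            level = EffectLevel(row.level)
        except ValueError:
            raise ValidationError(f"{ctx}: unknown level {row.level!r}") from None
        effects.append(
            ECO2Effect(
                target=row.crop_or_category,
                level=level,
                mean_pct_change=_as_float(row.mean_pct_change, ctx),
                ci_lo=_as_float(row.ci_lo, ctx),
                ci_hi=_as_float(row.ci_hi, ctx),
                n_samples=_as_int(row.n_samples, ctx),
                p_value=_as_float(row.p_value, ctx),
            )
        )
    return ECO2EffectTable(effects)


def save_eco2_effects(table: ECO2EffectTable, path) -> None:
    rows = [
        (e.target, e.level.value, e.mean_pct_change, e.ci_lo, e.ci_hi, e.n_samples, e.p_value)
        for e in table
    ]
    _write_csv(pd.DataFrame(rows, columns=EFFECTS_COLUMNS), path)


# ---------------------------------------------------------------------------
# Bundles

_BUNDLE_FILES = {
    "catalog": ("foods.csv", load_food_catalog, save_food_catalog),
    "supply": ("supply.csv", load_supply_table, save_supply_table),
    "gdd": ("gdd.csv", load_gdd_factors, save_gdd_factors),
    "energy": ("energy.csv", load_energy_profiles, save_energy_profiles),
    "anemia": ("anemia.csv", load_anemia, save_anemia),
    "population": ("population.csv", load_population, save_population),
    "effects": ("eco2_effects.csv", load_eco2_effects, save_eco2_effects),
}


@dataclass
class TableBundle:
    """The complete set of input tables one analysis run consumes."""

    catalog: FoodCatalog
    supply: SupplyTable
    gdd: GDDFactorTable
    energy: EnergyTable
    anemia: AnemiaTable
    population: PopulationTable
    effects: ECO2EffectTable

    def save(self, directory) -> dict[str, Path]:
        """Write all seven tables into ``directory``; returns written paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = {}
        for attr, (fname, _loader, saver) in _BUNDLE_FILES.items():
            path = directory / fname
            saver(getattr(self, attr), path)
            written[attr] = path
        return written

    @classmethod
    def load(cls, directory) -> "TableBundle":
        directory = Path(directory)
        kwargs = {
            attr: loader(directory / fname)
            for attr, (fname, loader, _saver) in _BUNDLE_FILES.items()
        }
        return cls(**kwargs)
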