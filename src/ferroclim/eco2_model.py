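"""Elevated-CO2 effect model and Monte Carlo propagation of iron losses.

Each crop (or, where no crop-level estimate exists, each broader category —
C3 grains, legumes, maize) carries a percentage change in iron content under
~550 ppm CO2, reported as a central value with a 95% uncertainty interval and
a sample count.  The model:

* zeroes out effects whose change is not statistically significant
  (``p > alpha``, default 0.05 — e.g. sorghum, potato);
* pools crop-level effects into category effects by sample-count-weighted
  averaging;
* represents each remaining effect as a skew-normal law whose median and
  2.5%/97.5% quantiles reproduce the reported central value and interval;
* propagates effect and intake uncertainty jointly by Monte Carlo: on each
  iteration one percent-change is drawn per effect entry (shared by every
  country and by every food mapped to that entry) and one multiplicative
  intake perturbation per dietary-database factor, and the country's total
  percentage iron loss is the iron-weighted average of its per-food losses.

Losses are reported as positive percentages (a 5% decline in iron is +5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import skewnorm

from .disaggregation import GDD_MATCHED, DisaggregationResult
from .errors import ConfigurationError, DomainError, FitError
from .food_data_io import (
    AFFECTED_CATEGORIES,
    ECO2Category,
    ECO2Effect,
    ECO2EffectTable,
    FoodCatalog,
    FoodRecord,
    GDDFactorTable,
)
from .iron_supply import IronSupply

__all__ = [
    "DEFAULT_ALPHA",
    "SkewNormalParams",
    "EffectDistribution",
    "LossDistribution",
    "apply_zero_effect_rule",
    "pool_category",
    "fit_skew_normal",
    "effect_for_food",
    "build_effect_distributions",
    "expected_pct_change",
    "intake_uncertainty",
    "simulate_losses",
]

DEFAULT_ALPHA = 0.05

_PROBS = np.array([0.025, 0.5, 0.975])
# Half-width of the central 95% interval of a standard normal.
_Z975 = 1.959963984540054
# Attainable relative position of the skew-normal median inside its 95%
# interval: the half-normal limits (shape -> +/- inf) pin it to ~(0.291, 0.709).
_MEDIAN_POSITION_LIMITS = (0.2909, 0.7091)


@dataclass(frozen=True)
class SkewNormalParams:
    """Location, scale and shape of a skew-normal law over percent change.

    With ``shape == 0`` the law reduces to Normal(location, scale).
    """

    location: float
    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise DomainError(f"scale must be > 0, got {self.scale}")

    def frozen(self):
        return skewnorm(self.shape, loc=self.location, scale=self.scale)

    def mean(self) -> float:
        delta = self.shape / math.hypot(1.0, self.shape)
        return self.location + self.scale * delta * math.sqrt(2.0 / math.pi)

    def quantiles(self, probs: Sequence[float] = _PROBS) -> np.ndarray:
        return skewnorm.ppf(np.asarray(probs), self.shape, self.location, self.scale)


class EffectDistribution:
    """A law over percent iron change: skew-normal or degenerate at a point."""

    def __init__(self, params: SkewNormalParams | None = None, point: float = 0.0):
        self.params = params
        self.point = float(point)

    @classmethod
    def zero(cls) -> "EffectDistribution":
        return cls(None, 0.0)

    @classmethod
    def degenerate(cls, value: float) -> "EffectDistribution":
        return cls(None, value)

    @property
    def is_degenerate(self) -> bool:
        return self.params is None

    def mean(self) -> float:
        return self.point if self.is_degenerate else self.params.mean()

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.is_degenerate:
            return np.full(size, self.point)
        return skewnorm.rvs(
            self.params.shape,
            loc=self.params.location,
            scale=self.params.scale,
            size=size,
            random_state=rng,
        )

    def __repr__(self) -> str:  # pragma: no cover
        if self.is_degenerate:
            return f"EffectDistribution(point={self.point})"
        return f"EffectDistribution({self.params})"


def apply_zero_effect_rule(effect: ECO2Effect, alpha: float = DEFAULT_ALPHA) -> ECO2Effect:
    """Zero out a non-significant effect (``p_value > alpha``).

    The returned effect has a mean of exactly 0 and a zero-width interval, so
    downstream it becomes a point mass rather than a fitted law.  Significant
    effects pass through unchanged.
    """
    if effect.p_value > alpha:
        return replace(effect, mean_pct_change=0.0, ci_lo=0.0, ci_hi=0.0)
    return effect


def pool_category(effects: Sequence[ECO2Effect], target: str | None = None) -> ECO2Effect:
    """Pool crop-level effects into one category effect.

    The pooled mean, interval bounds and p-value are sample-count-weighted
    averages of the members'; the pooled sample count is the total.
    """
    effects = list(effects)
    if not effects:
        raise DomainError("cannot pool an empty list of effects")
    weights = np.array([e.n_samples for e in effects], dtype=float)
    if np.any(weights <= 0):
        raise DomainError("all n_samples must be > 0 for pooling")
    weights /= weights.sum()

    def wavg(attr: str) -> float:
        return float(np.dot(weights, [getattr(e, attr) for e in effects]))

    return ECO2Effect(
        target=target if target is not None else effects[0].target,
        level=effects[0].level,
        mean_pct_change=wavg("mean_pct_change"),
        ci_lo=wavg("ci_lo"),
        ci_hi=wavg("ci_hi"),
        n_samples=int(sum(e.n_samples for e in effects)),
        p_value=wavg("p_value"),
    )


def fit_skew_normal(
    median_pct: float, ci_lo: float, ci_hi: float, tol: float = 1e-9
) -> SkewNormalParams:
    """Fit a skew-normal whose median and 2.5%/97.5% quantiles match the inputs.

    The three parameters (location, scale, shape) are found by root-finding on
    the CDF residuals at the three target points, initialised from the normal
    law (shape 0) implied by the interval half-width.  The fit is accepted
    only if the re-evaluated quantiles reproduce the inputs to ``tol``
    (percent units).

    Raises :class:`FitError` when the requested median sits outside the range
    a skew-normal can place it within its own 95% interval (roughly the
    central 29–71% of the interval), or when root-finding fails.
    """
    if not ci_lo < ci_hi:
        raise DomainError(f"interval must have ci_lo < ci_hi, got [{ci_lo}, {ci_hi}]")
    if not ci_lo < median_pct < ci_hi:
        raise FitError(
            f"median {median_pct} lies outside the open interval ({ci_lo}, {ci_hi})"
        )
    rel = (median_pct - ci_lo) / (ci_hi - ci_lo)
    if not _MEDIAN_POSITION_LIMITS[0] < rel < _MEDIAN_POSITION_LIMITS[1]:
        raise FitError(
            f"median position {rel:.4f} within the interval is not attainable by a "
            f"skew-normal (attainable range ~{_MEDIAN_POSITION_LIMITS})"
        )

    targets = np.array([ci_lo, median_pct, ci_hi])
    scale0 = (ci_hi - ci_lo) / (2.0 * _Z975)

    def residual(params: np.ndarray) -> np.ndarray:
        loc, log_scale, shape = params
        scale = math.exp(log_scale)
        return skewnorm.cdf(targets, shape, loc, scale) - _PROBS

    best: SkewNormalParams | None = None
    best_err = np.inf
    for shape0 in (0.0, 1.0, -1.0, 3.0, -3.0, 8.0, -8.0):
        sol = optimize.root(
            residual,
            x0=np.array([median_pct, math.log(scale0), shape0]),
            method="hybr",
            tol=1e-13,
        )
        loc, log_scale, shape = sol.x
        try:
            params = SkewNormalParams(float(loc), float(math.exp(log_scale)), float(shape))
        except DomainError:  # pragma: no cover - log-parametrised, cannot trip
            continue
        err = float(np.max(np.abs(params.quantiles() - targets)))
        if err < best_err:
            best, best_err = params, err
        if best_err < tol:
            break
    if best is None or best_err > max(tol, 1e-6):
        raise FitError(
            f"skew-normal fit to (median={median_pct}, lo={ci_lo}, hi={ci_hi}) "
            f"did not converge (max quantile residual {best_err:.3e})",
            residuals=best_err,
        )
    return best


def _distribution_from_effect(effect: ECO2Effect, alpha: float) -> EffectDistribution:
    effect = apply_zero_effect_rule(effect, alpha)
    if effect.is_zero_width:
        return EffectDistribution.degenerate(effect.mean_pct_change)
    return EffectDistribution(
        fit_skew_normal(effect.mean_pct_change, effect.ci_lo, effect.ci_hi)
    )


_ZERO_KEY = ("zero", "")


def _resolve_effect(
    food: FoodRecord, effects: ECO2EffectTable, alpha: float
) -> tuple[tuple[str, str], ECO2Effect | None]:
    """Pick the effect row governing a food, or None for an exact zero.

    The first element keys the shared Monte Carlo draw: foods resolved to the
    same crop or category row share one draw per iteration.
    """
    category = food.eco2_category
    if category in (ECO2Category.ANIMAL, ECO2Category.ZERO_EFFECT):
        crop = effects.crop(food.food_id)
        if crop is not None:  # e.g. sorghum/potato rows carrying the p-value
            return ("crop", food.food_id), crop
        return _ZERO_KEY, None
    crop = effects.crop(food.food_id)
    if crop is not None:
        return ("crop", food.food_id), crop
    if category in AFFECTED_CATEGORIES:
        cat_effect = effects.category(category)
        if cat_effect is None:
            raise ConfigurationError(
                f"food {food.food_id!r} has category {category.value} but no crop- or "
                "category-level effect row"
            )
        return ("category", category.value), cat_effect
    return _ZERO_KEY, None  # OTHER_VEGETAL without a crop row


def effect_for_food(
    food: FoodRecord, effects: ECO2EffectTable, alpha: float = DEFAULT_ALPHA
) -> EffectDistribution:
    """Distribution of percent iron change for one food under elevated CO2."""
    _key, effect = _resolve_effect(food, effects, alpha)
    if effect is None:
        return EffectDistribution.zero()
    return _distribution_from_effect(effect, alpha)


def build_effect_distributions(
    catalog: FoodCatalog, effects: ECO2EffectTable, alpha: float = DEFAULT_ALPHA
) -> dict[str, tuple[tuple[str, str], EffectDistribution]]:
    """Map every catalog food to its (shared draw key, effect distribution)."""
    cache: dict[tuple[str, str], EffectDistribution] = {
        _ZERO_KEY: EffectDistribution.zero()
    }
    out: dict[str, tuple[tuple[str, str], EffectDistribution]] = {}
    for food in catalog:
        key, effect = _resolve_effect(food, effects, alpha)
        if key not in cache:
            cache[key] = _distribution_from_effect(effect, alpha)
        out[food.food_id] = (key, cache[key])
    return out


def expected_pct_change(
    catalog: FoodCatalog, effects: ECO2EffectTable, alpha: float = DEFAULT_ALPHA
) -> dict[str, float]:
    """Expected percent iron change per food (negative = loss)."""
    dists = build_effect_distributions(catalog, effects, alpha)
    return {food_id: dist.mean() for food_id, (_key, dist) in dists.items()}


def intake_uncertainty(
    disaggregation: DisaggregationResult,
    catalog: FoodCatalog,
    gdd: GDDFactorTable,
) -> dict[tuple[str, str, str], tuple[tuple[str, str, str], float]]:
    """Relative intake uncertainty per disaggregated entry.

    Maps (country, food_id, group token) to a (perturbation key, coefficient
    of variation) pair for every GDD-matched entry with positive factor_sd.
    Entries sharing a dietary-database factor share the perturbation key and
    hence the Monte Carlo draw.
    """
    out: dict[tuple[str, str, str], tuple[tuple[str, str, str], float]] = {}
    for (country, food_id, token), route in disaggregation.provenance.items():
        if route != GDD_MATCHED:
            continue
        record = catalog[food_id]
        factor_row = gdd.lookup(country, record.gdd_group, token)
        if factor_row is None or factor_row.factor_sd <= 0:
            continue
        cv = factor_row.factor_sd / factor_row.factor
        out[(country, food_id, token)] = ((country, record.gdd_group, token), cv)
    return out


@dataclass
class LossDistribution:
    """Monte Carlo draws of total percentage dietary-iron loss.

    ``draws`` maps (country, group token) to a length-``n_draws`` vector of
    positive loss percentages.  ``effect_draws`` is the shared (n_draws x
    n_effect_keys) matrix of sampled percent changes and ``food_effect_col``
    maps each food to its column (exact-zero foods point at the all-zero
    column), which lets callers audit per-draw convexity bounds.
    """

    draws: dict[tuple[str, str], np.ndarray]
    effect_keys: list[tuple[str, str]]
    effect_draws: np.ndarray
    food_effect_col: dict[str, int]
    seed: int

    @property
    def n_draws(self) -> int:
        return self.effect_draws.shape[0]

    def loss(self, country: str, group: str) -> np.ndarray:
        return self.draws[(country, group)]

    def median(self, country: str, group: str) -> float:
        return float(np.median(self.draws[(country, group)]))

    def summary(self) -> pd.DataFrame:
        rows = [
            (
                country,
                group,
                float(np.median(vec)),
                float(np.quantile(vec, 0.025)),
                float(np.quantile(vec, 0.975)),
            )
            for (country, group), vec in sorted(self.draws.items())
        ]
        return pd.DataFrame(
            rows, columns=["country", "group", "median_loss_pct", "lo95", "hi95"]
        )


def simulate_losses(
    iron: IronSupply,
    catalog: FoodCatalog,
    effects: ECO2EffectTable,
    gdd_uncertainty: Mapping[tuple[str, str, str], tuple[tuple[str, str, str], float]]
    | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> LossDistribution:
    """Monte Carlo propagation of CO2 effects (and intake uncertainty) to losses.

    On each iteration one percent-change is sampled per effect entry — shared
    across countries and across the foods mapped to that entry — and, when
    ``gdd_uncertainty`` is given, one mean-one log-normal multiplier
    ``exp(sigma Z - sigma^2/2)`` per dietary-database factor.  The country's
    loss on that iteration is ``-sum(iron_f * delta_f) / sum(iron_f)`` in
    percent, an iron-weighted average of per-food changes.
    """
    if n_draws < 1:
        raise DomainError(f"n_draws must be >= 1, got {n_draws}")
    dists = build_effect_distributions(catalog, effects, alpha)

    # Sample the shared effect matrix, one column per draw key, in sorted key
    # order so results are reproducible.
    keys = sorted({key for key, _dist in dists.values()})
    key_col = {key: j for j, key in enumerate(keys)}
    rng = np.random.default_rng(seed)
    effect_draws = np.zeros((n_draws, len(keys)))
    for key in keys:
        dist = next(d for k, d in dists.values() if k == key)
        effect_draws[:, key_col[key]] = dist.sample(rng, n_draws)

    gdd_uncertainty = dict(gdd_uncertainty or {})
    pert_keys = sorted({pk for pk, _cv in gdd_uncertainty.values()})
    pert_col = {pk: j for j, pk in enumerate(pert_keys)}
    z = rng.standard_normal((n_draws, len(pert_keys))) if pert_keys else None

    food_effect_col = {food_id: key_col[key] for food_id, (key, _d) in dists.items()}

    draws: dict[tuple[str, str], np.ndarray] = {}
    for country, group in iron.units():
        vec = iron.vector(country, group)
        vec = vec[vec.to_numpy() > 0]
        total = float(vec.sum())
        if total <= 0:
            raise DomainError(
                f"total iron for ({country!r}, {group!r}) is zero; loss undefined"
            )
        foods = list(vec.index)
        base = vec.to_numpy()  # (n_foods,)
        cols = np.array([food_effect_col[f] for f in foods])
        deltas = effect_draws[:, cols]  # (n_draws, n_foods), percent change

        if z is not None:
            mult = np.ones((n_draws, len(foods)))
            for j, food_id in enumerate(foods):
                entry = gdd_uncertainty.get((country, food_id, group))
                if entry is None:
                    continue
                pk, cv = entry
                zz = z[:, pert_col[pk]]
                mult[:, j] = np.exp(cv * zz - 0.5 * cv * cv)
            iron_draws = base[None, :] * mult
        else:
            iron_draws = np.broadcast_to(base[None, :], (n_draws, len(foods)))

        loss = -(iron_draws * deltas).sum(axis=1) / iron_draws.sum(axis=1)
        draws[(country, group)] = loss

    return LossDistribution(
        draws=draws,
        effect_keys=keys,
        effect_draws=effect_draws,
        food_effect_col=food_effect_col,
        seed=seed,
    )
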