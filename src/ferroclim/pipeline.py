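"""End-to-end orchestration: one configuration, one output directory.

``run_all`` sequences the stages — age-sex disaggregation, iron accounting,
Monte Carlo loss simulation, risk classification, the vegetarian scenario and
the diversity statistic — writes every result as CSV/JSON, and records a
manifest with the seed and a SHA-256 hash per output so identical
configuration and seed yield byte-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import disaggregation, eco2_model, iron_supply, risk_assessment, scenarios_diversity
from .errors import ConfigurationError, DomainError
from .food_data_io import (
    CHILDREN_1_5,
    NATIONAL,
    WOMEN_15_49,
    SupplyTable,
    TableBundle,
    save_supply_table,
)
from .risk_assessment import RiskConfig, TertileMode

logger = logging.getLogger("ferroclim")

__all__ = ["RunConfig", "run_all"]

_DEFAULT_GROUPS = (CHILDREN_1_5.token, WOMEN_15_49.token)


@dataclass
class RunConfig:
    """Everything one full run needs.

    Defaults mirror the published parameters: 1000 Monte Carlo draws, 20%
    anemia threshold, 3.1/3.8% loss cutoffs, 99% diversity threshold and a
    0.05 significance level for the zero-effect rule.
    """

    input_dir: str | Path
    output_dir: str | Path
    groups: tuple[str, ...] = _DEFAULT_GROUPS
    n_draws: int = 1000
    seed: int = 0
    risk: RiskConfig = field(default_factory=RiskConfig)
    vegetarian: bool = True
    diversity_threshold: float = 0.99
    alpha: float = eco2_model.DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise DomainError(f"n_draws must be >= 1, got {self.n_draws}")
        if Path(self.input_dir).resolve() == Path(self.output_dir).resolve():
            raise ConfigurationError("input and output directories must differ")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a config from a YAML mapping; keyword overrides win."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        risk_raw = raw.pop("risk", None)
        if risk_raw is not None:
            if "tertile_mode" in risk_raw:
                risk_raw["tertile_mode"] = TertileMode(risk_raw["tertile_mode"])
            raw["risk"] = RiskConfig(**risk_raw)
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        raw.update(overrides)
        return cls(**raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _write_frame(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n")


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the output manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = TableBundle.load(config.input_dir)
    logger.info(
        "loaded bundle: %d foods, %d supply rows, %d countries",
        len(bundle.catalog),
        len(bundle.supply),
        len(bundle.supply.countries),
    )
    written: list[Path] = []

    # 1. disaggregation
    disagg = disaggregation.disaggregate(
        bundle.supply, bundle.catalog, bundle.gdd, bundle.energy, config.groups
    )
    path = out / "supply_by_group.csv"
    save_supply_table(disagg.supply, path)
    written.append(path)
    logger.info("disaggregate: %d group-level supply rows", len(disagg.supply))

    # 2. iron accounting
    iron = iron_supply.compute_iron_supply(disagg.supply, bundle.catalog)
    _write_frame(iron.by_food, out / "iron_by_food.csv")
    _write_frame(iron.totals(), out / "iron_totals.csv")
    shares = iron_supply.source_decomposition(iron, bundle.catalog)
    _write_frame(shares, out / "iron_shares.csv")
    written += [out / "iron_by_food.csv", out / "iron_totals.csv", out / "iron_shares.csv"]
    logger.info("iron: %d per-food rows", len(iron.by_food))

    # 3. Monte Carlo losses
    uncertainty = eco2_model.intake_uncertainty(disagg, bundle.catalog, bundle.gdd)
    losses = eco2_model.simulate_losses(
        iron,
        bundle.catalog,
        bundle.effects,
        gdd_uncertainty=uncertainty,
        n_draws=config.n_draws,
        seed=config.seed,
        alpha=config.alpha,
    )
    loss_summary = losses.summary()
    _write_frame(loss_summary, out / "losses.csv")
    written.append(out / "losses.csv")
    logger.info("simulate: %d draws x %d units", config.n_draws, len(losses.draws))

    # 4. risk classification
    medians = {
        (row.country, row.group): row.median_loss_pct
        for row in loss_summary.itertuples(index=False)
    }
    assessment = risk_assessment.assess(medians, bundle.anemia, config.risk)
    _write_frame(assessment.frame, out / "risk.csv")
    totals = risk_assessment.aggregate_population(assessment, bundle.population)
    _write_frame(totals, out / "category_totals.csv")
    expected = eco2_model.expected_pct_change(bundle.catalog, bundle.effects, config.alpha)
    top = risk_assessment.top_lost_sources(
        iron, expected, bundle.population, assessment
    )
    _write_frame(top, out / "top_sources.csv")
    written += [out / "risk.csv", out / "category_totals.csv", out / "top_sources.csv"]
    logger.info("risk: cutoffs %s", assessment.cutoffs)

    # 5. vegetarian scenario on national-average diets
    if config.vegetarian:
        national_iron = iron_supply.compute_iron_supply(
            _national_only(bundle.supply), bundle.catalog
        )
        base = eco2_model.simulate_losses(
            national_iron,
            bundle.catalog,
            bundle.effects,
            n_draws=config.n_draws,
            seed=config.seed,
            alpha=config.alpha,
        )
        scenario = scenarios_diversity.vegetarian_transform(bundle.supply, bundle.catalog)
        scen_iron = iron_supply.compute_iron_supply(scenario.supply, bundle.catalog)
        scen = eco2_model.simulate_losses(
            scen_iron,
            bundle.catalog,
            bundle.effects,
            n_draws=config.n_draws,
            seed=config.seed,
            alpha=config.alpha,
        )
        base_medians = {c: base.median(c, NATIONAL) for c in bundle.supply.countries}
        scen_medians = {c: scen.median(c, NATIONAL) for c in bundle.supply.countries}
        delta = scenarios_diversity.scenario_loss_delta(base_medians, scen_medians)
        frame = pd.DataFrame(
            [
                (c, base_medians[c], scen_medians[c], delta[c], scenario.factors[c])
                for c in sorted(delta)
            ],
            columns=[
                "country",
                "baseline_median_loss_pct",
                "vegetarian_median_loss_pct",
                "delta_pct_points",
                "vegetal_inflation_factor",
            ],
        )
        _write_frame(frame, out / "scenario_losses.csv")
        written.append(out / "scenario_losses.csv")
        logger.info("scenario: %d countries", len(frame))

    # 6. diversity statistic (reference group: women of childbearing age)
    div_group = config.groups[-1]
    points = scenarios_diversity.diversity_points(
        iron,
        bundle.supply,
        bundle.catalog,
        bundle.anemia,
        div_group,
        threshold=config.diversity_threshold,
    )
    div_frame = pd.DataFrame(
        [
            (p.country, p.n_iron_sources, p.anemia_pct, int(p.wild_harvest_flag))
            for p in points
        ],
        columns=["country", "n_sources", "anemia_pct", "wild_flag"],
    )
    _write_frame(div_frame, out / "diversity.csv")
    written.append(out / "diversity.csv")
    fit_lines = []
    if len(points) >= 3:
        for exclude in (False, True):
            try:
                fit = scenarios_diversity.diversity_anemia_fit(points, exclude_wild=exclude)
            except DomainError:
                continue
            fit_lines.append(
                f"exclude_wild={exclude}: n={fit.n_points} intercept={fit.intercept:.6g} "
                f"slope={fit.slope:.6g} pearson_r={fit.pearson_r:.6g}"
            )
    (out / "diversity_fit.txt").write_text("\n".join(fit_lines) + "\n", encoding="utf-8")
    written.append(out / "diversity_fit.txt")
    logger.info("diversity: %d countries", len(points))

    manifest = {
        "seed": config.seed,
        "n_draws": config.n_draws,
        "groups": list(config.groups),
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def _national_only(supply: SupplyTable) -> SupplyTable:
    records = [
        (c, f, g, v) for c, f, g, v in supply.entries() if g == NATIONAL
    ]
    return SupplyTable.from_records(records)
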