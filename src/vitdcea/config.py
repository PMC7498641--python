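"""Configuration loading, validation and model-bundle assembly.

A single YAML file carries the parameter registry (point estimates + PSA
distributions), subgroup case counts and census denominators, costing and
engine knobs.  ``default_config()`` loads the bundled defaults that
reproduce the published parameter tables; ``build_bundle`` wires a subgroup
into a ready-to-evaluate :class:`~vitdcea.decision_model.ModelBundle`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .costing import CostConfig, SupplementPrice, SupplementPrices
from .decision_model import (
    ArmSpec,
    BaselineUtilityParams,
    HealthStateParams,
    ModelBundle,
    ModelConfig,
    Subgroup,
)
from .epidemiology import IncidenceInput, annual_rate
from .parameters import DistributionSpec, ParamRegistry, ParamSpec, assumed_sd

__all__ = [
    "ConfigError",
    "AnalysisConfig",
    "SubgroupConfig",
    "load_config",
    "default_config",
    "build_bundle",
    "REQUIRED_PARAMETERS",
]

REQUIRED_PARAMETERS = (
    "rickets_utility",
    "rickets_duration",
    "rickets_or",
    "uptake_increase_child",
    "uptake_increase_woman",
    "baseline_supp_child",
    "baseline_supp_woman",
    "complication_probability",
    "complication_disutility",
    "complication_cost_annual",
    "deficiency_disutility",
    "deficiency_disutility_onset_age",
    "deficiency_prevalence_baseline",
    "mortality_rr",
    "mortality_rr_onset_age",
)


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


@dataclass(frozen=True)
class SubgroupConfig:
    label: str
    census_count: int
    cases_total: float
    window_years: float
    treatment_cost_mean: float
    treatment_cost_sd_observed: float

    @property
    def annual_risk(self) -> float:
        return annual_rate(
            IncidenceInput(
                self.label, self.cases_total, self.window_years, self.census_count
            )
        ).annual_risk


@dataclass(frozen=True)
class AnalysisConfig:
    registry: ParamRegistry
    subgroups: dict[str, SubgroupConfig]
    costcfg: CostConfig
    model_cfg: ModelConfig
    prices: SupplementPrices
    master_seed: int
    psa_n_samples: int
    lambda_grid: tuple[float, ...]
    raw: dict

    @property
    def total_children(self) -> int:
        return sum(s.census_count for s in self.subgroups.values())


def _require(raw: dict, key: str, ctx: str):
    if key not in raw:
        raise ConfigError(f"missing configuration key {ctx}.{key}")
    return raw[key]


def _check_nonneg(value: float, key: str) -> float:
    if value < 0:
        raise ConfigError(f"configuration key {key} must be >= 0, got {value}")
    return float(value)


def _build_registry(raw: dict, subgroups: dict[str, SubgroupConfig]) -> ParamRegistry:
    registry = ParamRegistry.from_dict(
        raw["parameters"], provenance=raw.get("_provenance", "config")
    )
    registry.validate_complete(REQUIRED_PARAMETERS)
    # Derived per-subgroup entries: the annual risk gets a gamma with the
    # Poisson shape implied by the case count; treatment costs get a gamma
    # under the SD = 10% of mean rule (positive support for skewed costs).
    for sub in subgroups.values():
        risk = sub.annual_risk
        if sub.cases_total > 0:
            dist = DistributionSpec(
                "gamma",
                a=float(sub.cases_total),
                b=risk / sub.cases_total,
                note="Poisson-count gamma on the annual risk",
            )
        else:
            dist = DistributionSpec("fixed", risk)
        registry.add(
            ParamSpec(
                name=f"annual_risk_{sub.label}",
                point=risk,
                dist=dist,
                source="case series / census",
            )
        )
        mean = sub.treatment_cost_mean
        sd = assumed_sd(mean)
        registry.add(
            ParamSpec(
                name=f"treatment_cost_{sub.label}",
                point=mean,
                dist=DistributionSpec("gamma", a=100.0, b=mean / 100.0),
                sd_reported=sd,
                source="case series; SD assumed 10% of mean",
            )
        )
    return registry


def _parse(raw: dict) -> AnalysisConfig:
    for section in ("parameters", "subgroups", "costing", "model"):
        _require(raw, section, "<root>")

    subgroups: dict[str, SubgroupConfig] = {}
    for label, sv in raw["subgroups"].items():
        sub = SubgroupConfig(
            label=label,
            census_count=int(_require(sv, "census_count", f"subgroups.{label}")),
            cases_total=float(_require(sv, "cases_total", f"subgroups.{label}")),
            window_years=float(_require(sv, "window_years", f"subgroups.{label}")),
            treatment_cost_mean=_check_nonneg(
                _require(sv, "treatment_cost_mean", f"subgroups.{label}"),
                f"subgroups.{label}.treatment_cost_mean",
            ),
            treatment_cost_sd_observed=float(sv.get("treatment_cost_sd_observed", 0.0)),
        )
        if sub.census_count <= 0:
            raise ConfigError(f"subgroups.{label}.census_count must be > 0")
        if sub.cases_total < 0:
            raise ConfigError(f"subgroups.{label}.cases_total must be >= 0")
        subgroups[label] = sub

    c = raw["costing"]
    for key in ("child_pack_price", "woman_pack_price"):
        _check_nonneg(_require(c, key, "costing"), f"costing.{key}")
    for key in ("child_days_per_pack", "woman_days_per_pack"):
        if _require(c, key, "costing") <= 0:
            raise ConfigError(f"costing.{key} must be > 0")
    prices = SupplementPrices(
        child=SupplementPrice(float(c["child_pack_price"]), float(c["child_days_per_pack"])),
        woman=SupplementPrice(float(c["woman_pack_price"]), float(c["woman_days_per_pack"])),
    )
    total_children = int(c.get("target_children", sum(s.census_count for s in subgroups.values())))
    try:
        costcfg = CostConfig(
            admin_budget_per_year=float(c.get("admin_budget_per_year", 10_000.0)),
            discount_rate_costs=float(c.get("discount_rate_costs", 0.035)),
            price_year=str(c.get("price_year", "2016-17")),
            target_children=total_children,
            target_pregnancies=int(c.get("target_pregnancies", 0)),
            spread_admin_over_pregnancies=bool(c.get("spread_admin_over_pregnancies", False)),
            pregnancy_supplement_days=float(c.get("pregnancy_supplement_days", 270.0)),
            coverage_policy=str(c.get("coverage_policy", "incremental-uptake")),
            timing=str(c.get("timing", "start")),
        )
    except ValueError as exc:
        raise ConfigError(f"costing: {exc}") from exc

    m = raw["model"]
    variant = str(m.get("utility_variant", "quadratic"))
    if variant == "quadratic":
        up = BaselineUtilityParams()
    elif variant == "population_norm":
        up = BaselineUtilityParams.population_norm()
    else:
        raise ConfigError(
            f"model.utility_variant must be quadratic|population_norm, got {variant!r}"
        )
    try:
        model_cfg = ModelConfig(
            discount_rate_qalys=float(m.get("discount_rate_qalys", 0.035)),
            male_share=float(m.get("male_share", 0.5)),
            half_cycle=bool(m.get("half_cycle", False)),
            max_age=int(m.get("max_age", 100)),
            utility_params=up,
        )
    except ValueError as exc:
        raise ConfigError(f"model: {exc}") from exc

    registry = _build_registry(raw, subgroups)
    psa = raw.get("psa", {})
    return AnalysisConfig(
        registry=registry,
        subgroups=subgroups,
        costcfg=costcfg,
        model_cfg=model_cfg,
        prices=prices,
        master_seed=int(raw.get("master_seed", 0)),
        psa_n_samples=int(psa.get("n_samples", 10_000)),
        lambda_grid=tuple(float(x) for x in psa.get("lambda_grid", (20_000.0, 30_000.0))),
        raw=raw,
    )


def load_config(path) -> AnalysisConfig:
    """Load and validate an analysis configuration YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration file {path} is not a mapping")
    raw["_provenance"] = str(path)
    return _parse(raw)


def default_config(master_seed: int | None = None) -> AnalysisConfig:
    """The bundled default configuration (published parameter tables)."""
    ref = resources.files("vitdcea.data").joinpath("published_defaults.yaml")
    raw = yaml.safe_load(ref.read_text())
    raw["_provenance"] = "published-defaults"
    if master_seed is not None:
        raw["master_seed"] = int(master_seed)
    return _parse(raw)


def build_bundle(
    cfg: AnalysisConfig, label: str, scenario: bool = False
) -> ModelBundle:
    """Assemble the two-arm comparison for one subgroup.

    ``scenario=True`` switches to the lifetime horizon with lifelong
    complications enabled; the base case keeps the 4-year horizon and no
    complications.
    """
    if label not in cfg.subgroups:
        raise KeyError(f"unknown subgroup {label!r}; known: {sorted(cfg.subgroups)}")
    sc = cfg.subgroups[label]
    reg = cfg.registry
    subgroup = Subgroup(
        label=label,
        annual_rickets_risk=sc.annual_risk,
        treatment_cost_mean=sc.treatment_cost_mean,
        treatment_cost_sd=assumed_sd(sc.treatment_cost_mean),
        census_count=sc.census_count,
    )
    health = HealthStateParams(
        rickets_utility=reg.point("rickets_utility"),
        rickets_duration=reg.point("rickets_duration"),
        complication_probability=reg.point("complication_probability") if scenario else 0.0,
        complication_disutility=reg.point("complication_disutility"),
        complication_cost_annual=reg.point("complication_cost_annual") if scenario else 0.0,
        deficiency_disutility=reg.point("deficiency_disutility"),
        deficiency_disutility_onset_age=reg.point("deficiency_disutility_onset_age"),
        deficiency_prevalence_baseline=reg.point("deficiency_prevalence_baseline"),
        mortality_rr=reg.point("mortality_rr"),
        mortality_rr_onset_age=reg.point("mortality_rr_onset_age"),
    )
    comparator = ArmSpec(name="comparator", or_effect=1.0, bears_intervention_cost=False)
    intervention = ArmSpec(
        name="intervention",
        or_effect=reg.point("rickets_or"),
        uptake_increase_child=reg.point("uptake_increase_child"),
        uptake_increase_woman=reg.point("uptake_increase_woman"),
        bears_intervention_cost=True,
    )
    registry_map = {
        "rickets_utility": "rickets_utility",
        "rickets_duration": "rickets_duration",
        "rickets_or": "rickets_or",
        "uptake_increase_child": "uptake_increase_child",
        "uptake_increase_woman": "uptake_increase_woman",
        "baseline_supp_child": "baseline_supp_child",
        "baseline_supp_woman": "baseline_supp_woman",
        f"annual_risk_{label}": "annual_rickets_risk",
        f"treatment_cost_{label}": "treatment_cost_mean",
    }
    if scenario:
        registry_map.update(
            {
                "complication_probability": "complication_probability",
                "complication_disutility": "complication_disutility",
                "complication_cost_annual": "complication_cost_annual",
                "deficiency_disutility": "deficiency_disutility",
                "deficiency_disutility_onset_age": "deficiency_disutility_onset_age",
                "mortality_rr": "mortality_rr",
                "mortality_rr_onset_age": "mortality_rr_onset_age",
            }
        )
    return ModelBundle(
        subgroup=subgroup,
        health=health,
        costcfg=cfg.costcfg,
        model_cfg=cfg.model_cfg,
        prices=cfg.prices,
        comparator=comparator,
        intervention=intervention,
        horizon="lifetime" if scenario else 4,
        baseline_supp_child=reg.point("baseline_supp_child"),
        baseline_supp_woman=reg.point("baseline_supp_woman"),
        registry_map=registry_map,
    )
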