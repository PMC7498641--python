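"""Two-arm, two-stage decision-tree evaluation.

Stage 1 covers the first four years of life in annual cycles.  Each year a
child who has not yet had rickets may develop it (annual risk, reduced on
the odds scale in the intervention arm); a case holds the rickets utility
for the episode duration and incurs the subgroup's treatment cost at onset.
All-cause mortality from a life table applies throughout.  In the base case
the horizon stops at four years and lifelong complications are switched off.

Stage 2 (lifetime scenario) continues in annual cycles to a maximum age:
a fixed share of rickets cases suffers lifelong complications (utility
decrement plus annual management cost); a population-baseline share is
vitamin-D deficient and, from the configured onset ages, accrues a small
disutility and an elevated mortality risk.  The deficiency channel is
deliberately identical in both arms (prevalence is assumed to return to the
population baseline regardless of the programme), so it shifts absolute
totals but not incrementals.

Expected costs and QALYs are cohort expectations per child entering the
model, discounted to present value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .costing import CostConfig, SupplementPrices, coverage_fractions, discount_factor
from .epidemiology import apply_or

__all__ = [
    "Subgroup",
    "ArmSpec",
    "HealthStateParams",
    "BaselineUtilityParams",
    "ModelConfig",
    "StrategyOutcome",
    "ModelBundle",
    "baseline_utility",
    "evaluate_arm",
    "lifetime_extension",
    "load_life_table",
    "default_life_table",
]

STAGE1_YEARS = 4


@dataclass(frozen=True)
class Subgroup:
    """A skin-tone stratum with its risk, treatment cost and census size."""

    label: str
    annual_rickets_risk: float
    treatment_cost_mean: float
    treatment_cost_sd: float = 0.0
    census_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_rickets_risk <= 1.0:
            raise ValueError(
                f"annual_rickets_risk must be in [0, 1], got {self.annual_rickets_risk}"
            )
        if self.treatment_cost_mean < 0 or self.treatment_cost_sd < 0:
            raise ValueError("treatment costs must be >= 0")


@dataclass(frozen=True)
class ArmSpec:
    """One strategy arm: comparator (current practice) or intervention."""

    name: str
    or_effect: float = 1.0
    uptake_increase_child: float = 0.0
    uptake_increase_woman: float = 0.0
    bears_intervention_cost: bool = False

    def __post_init__(self) -> None:
        if self.or_effect <= 0:
            raise ValueError(f"or_effect must be > 0, got {self.or_effect}")


@dataclass(frozen=True)
class HealthStateParams:
    """Utilities, durations and scenario (stage-2) parameters.

    ``complication_probability`` is zero in the base case; the lifetime
    scenario sets it to the share of rickets cases left with lifelong
    complications.
    """

    rickets_utility: float = 0.621
    rickets_duration: float = 2.0  # years
    complication_probability: float = 0.0
    complication_disutility: float = 0.05
    complication_cost_annual: float = 0.0
    deficiency_disutility: float = 0.002
    deficiency_disutility_onset_age: float = 67.04
    deficiency_prevalence_baseline: float = 0.23
    mortality_rr: float = 1.05
    mortality_rr_onset_age: float = 76.92

    def __post_init__(self) -> None:
        for name in ("rickets_utility", "complication_disutility", "deficiency_disutility"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "rickets_duration",
            "complication_probability",
            "deficiency_prevalence_baseline",
            "deficiency_disutility_onset_age",
            "mortality_rr_onset_age",
            "complication_cost_annual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mortality_rr <= 0:
            raise ValueError(f"mortality_rr must be > 0, got {self.mortality_rr}")


@dataclass(frozen=True)
class BaselineUtilityParams:
    """Coefficients of the age/sex population baseline-utility equation.

    The default is the quoted quadratic-in-age form
    ``u = intercept + age_sq_coef * age**2 + gender_coef * male`` (gender
    code 1 = male, 0 = female), clipped to [0, 1].  That form goes to zero
    in the early sixties; :meth:`population_norm` provides the conventional
    age + age-squared population-norm equation for users who want plausible
    old-age utilities.
    """

    intercept: float = 0.950857
    age_coef: float = 0.0
    age_sq_coef: float = -0.000259
    gender_coef: float = 0.021213

    @classmethod
    def population_norm(cls) -> "BaselineUtilityParams":
        return cls(
            intercept=0.9508566,
            age_coef=-0.0002587,
            age_sq_coef=-0.0000332,
            gender_coef=0.0212126,
        )


def baseline_utility(
    age: float, gender_code: int, params: BaselineUtilityParams | None = None
) -> float:
    """Population baseline utility at an age for one sex, clipped to [0, 1]."""
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    p = params or BaselineUtilityParams()
    u = p.intercept + p.age_coef * age + p.age_sq_coef * age * age + p.gender_coef * gender_code
    return min(max(u, 0.0), 1.0)


def load_life_table(path) -> np.ndarray:
    """Life table CSV (age, annual mortality probability) -> array indexed by age."""
    df = pd.read_csv(path, comment="#")
    ages = df.iloc[:, 0].to_numpy(dtype=int)
    q = df.iloc[:, 1].to_numpy(dtype=float)
    if not np.array_equal(ages, np.arange(len(ages))):
        raise ValueError("life table ages must be contiguous from 0")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("mortality probabilities must lie in [0, 1]")
    return q


def default_life_table() -> np.ndarray:
    """Bundled stylised life table (synthetic; see the file's name and docs)."""
    ref = resources.files("vitdcea.data").joinpath("life_table_synthetic.csv")
    with resources.as_file(ref) as path:
        return load_life_table(path)


@dataclass(frozen=True)
class ModelConfig:
    """Engine knobs: discounting, sex mix, accrual, life table, max age."""

    discount_rate_qalys: float = 0.035
    male_share: float = 0.5
    half_cycle: bool = False
    max_age: int = 100
    utility_params: BaselineUtilityParams = field(default_factory=BaselineUtilityParams)
    life_table: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate_qalys < 1.0:
            raise ValueError("discount_rate_qalys must be in [0, 1)")
        if not 0.0 <= self.male_share <= 1.0:
            raise ValueError("male_share must be in [0, 1]")
        if self.life_table is None:
            object.__setattr__(self, "life_table", default_life_table())
        if len(self.life_table) < self.max_age + 1:
            raise ValueError(
                f"life table covers {len(self.life_table)} ages; "
                f"max_age={self.max_age} requires {self.max_age + 1}"
            )

    def mixed_baseline(self, ages: np.ndarray) -> np.ndarray:
        """Sex-mixed clipped baseline utility per age (clip before mixing)."""
        p = self.utility_params
        u = p.intercept + p.age_coef * ages + p.age_sq_coef * ages * ages
        male = np.clip(u + p.gender_coef, 0.0, 1.0)
        female = np.clip(u, 0.0, 1.0)
        return self.male_share * male + (1.0 - self.male_share) * female


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected discounted cost and QALYs per child, with an audit trace."""

    expected_cost: float
    expected_qalys: float
    trace: dict


def _rickets_activity(years_since_onset: int, duration: float) -> float:
    """Fraction of model year ``k`` after onset spent in the rickets state."""
    whole = math.floor(duration)
    if years_since_onset < whole:
        return 1.0
    if years_since_onset == whole:
        return duration - whole
    return 0.0


def evaluate_arm(
    arm: ArmSpec,
    subgroup: Subgroup,
    health: HealthStateParams,
    costcfg: CostConfig,
    horizon: int | str = STAGE1_YEARS,
    model_cfg: ModelConfig | None = None,
    prices: SupplementPrices | None = None,
    baseline_supp_child: float = 0.0,
    baseline_supp_woman: float = 0.0,
) -> StrategyOutcome:
    """Expected discounted cost and QALYs per child for one arm.

    ``horizon`` is 4 (base case) or ``"lifetime"`` (appends stage 2 up to
    ``model_cfg.max_age``).  The trace records per-cycle survival, onset
    probabilities and utilities for audit; stage-1 path probabilities
    (ever-onset split by year + never-onset) sum to one.
    """
    if horizon not in (STAGE1_YEARS, "lifetime"):
        raise ValueError(f"horizon must be {STAGE1_YEARS} or 'lifetime', got {horizon!r}")
    cfg = model_cfg or ModelConfig()
    if arm.bears_intervention_cost and prices is None:
        raise ValueError(f"arm {arm.name!r} bears intervention costs but no prices given")

    q = cfg.life_table
    rq = cfg.discount_rate_qalys
    rc = costcfg.discount_rate_costs
    p_onset = apply_or(subgroup.annual_rickets_risk, arm.or_effect)
    d = health.rickets_duration
    u_rickets = health.rickets_utility
    ubase = cfg.mixed_baseline(np.arange(STAGE1_YEARS, dtype=float))

    if arm.bears_intervention_cost:
        cov_child, cov_woman = coverage_fractions(
            costcfg.coverage_policy,
            arm.uptake_increase_child,
            arm.uptake_increase_woman,
            baseline_supp_child,
            baseline_supp_woman,
        )
        child_annual = prices.child.annual_cost * cov_child
        pregnancy_cost = prices.woman.cost_for(costcfg.pregnancy_supplement_days) * cov_woman
        admin_annual = costcfg.admin_budget_per_year / costcfg.admin_denominator
    else:
        child_annual = pregnancy_cost = admin_annual = 0.0

    survival = 1.0  # P(alive at start of current year)
    never = 1.0  # P(no rickets onset so far), mortality-independent
    onsets: list[float] = []  # P(onset in year t) among the initial cohort
    qalys = 0.0
    costs = 0.0
    rows = []

    for t in range(STAGE1_YEARS):
        onset_t = never * p_onset
        never -= onset_t
        onsets.append(onset_t)
        active = sum(
            onsets[s] * _rickets_activity(t - s, d) for s in range(t + 1)
        )
        # truncate the episode at the horizon only in the 4-year base case
        u_mean = (1.0 - active) * ubase[t] + active * u_rickets
        if cfg.half_cycle:
            accrual = survival * (1.0 - q[t] / 2.0)
            qalys += accrual * u_mean * (1.0 + rq) ** -(t + 0.5)
        else:
            accrual = survival
            qalys += accrual * u_mean * discount_factor(t, rq, "start")
        dfc = discount_factor(t, rc, costcfg.timing)
        costs += onset_t * survival * subgroup.treatment_cost_mean * dfc
        if arm.bears_intervention_cost:
            costs += (child_annual * survival + admin_annual) * dfc
            if t == 0:
                costs += pregnancy_cost * dfc
        rows.append(
            {
                "age": t,
                "survival_start": survival,
                "p_onset": onset_t,
                "active_rickets": active,
                "mean_utility": u_mean,
            }
        )
        survival *= 1.0 - q[t]

    trace = {
        "arm": arm.name,
        "subgroup": subgroup.label,
        "stage1": pd.DataFrame(rows),
        "onsets": onsets,
        "ever_rickets": sum(onsets),
        "never_rickets": never,
        "path_probability_total": sum(onsets) + never,
        "survival_age4": survival,
        "rickets_duration": d,
        "horizon": horizon,
    }
    stage1 = StrategyOutcome(expected_cost=costs, expected_qalys=qalys, trace=trace)
    if horizon == STAGE1_YEARS:
        return stage1
    return lifetime_extension(stage1, health, costcfg, cfg)


def lifetime_extension(
    stage1: StrategyOutcome,
    health: HealthStateParams,
    costcfg: CostConfig,
    model_cfg: ModelConfig | None = None,
) -> StrategyOutcome:
    """Append annual stage-2 cycles (age 4 to ``max_age``) to a stage-1 result.

    Lifelong-complication sufferers (``complication_probability`` among
    rickets cases) accrue the complication disutility and annual management
    cost for life.  The deficiency share accrues its disutility from the
    deficiency onset age and the mortality relative risk from the mortality
    onset age; both apply equally in either arm.  Late rickets episodes
    spilling past age four keep the rickets utility until the episode ends.
    """
    cfg = model_cfg or ModelConfig()
    q = cfg.life_table
    rq = cfg.discount_rate_qalys
    rc = costcfg.discount_rate_costs
    tr = stage1.trace

    onsets = tr["onsets"]
    d = tr["rickets_duration"]
    comp = tr["ever_rickets"] * health.complication_probability
    defic = health.deficiency_prevalence_baseline
    survival = tr["survival_age4"]
    ages = np.arange(STAGE1_YEARS, cfg.max_age + 1, dtype=float)
    ubase = cfg.mixed_baseline(ages)

    qalys = stage1.expected_qalys
    costs = stage1.expected_cost
    rows = []
    for i, age_f in enumerate(ages):
        age = int(age_f)
        active = sum(
            o * _rickets_activity(age - s, d) for s, o in enumerate(onsets)
        )
        u = (1.0 - active) * ubase[i] + active * health.rickets_utility
        u -= comp * health.complication_disutility
        if age >= health.deficiency_disutility_onset_age:
            u -= defic * health.deficiency_disutility
        u = max(u, 0.0)
        q_age = q[age] if age < len(q) else 1.0
        if age >= health.mortality_rr_onset_age:
            q_age = min(q_age * (1.0 + defic * (health.mortality_rr - 1.0)), 1.0)
        if cfg.half_cycle:
            accrual = survival * (1.0 - q_age / 2.0)
            qalys += accrual * u * (1.0 + rq) ** -(age + 0.5)
        else:
            qalys += survival * u * discount_factor(age, rq, "start")
        costs += (
            comp
            * health.complication_cost_annual
            * survival
            * discount_factor(age, rc, costcfg.timing)
        )
        rows.append(
            {"age": age, "survival_start": survival, "mean_utility": u, "q": q_age}
        )
        survival *= 1.0 - q_age

    trace = dict(tr)
    trace["stage2"] = pd.DataFrame(rows)
    trace["horizon"] = "lifetime"
    trace["complication_share"] = comp
    return StrategyOutcome(expected_cost=costs, expected_qalys=qalys, trace=trace)


# ---------------------------------------------------------------------------
# Bundle: everything needed to evaluate both arms, with named overrides
# ---------------------------------------------------------------------------

# override name -> (bundle attribute, field name on that attribute)
_OVERRIDE_TARGETS: dict[str, tuple[str, str]] = {
    "rickets_utility": ("health", "rickets_utility"),
    "rickets_duration": ("health", "rickets_duration"),
    "complication_probability": ("health", "complication_probability"),
    "complication_disutility": ("health", "complication_disutility"),
    "complication_cost_annual": ("health", "complication_cost_annual"),
    "deficiency_disutility": ("health", "deficiency_disutility"),
    "deficiency_disutility_onset_age": ("health", "deficiency_disutility_onset_age"),
    "deficiency_prevalence_baseline": ("health", "deficiency_prevalence_baseline"),
    "mortality_rr": ("health", "mortality_rr"),
    "mortality_rr_onset_age": ("health", "mortality_rr_onset_age"),
    "annual_rickets_risk": ("subgroup", "annual_rickets_risk"),
    "treatment_cost_mean": ("subgroup", "treatment_cost_mean"),
    "rickets_or": ("intervention", "or_effect"),
    "uptake_increase_child": ("intervention", "uptake_increase_child"),
    "uptake_increase_woman": ("intervention", "uptake_increase_woman"),
    "admin_budget_per_year": ("costcfg", "admin_budget_per_year"),
    "discount_rate_costs": ("costcfg", "discount_rate_costs"),
    "pregnancy_supplement_days": ("costcfg", "pregnancy_supplement_days"),
    "discount_rate_qalys": ("model_cfg", "discount_rate_qalys"),
    "male_share": ("model_cfg", "male_share"),
    "child_pack_price": ("prices.child", "pack_price"),
    "woman_pack_price": ("prices.woman", "pack_price"),
    "baseline_supp_child": ("self", "baseline_supp_child"),
    "baseline_supp_woman": ("self", "baseline_supp_woman"),
}


@dataclass(frozen=True)
class ModelBundle:
    """A fully-specified comparison: subgroup, both arms, all parameters.

    ``registry_map`` links parameter-registry names to the bundle's override
    names so that PSA, tornado sweeps and threshold searches can drive the
    model directly from a :class:`~vitdcea.parameters.ParamRegistry`.
    """

    subgroup: Subgroup
    health: HealthStateParams
    costcfg: CostConfig
    model_cfg: ModelConfig
    prices: SupplementPrices
    comparator: ArmSpec
    intervention: ArmSpec
    horizon: int | str = STAGE1_YEARS
    baseline_supp_child: float = 0.0
    baseline_supp_woman: float = 0.0
    registry_map: Mapping[str, str] = field(default_factory=dict)

    def with_overrides(self, overrides: Mapping[str, float] | None) -> "ModelBundle":
        if not overrides:
            return self
        groups: dict[str, dict[str, float]] = {}
        for name, value in overrides.items():
            try:
                target, fieldname = _OVERRIDE_TARGETS[name]
            except KeyError:
                raise KeyError(
                    f"unknown model parameter {name!r}; known: "
                    f"{sorted(_OVERRIDE_TARGETS)}"
                ) from None
            groups.setdefault(target, {})[fieldname] = float(value)
        b = self
        if "self" in groups:
            b = replace(b, **groups.pop("self"))
        if "prices.child" in groups:
            b = replace(b, prices=replace(b.prices, child=replace(b.prices.child, **groups.pop("prices.child"))))
        if "prices.woman" in groups:
            b = replace(b, prices=replace(b.prices, woman=replace(b.prices.woman, **groups.pop("prices.woman"))))
        for target, kw in groups.items():
            b = replace(b, **{target: replace(getattr(b, target), **kw)})
        return b

    def evaluate(
        self, overrides: Mapping[str, float] | None = None
    ) -> tuple[StrategyOutcome, StrategyOutcome]:
        """(comparator, intervention) outcomes, optionally with overrides."""
        b = self.with_overrides(overrides)
        out = []
        for arm in (b.comparator, b.intervention):
            out.append(
                evaluate_arm(
                    arm,
                    b.subgroup,
                    b.health,
                    b.costcfg,
                    b.horizon,
                    b.model_cfg,
                    b.prices,
                    b.baseline_supp_child,
                    b.baseline_supp_woman,
                )
            )
        return out[0], out[1]

    def cea(self, overrides: Mapping[str, float] | None = None):
        """Incremental comparison (intervention vs comparator)."""
        from .cea import compare

        comp, interv = self.evaluate(overrides)
        return compare(comp, interv)
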