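"""Per-child cost calculations: rickets treatment, supplements, administration.

All amounts are pounds sterling at the configured price year; rounding
happens only in the report layer, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TariffItem",
    "SupplementPrice",
    "SupplementPrices",
    "CostConfig",
    "supplement_cost",
    "rickets_treatment_cost",
    "intervention_cost_per_child",
    "discount",
    "discount_factor",
    "coverage_fractions",
    "read_tariff_csv",
    "read_line_items_csv",
]

COVERAGE_POLICIES = ("incremental-uptake", "all-supplemented", "universal")
TIMINGS = ("start", "mid", "end")


@dataclass(frozen=True)
class TariffItem:
    """One priced line item of a treatment episode (tariff unit price x quantity)."""

    code: str
    description: str
    unit_price: float
    quantity: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_price < 0:
            raise ValueError(f"unit_price must be >= 0, got {self.unit_price}")
        if self.quantity < 0:
            raise ValueError(f"quantity must be >= 0, got {self.quantity}")

    @property
    def total(self) -> float:
        return self.unit_price * self.quantity


@dataclass(frozen=True)
class SupplementPrice:
    """Pack price and how many days one pack covers."""

    pack_price: float
    days_per_pack: float

    def __post_init__(self) -> None:
        if self.pack_price < 0:
            raise ValueError(f"pack_price must be >= 0, got {self.pack_price}")
        if self.days_per_pack <= 0:
            raise ValueError(f"days_per_pack must be > 0, got {self.days_per_pack}")

    def cost_for(self, duration_days: float) -> float:
        return supplement_cost(self.pack_price, self.days_per_pack, duration_days)

    @property
    def annual_cost(self) -> float:
        return self.cost_for(365.0)


@dataclass(frozen=True)
class SupplementPrices:
    child: SupplementPrice
    woman: SupplementPrice


@dataclass(frozen=True)
class CostConfig:
    """Costing policy knobs.

    ``admin_budget_per_year`` covers promotion, distribution and overheads
    for the whole region and is spread over ``target_children`` (optionally
    plus ``target_pregnancies``).  ``coverage_policy`` selects whose
    supplements the payer is costed for: only the uptake increase
    (``incremental-uptake``, default), everyone supplemented
    (``all-supplemented``), or the whole cohort (``universal``).
    """

    admin_budget_per_year: float = 10_000.0
    discount_rate_costs: float = 0.035
    price_year: str = "2016-17"
    target_children: int = 36_413
    target_pregnancies: int = 0
    spread_admin_over_pregnancies: bool = False
    pregnancy_supplement_days: float = 270.0
    coverage_policy: str = "incremental-uptake"
    timing: str = "start"

    def __post_init__(self) -> None:
        if self.admin_budget_per_year < 0:
            raise ValueError(
                f"admin_budget_per_year must be >= 0, got {self.admin_budget_per_year}"
            )
        if not 0.0 <= self.discount_rate_costs < 1.0:
            raise ValueError(
                f"discount_rate_costs must be in [0, 1), got {self.discount_rate_costs}"
            )
        if self.coverage_policy not in COVERAGE_POLICIES:
            raise ValueError(
                f"coverage_policy must be one of {COVERAGE_POLICIES}, "
                f"got {self.coverage_policy!r}"
            )
        if self.timing not in TIMINGS:
            raise ValueError(f"timing must be one of {TIMINGS}, got {self.timing!r}")

    @property
    def admin_denominator(self) -> float:
        denom = self.target_children
        if self.spread_admin_over_pregnancies:
            denom += self.target_pregnancies
        if denom <= 0:
            raise ValueError("admin budget denominator (target population) is zero")
        return float(denom)


def supplement_cost(pack_price: float, days_per_pack: float, duration_days: float) -> float:
    """Pro-rata supplement cost: ``pack_price * duration / days_per_pack``, unrounded."""
    if pack_price < 0 or duration_days < 0:
        raise ValueError("pack_price and duration_days must be >= 0")
    if days_per_pack <= 0:
        raise ValueError(f"days_per_pack must be > 0, got {days_per_pack}")
    return pack_price * duration_days / days_per_pack


def rickets_treatment_cost(items: Iterable[TariffItem]) -> float:
    """Sum of unit_price x quantity over an episode's tariff line items."""
    return sum(it.total for it in items)


def discount_factor(t: float, rate: float, timing: str = "start") -> float:
    """Present-value factor for period ``t`` (0-based) under a timing convention."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    offset = {"start": 0.0, "mid": 0.5, "end": 1.0}[timing]
    return (1.0 + rate) ** -(t + offset)


def discount(stream: Sequence[float], rate: float, timing: str = "start") -> float:
    """Present value of per-period amounts: ``sum x_t / (1+rate)**(t+offset)``."""
    return sum(x * discount_factor(t, rate, timing) for t, x in enumerate(stream))


def coverage_fractions(
    policy: str,
    uptake_increase_child: float,
    uptake_increase_woman: float,
    baseline_child: float = 0.0,
    baseline_woman: float = 0.0,
) -> tuple[float, float]:
    """Fraction of (children, pregnancies) whose supplements the payer funds."""
    for name, v in (
        ("uptake_increase_child", uptake_increase_child),
        ("uptake_increase_woman", uptake_increase_woman),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if policy == "incremental-uptake":
        return uptake_increase_child, uptake_increase_woman
    if policy == "all-supplemented":
        return (
            min(baseline_child + uptake_increase_child, 1.0),
            min(baseline_woman + uptake_increase_woman, 1.0),
        )
    if policy == "universal":
        return 1.0, 1.0
    raise ValueError(f"unknown coverage policy {policy!r}")


def intervention_cost_per_child(
    prices: SupplementPrices,
    uptake_increase_child: float,
    uptake_increase_woman: float,
    config: CostConfig,
    horizon_years: int = 4,
    baseline_child: float = 0.0,
    baseline_woman: float = 0.0,
) -> float:
    """Expected discounted intervention cost per child in the cohort.

    Components: the child's annual supplement cost over the programme years
    and the pregnancy supplement cost at entry, each weighted by the
    payer-coverage fraction; plus the per-child share of the yearly
    administration budget.
    """
    cov_child, cov_woman = coverage_fractions(
        config.coverage_policy,
        uptake_increase_child,
        uptake_increase_woman,
        baseline_child,
        baseline_woman,
    )
    r = config.discount_rate_costs
    child_annual = prices.child.annual_cost * cov_child
    admin_annual = config.admin_budget_per_year / config.admin_denominator
    total = sum(
        (child_annual + admin_annual) * discount_factor(t, r, config.timing)
        for t in range(horizon_years)
    )
    total += (
        prices.woman.cost_for(config.pregnancy_supplement_days)
        * cov_woman
        * discount_factor(0, r, config.timing)
    )
    return total


def read_tariff_csv(path) -> dict[str, TariffItem]:
    """Read a tariff price list (code, description, unit_price) keyed by code."""
    df = pd.read_csv(path)
    out = {}
    for r in df.itertuples():
        out[str(r.code)] = TariffItem(
            code=str(r.code),
            description=str(r.description),
            unit_price=float(r.unit_price),
            quantity=1.0,
        )
    return out


def read_line_items_csv(path, tariff: dict[str, TariffItem]) -> dict[str, list[TariffItem]]:
    """Read case line items (case_id, code, quantity), priced against a tariff."""
    df = pd.read_csv(path)
    cases: dict[str, list[TariffItem]] = {}
    for r in df.itertuples():
        code = str(r.code)
        if code not in tariff:
            raise KeyError(f"line item references unknown tariff code {code!r}")
        base = tariff[code]
        cases.setdefault(str(r.case_id), []).append(
            TariffItem(base.code, base.description, base.unit_price, float(r.quantity))
        )
    return cases
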