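"""Rickets incidence estimation and intervention-effect arithmetic.

Annual risks are estimated from case counts over an observation window and
census denominators of children under 4 years; the intervention's effect is
an odds ratio applied on the odds scale to the annual risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "IncidenceInput",
    "RiskEstimate",
    "annual_rate",
    "onset_proportion_ci",
    "apply_or",
    "pool",
    "read_incidence_csv",
]

SUBGROUPS = ("light", "medium", "dark", "general", "medium+dark")


@dataclass(frozen=True)
class IncidenceInput:
    """Case count over an observation window plus the census denominator."""

    subgroup: str
    cases_total: float
    window_years: float
    population_at_risk: float

    def __post_init__(self) -> None:
        if self.cases_total < 0:
            raise ValueError(f"cases_total must be >= 0, got {self.cases_total}")
        if self.window_years <= 0:
            raise ValueError(f"window_years must be > 0, got {self.window_years}")
        if self.population_at_risk <= 0:
            raise ValueError(
                f"population_at_risk must be > 0, got {self.population_at_risk}"
            )


@dataclass(frozen=True)
class RiskEstimate:
    annual_risk: float  # probability per child-year
    per_100k: float  # annual_risk * 1e5
    cumulative_4yr: float  # probability over the 4-year horizon


def annual_rate(inp: IncidenceInput, horizon_years: int = 4, compound: bool = True) -> RiskEstimate:
    """Annual risk = (cases per year) / population at risk.

    The multi-year risk uses independent-year compounding
    ``1 - (1 - p)**horizon`` by default; ``compound=False`` gives the linear
    approximation ``horizon * p`` (an upper bound, by Bernoulli).
    """
    p = (inp.cases_total / inp.window_years) / inp.population_at_risk
    if compound:
        cum = 1.0 - (1.0 - p) ** horizon_years
    else:
        cum = min(horizon_years * p, 1.0)
    return RiskEstimate(annual_risk=p, per_100k=p * 1e5, cumulative_4yr=cum)


def onset_proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion (default Wilson score).

    Used for e.g. the share of cases with onset before 48 months.  Wilson is
    the default because it is well-behaved near the boundary; the
    Clopper-Pearson exact interval is available via ``method="beta"``.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=method)
    return float(lo), float(hi)


def apply_or(baseline_risk: float, or_effect: float) -> float:
    """Apply an odds ratio to a probability: ``p' = OR*p / (1 - p + OR*p)``.

    The identity at OR = 1; for rare outcomes OR approximates a risk ratio.
    """
    if not 0.0 <= baseline_risk <= 1.0:
        raise ValueError(f"baseline_risk must be in [0, 1], got {baseline_risk}")
    if or_effect <= 0:
        raise ValueError(f"or_effect must be > 0, got {or_effect}")
    if baseline_risk == 1.0:
        if or_effect != 1.0:
            raise ValueError("baseline_risk = 1 has infinite odds; OR undefined")
        return 1.0
    num = or_effect * baseline_risk
    return num / (1.0 - baseline_risk + num)


def pool(inputs: Sequence[IncidenceInput], label: str = "pooled") -> IncidenceInput:
    """Aggregate subgroups by summing numerators and denominators.

    All inputs must share the same observation window.
    """
    if not inputs:
        raise ValueError("nothing to pool")
    windows = {i.window_years for i in inputs}
    if len(windows) != 1:
        raise ValueError(f"cannot pool across different windows: {sorted(windows)}")
    return IncidenceInput(
        subgroup=label,
        cases_total=sum(i.cases_total for i in inputs),
        window_years=inputs[0].window_years,
        population_at_risk=sum(i.population_at_risk for i in inputs),
    )


def read_incidence_csv(path) -> list[IncidenceInput]:
    """Read (subgroup, cases_total, window_years, population_at_risk) rows."""
    df = pd.read_csv(path)
    required = {"subgroup", "cases_total", "window_years", "population_at_risk"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"incidence CSV missing columns: {sorted(missing)}")
    return [
        IncidenceInput(
            subgroup=str(r.subgroup),
            cases_total=float(r.cases_total),
            window_years=float(r.window_years),
            population_at_risk=float(r.population_at_risk),
        )
        for r in df.itertuples()
    ]
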