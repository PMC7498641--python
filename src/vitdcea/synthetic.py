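"""Synthetic observational dataset and census generator.

Emulates the statistical structure of a single-region rickets case series
with census denominators: per-subgroup case counts are Poisson with mean
``rate x population x window`` (binomial per child-year available by flag),
onset ages follow a right-skewed gamma calibrated to a target mean and a
target share of onsets before 48 months, and per-case treatment costs are
gamma with the subgroup's configured mean/SD, decomposed into tariff line
items.  Everything is seeded and reproducible, and the writers emit exactly
the CSV schemas the epidemiology and costing readers consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .costing import TariffItem
from .epidemiology import IncidenceInput, annual_rate
from .parameters import fit_from_moments, substream

__all__ = [
    "SyntheticConfig",
    "CaseRecord",
    "RoundtripReport",
    "generate_dataset",
    "roundtrip_check",
    "calibrate_onset_gamma",
    "write_dataset",
    "TARIFF_FIXTURE",
]

# Six stylised tariff codes used purely to decompose case totals into line
# items for I/O testing; prices are invented round figures, not a tariff
# database extract.
TARIFF_FIXTURE = (
    TariffItem("OPFU", "Paediatric outpatient follow-up", 163.0),
    TariffItem("XRAY", "Plain radiograph, wrist/knee", 31.0),
    TariffItem("BIOC", "Biochemistry panel (25OHD, ALP, PTH)", 24.0),
    TariffItem("EDAT", "Emergency department attendance", 148.0),
    TariffItem("IPAD", "Inpatient admission, paediatric metabolic", 662.0),
    TariffItem("PHRX", "Pharmacy, cholecalciferol treatment course", 18.0),
)


def _default_populations() -> dict[str, int]:
    return {"light": 17_344, "medium": 14_117, "dark": 4_952}


def _default_rates() -> dict[str, float]:
    return {"light": 1.92, "medium": 34.23, "dark": 84.14}


def _default_cost_means() -> dict[str, float]:
    return {"light": 1_750.0, "medium": 2_385.0, "dark": 7_305.0}


def _default_cost_sds() -> dict[str, float]:
    return {"light": 48.0, "medium": 3_759.0, "dark": 16_208.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the observed case series."""

    seed: int = 0
    window_years: float = 6.0
    subgroup_populations: dict[str, int] = field(default_factory=_default_populations)
    subgroup_annual_per_100k: dict[str, float] = field(default_factory=_default_rates)
    onset_before_48mo_prob: float = 0.95
    onset_mean_months: float = 21.16
    cost_means: dict[str, float] = field(default_factory=_default_cost_means)
    cost_sds: dict[str, float] = field(default_factory=_default_cost_sds)
    sex_male_prob: float = 0.6316
    counts_law: str = "poisson"  # or "binomial"

    def __post_init__(self) -> None:
        for name in ("onset_before_48mo_prob", "sex_male_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.window_years <= 0:
            raise ValueError("window_years must be > 0")
        if self.counts_law not in ("poisson", "binomial"):
            raise ValueError(f"counts_law must be poisson|binomial, got {self.counts_law}")
        if any(p <= 0 for p in self.subgroup_populations.values()):
            raise ValueError("populations must be positive")


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    skin_tone: str
    sex: str
    onset_age_months: float
    treatment_cost_total: float
    line_items: tuple[TariffItem, ...]


def calibrate_onset_gamma(
    mean_months: float = 21.16, p_before_48: float = 0.95
) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and P(onset < 48 mo).

    Two targets determine the two gamma parameters; the quoted onset-age SD
    is reported by the generator but not jointly enforced (it would
    over-determine the fit).
    """
    if not 0.0 < p_before_48 < 1.0:
        # degenerate targets handled by the caller (truncate / point mass)
        raise ValueError("p_before_48 must be strictly in (0, 1) to calibrate")

    def gap(shape: float) -> float:
        return stats.gamma(shape, scale=mean_months / shape).cdf(48.0) - p_before_48

    shape = brentq(gap, 0.05, 200.0, rtol=1e-10)
    return shape, mean_months / shape


def _decompose_line_items(
    total: float, rng: np.random.Generator
) -> tuple[TariffItem, ...]:
    """Split a case total across the tariff fixture with Dirichlet weights."""
    weights = rng.dirichlet(np.ones(len(TARIFF_FIXTURE)))
    items = []
    for w, base in zip(weights, TARIFF_FIXTURE):
        items.append(
            TariffItem(base.code, base.description, base.unit_price, w * total / base.unit_price)
        )
    return tuple(items)


def generate_dataset(cfg: SyntheticConfig) -> tuple[list[CaseRecord], pd.DataFrame]:
    """Generate case records plus the census denominator table.

    Returns ``(cases, census)`` where ``census`` has one row per subgroup
    with columns (subgroup, cases_total, window_years, population_at_risk).
    """
    onset_fixed = cfg.onset_before_48mo_prob in (0.0, 1.0)
    if not onset_fixed:
        shape, scale = calibrate_onset_gamma(
            cfg.onset_mean_months, cfg.onset_before_48mo_prob
        )
    cases: list[CaseRecord] = []
    census_rows = []
    for subgroup in sorted(cfg.subgroup_populations):
        pop = cfg.subgroup_populations[subgroup]
        rate = cfg.subgroup_annual_per_100k.get(subgroup, 0.0) / 1e5
        rng = substream(cfg.seed, f"synthetic/{subgroup}")
        lam = rate * pop * cfg.window_years
        if cfg.counts_law == "poisson":
            k = int(rng.poisson(lam)) if lam > 0 else 0
        else:
            n_trials = int(round(pop * cfg.window_years))
            k = int(rng.binomial(n_trials, rate)) if rate > 0 else 0

        mean_c = cfg.cost_means.get(subgroup, 0.0)
        sd_c = cfg.cost_sds.get(subgroup, 0.0)
        if mean_c > 0:
            cost_dist = fit_from_moments(mean_c, max(sd_c, 1e-9 * mean_c), "gamma")
        for i in range(k):
            if onset_fixed:
                onset = (
                    rng.uniform(0.0, 48.0)
                    if cfg.onset_before_48mo_prob == 1.0
                    else rng.uniform(48.0, 200.0)
                )
            else:
                onset = float(rng.gamma(shape, scale))
            sex = "male" if rng.random() < cfg.sex_male_prob else "female"
            total = float(rng.gamma(cost_dist.a, cost_dist.b)) if mean_c > 0 else 0.0
            items = _decompose_line_items(total, rng)
            total = sum(it.total for it in items)  # exact line-item sum
            cases.append(
                CaseRecord(
                    case_id=f"{subgroup[:1].upper()}{i + 1:03d}",
                    skin_tone=subgroup,
                    sex=sex,
                    onset_age_months=onset,
                    treatment_cost_total=total,
                    line_items=items,
                )
            )
        census_rows.append(
            {
                "subgroup": subgroup,
                "cases_total": k,
                "window_years": cfg.window_years,
                "population_at_risk": pop,
            }
        )
    census = pd.DataFrame(census_rows)
    return cases, census


def write_dataset(cases: list[CaseRecord], census: pd.DataFrame, outdir) -> dict[str, Path]:
    """Write cases.csv, line_items.csv, tariff.csv and census.csv to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cases": outdir / "cases.csv",
        "line_items": outdir / "line_items.csv",
        "tariff": outdir / "tariff.csv",
        "census": outdir / "census.csv",
    }
    pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "skin_tone": c.skin_tone,
                "sex": c.sex,
                "onset_age_months": round(c.onset_age_months, 3),
                "treatment_cost_total": round(c.treatment_cost_total, 2),
            }
            for c in cases
        ]
    ).to_csv(paths["cases"], index=False)
    pd.DataFrame(
        [
            {"case_id": c.case_id, "code": it.code, "quantity": it.quantity}
            for c in cases
            for it in c.line_items
        ]
    ).to_csv(paths["line_items"], index=False)
    pd.DataFrame(
        [
            {"code": t.code, "description": t.description, "unit_price": t.unit_price}
            for t in TARIFF_FIXTURE
        ]
    ).to_csv(paths["tariff"], index=False)
    census.to_csv(paths["census"], index=False)
    return paths


@dataclass(frozen=True)
class RoundtripReport:
    """Generator -> estimator recovery check for one seed."""

    seed: int
    rate_rows: pd.DataFrame  # per subgroup: expected count, observed, CI, recovered
    cost_rows: pd.DataFrame  # per subgroup: configured mean, sample mean, recovered

    @property
    def rates_recovered(self) -> bool:
        return bool(self.rate_rows["recovered"].all())

    @property
    def costs_recovered(self) -> bool:
        return bool(self.cost_rows["recovered"].all())


def _poisson_ci(k: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson mean given count k."""
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2.0, 2 * k) / 2.0
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * k + 2) / 2.0
    return lo, hi


def roundtrip_check(cfg: SyntheticConfig, level: float = 0.95) -> RoundtripReport:
    """Generate a dataset, re-estimate rates and costs, and report recovery.

    A subgroup's rate is 'recovered' when the configured expected count lies
    inside the exact Poisson interval implied by the observed count; its
    cost mean is recovered when the configured mean lies within two standard
    errors (configured SD / sqrt(n)) of the sample mean, vacuously true for
    empty subgroups.
    """
    cases, census = generate_dataset(cfg)
    rate_rows = []
    for r in census.itertuples():
        est = annual_rate(
            IncidenceInput(r.subgroup, r.cases_total, r.window_years, r.population_at_risk)
        )
        expected = (
            cfg.subgroup_annual_per_100k.get(r.subgroup, 0.0)
            / 1e5
            * r.population_at_risk
            * r.window_years
        )
        lo, hi = _poisson_ci(int(r.cases_total), level)
        rate_rows.append(
            {
                "subgroup": r.subgroup,
                "expected_count": expected,
                "observed_count": r.cases_total,
                "ci_low": lo,
                "ci_high": hi,
                "estimated_per_100k": est.per_100k,
                "recovered": lo <= expected <= hi,
            }
        )
    cost_rows = []
    for subgroup in sorted(cfg.subgroup_populations):
        totals = [c.treatment_cost_total for c in cases if c.skin_tone == subgroup]
        mean_cfg = cfg.cost_means.get(subgroup, 0.0)
        sd_cfg = cfg.cost_sds.get(subgroup, 0.0)
        n = len(totals)
        if n == 0:
            cost_rows.append(
                {
                    "subgroup": subgroup,
                    "n": 0,
                    "configured_mean": mean_cfg,
                    "sample_mean": math.nan,
                    "recovered": True,
                }
            )
            continue
        sample_mean = float(np.mean(totals))
        se = sd_cfg / math.sqrt(n)
        cost_rows.append(
            {
                "subgroup": subgroup,
                "n": n,
                "configured_mean": mean_cfg,
                "sample_mean": sample_mean,
                "recovered": abs(sample_mean - mean_cfg) <= 2.0 * se,
            }
        )
    return RoundtripReport(cfg.seed, pd.DataFrame(rate_rows), pd.DataFrame(cost_rows))
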