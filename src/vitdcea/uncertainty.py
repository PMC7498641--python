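"""Probabilistic, univariate and threshold sensitivity analyses.

All three operate on a model bundle (anything exposing ``cea(overrides)``
and a ``registry_map`` from registry parameter names to model override
names) plus a :class:`~vitdcea.parameters.ParamRegistry`.  Parameters are
sampled independently; a rank-correlation hook is accepted but only the
identity (independence) is currently implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .cea import CEAResult, CEACPoint, ceac, nmb, DEFAULT_LAMBDA_GRID
from .parameters import ParamRegistry

__all__ = [
    "PSAConfig",
    "PSAResult",
    "SweepResult",
    "ThresholdResult",
    "run_psa",
    "univariate_sweep",
    "threshold_search",
    "BELOW_RANGE",
    "ABOVE_RANGE",
]

BELOW_RANGE = "below_range"
ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class PSAConfig:
    n_samples: int = 10_000
    master_seed: int = 0
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")


@dataclass(frozen=True)
class PSAResult:
    """Paired incremental samples plus summaries.

    ``icer_of_means`` is the ratio of mean increments (the stable summary
    for a ratio statistic); per-sample NMB quantiles are available through
    :meth:`nmb_interval` instead of a per-sample ICER mean, which is
    unstable when dQALYs crosses zero.
    """

    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    ceac: list[CEACPoint]
    master_seed: int
    mean_delta_cost: float = field(init=False)
    mean_delta_qalys: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_delta_cost", float(np.mean(self.delta_cost)))
        object.__setattr__(self, "mean_delta_qalys", float(np.mean(self.delta_qalys)))

    @property
    def n(self) -> int:
        return int(self.delta_cost.size)

    @property
    def icer_of_means(self) -> float | None:
        if self.mean_delta_qalys == 0.0:
            return None
        return self.mean_delta_cost / self.mean_delta_qalys

    def mean_result(self) -> CEAResult:
        return CEAResult.from_increments(self.mean_delta_cost, self.mean_delta_qalys)

    def nmb_interval(self, lam: float, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed interval of the per-sample NMB distribution at lam."""
        nmb_samples = lam * self.delta_qalys - self.delta_cost
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(nmb_samples, [alpha, 1.0 - alpha])
        return float(lo), float(hi)


def run_psa(
    bundle,
    registry: ParamRegistry,
    cfg: PSAConfig,
    rank_correlation: np.ndarray | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Each registry parameter named in ``bundle.registry_map`` is drawn
    ``n_samples`` times from its own seeded sub-stream (so the draws for one
    parameter do not depend on which other parameters exist), the model is
    evaluated per joint draw, and the paired incrementals are summarised.
    """
    if rank_correlation is not None:
        raise NotImplementedError(
            "correlated sampling is a hook only; parameters are sampled independently"
        )
    reg_map: Mapping[str, str] = bundle.registry_map
    if not reg_map:
        raise ValueError("bundle.registry_map is empty: nothing to sample")
    registry.validate_complete(reg_map.keys())
    n = cfg.n_samples
    draws = {
        override_name: registry.sample_param(reg_name, n, cfg.master_seed)
        for reg_name, override_name in sorted(reg_map.items())
    }
    dc = np.empty(n)
    dq = np.empty(n)
    for i in range(n):
        try:
            res = bundle.cea({name: vec[i] for name, vec in draws.items()})
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        dc[i] = res.delta_cost
        dq[i] = res.delta_qalys
    return PSAResult(
        delta_cost=dc,
        delta_qalys=dq,
        ceac=ceac(dc, dq, cfg.lambda_grid),
        master_seed=cfg.master_seed,
    )


@dataclass(frozen=True)
class SweepResult:
    parameter: str
    value_low: float
    value_high: float
    result_low: CEAResult
    result_high: CEAResult
    decision_changed: bool
    lam: float


def univariate_sweep(
    bundle,
    registry: ParamRegistry,
    parameter: str,
    lower_q: float = 0.025,
    upper_q: float = 0.975,
    lam: float = 20_000.0,
) -> SweepResult:
    """One-way (tornado) sweep of a parameter between distribution quantiles.

    The parameter is set to its lower and upper quantile with everything
    else at point estimates; the decision is 'changed' when the NMB sign at
    the chosen willingness-to-pay differs between the two ends.
    """
    if parameter not in registry:
        raise KeyError(f"unknown parameter {parameter!r}")
    reg_map: Mapping[str, str] = bundle.registry_map
    if parameter not in reg_map:
        raise KeyError(
            f"parameter {parameter!r} is not wired into this bundle "
            f"(known: {sorted(reg_map)})"
        )
    override = reg_map[parameter]
    lo = registry.quantile_param(parameter, lower_q)
    hi = registry.quantile_param(parameter, upper_q)
    res_lo = bundle.cea({override: lo})
    res_hi = bundle.cea({override: hi})
    changed = (nmb(res_lo, lam) > 0.0) != (nmb(res_hi, lam) > 0.0)
    return SweepResult(parameter, lo, hi, res_lo, res_hi, changed, lam)


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    lam: float
    crossing_value: float | str  # float, or BELOW_RANGE / ABOVE_RANGE sentinel
    direction: int  # sign of d(NMB)/d(parameter) over the bracket


def threshold_search(
    bundle,
    parameter: str,
    lam: float,
    bracket: tuple[float, float],
    n_monotone_check: int = 9,
    rtol: float = 1e-6,
) -> ThresholdResult:
    """Parameter value at which the adoption decision changes at ``lam``.

    Works on the NMB sign (stable near zero QALY increments).  The response
    is first checked for monotonicity on a coarse grid over the bracket; a
    clear non-monotone pattern raises.  When the NMB does not change sign in
    the bracket, the sentinel says on which side the crossing would lie
    given the response direction.
    """
    lo, hi = bracket
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError(f"need a finite bracket with low < high, got {bracket}")

    def f(x: float) -> float:
        return nmb(bundle.cea({parameter: x}), lam)

    xs = np.linspace(lo, hi, n_monotone_check)
    ys = np.array([f(x) for x in xs])
    diffs = np.diff(ys)
    scale = max(np.max(np.abs(ys)), 1e-12)
    rising = diffs > 1e-9 * scale
    falling = diffs < -1e-9 * scale
    if rising.any() and falling.any():
        raise ValueError(
            f"NMB response to {parameter!r} is not monotone over {bracket}; "
            "threshold search would be ambiguous"
        )
    direction = 1 if rising.any() else (-1 if falling.any() else 0)

    if ys[0] == 0.0:
        return ThresholdResult(parameter, lam, float(lo), direction)
    if ys[-1] == 0.0:
        return ThresholdResult(parameter, lam, float(hi), direction)
    if np.sign(ys[0]) == np.sign(ys[-1]):
        # crossing lies outside the bracket (or nowhere, for a flat response)
        if direction == 0:
            sentinel = BELOW_RANGE if ys[0] > 0 else ABOVE_RANGE
        elif direction > 0:
            sentinel = BELOW_RANGE if ys[0] > 0 else ABOVE_RANGE
        else:
            sentinel = ABOVE_RANGE if ys[0] > 0 else BELOW_RANGE
        return ThresholdResult(parameter, lam, sentinel, direction)

    xtol = max(abs(hi - lo) * 1e-12, 1e-15)
    root = brentq(f, lo, hi, rtol=rtol, xtol=xtol)
    return ThresholdResult(parameter, lam, float(root), direction)
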