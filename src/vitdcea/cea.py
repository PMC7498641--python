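"""Incremental cost-effectiveness: ICER, dominance, NMB and the CEAC."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decision_model import StrategyOutcome

__all__ = ["CEAResult", "CEACPoint", "compare", "nmb", "ceac", "format_icer"]

DEFAULT_LAMBDA_GRID = (20_000.0, 30_000.0)


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost/QALYs of intervention vs comparator.

    ``status`` is one of: ``dominant`` (cheaper and more effective),
    ``dominated`` (costlier and less effective), ``icer_defined``, or
    ``zero_increment`` (no QALY difference, so no ratio is defined).  The
    ICER is only reported when ``status == "icer_defined"``; when both
    increments are negative the ratio is kept but flagged through the
    status-aware :func:`format_icer`, never shown as a bare negative number.
    """

    delta_cost: float
    delta_qalys: float
    icer: float | None
    status: str

    @classmethod
    def from_increments(cls, delta_cost: float, delta_qalys: float) -> "CEAResult":
        if delta_cost < 0 and delta_qalys > 0:
            return cls(delta_cost, delta_qalys, None, "dominant")
        if delta_cost > 0 and delta_qalys < 0:
            return cls(delta_cost, delta_qalys, None, "dominated")
        if delta_qalys == 0.0:
            return cls(delta_cost, delta_qalys, None, "zero_increment")
        return cls(delta_cost, delta_qalys, delta_cost / delta_qalys, "icer_defined")


def compare(comparator: StrategyOutcome, intervention: StrategyOutcome) -> CEAResult:
    """Incrementals = intervention − comparator, classified per quadrant."""
    return CEAResult.from_increments(
        intervention.expected_cost - comparator.expected_cost,
        intervention.expected_qalys - comparator.expected_qalys,
    )


def nmb(result: CEAResult, lam: float) -> float:
    """Net monetary benefit ``lambda * dQALYs - dCost`` at willingness-to-pay lam."""
    if lam < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {lam}")
    return lam * result.delta_qalys - result.delta_cost


@dataclass(frozen=True)
class CEACPoint:
    lam: float
    probability_ce: float


def ceac(
    delta_cost: Sequence[float],
    delta_qalys: Sequence[float],
    lambdas: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve from paired PSA increments.

    At each willingness-to-pay the probability is the fraction of samples
    with positive net monetary benefit.
    """
    dc = np.asarray(delta_cost, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    if dc.size == 0 or dc.shape != dq.shape:
        raise ValueError("need non-empty, equal-length delta_cost and delta_qalys")
    return [
        CEACPoint(float(lam), float(np.mean(lam * dq - dc > 0.0))) for lam in lambdas
    ]


def format_icer(result: CEAResult) -> str:
    """Report-layer rendering: 'Dominant'/'Dominated' literals, nearest pound."""
    if result.status == "dominant":
        return "Dominant"
    if result.status == "dominated":
        return "Dominated"
    if result.status == "zero_increment":
        return "n/a (no QALY difference)"
    if result.delta_cost < 0 and result.delta_qalys < 0:
        return f"{round(result.icer):d} (SW quadrant: less costly, less effective)"
    return f"{round(result.icer):d}"
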