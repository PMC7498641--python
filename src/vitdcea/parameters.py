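"""Model parameters and their probabilistic-sensitivity distributions.

Every quantity the decision model consumes — health-state utilities,
episode durations, the intervention odds ratio, supplement-uptake rates,
treatment costs and rickets risks — is represented as a :class:`ParamSpec`:
a deterministic point estimate paired with the distribution drawn from in
probabilistic sensitivity analysis (PSA).  A :class:`ParamRegistry` keys the
specs by name, provides seeded per-parameter sampling sub-streams, and can
be serialised to/from a YAML configuration file.

Distribution conventions
------------------------
* ``beta(a, b)``        — standard shape parameters; mean ``a / (a + b)``.
* ``gamma(a, b)``       — shape ``a``, scale ``b``; mean ``a * b``.
* ``normal(a, b)``      — mean ``a``, standard deviation ``b``.
* ``lognormal(a, b)``   — by default ``(a, b)`` are the *natural-scale* mean
  and SD, moment-matched to ``(mu, sigma)`` on the log scale so that the
  analytic mean equals the quoted point estimate.  Set
  ``log_scale_params=True`` to interpret ``(a, b)`` as ``(mu, sigma)`` of
  ``log(X)`` directly.
* ``fixed(a)``          — a point mass; ``b`` is ignored and sampling always
  returns the point.

Published source tables in this problem area frequently quote a point
estimate, a reported SD *and* explicit distribution parameters that are not
mutually consistent.  The registry deliberately stores all three and exposes
:meth:`ParamRegistry.validation_report` to flag mismatches, rather than
silently refitting: the deterministic analysis uses the point, the PSA uses
the quoted distribution, and the reported SD is carried for display only.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "DistributionSpec",
    "ParamSpec",
    "ParamRegistry",
    "ParameterisationError",
    "InfeasibleMomentsError",
    "dist_moments",
    "fit_from_moments",
    "sample",
    "quantile",
    "substream",
    "assumed_sd",
]

FAMILIES = ("beta", "gamma", "lognormal", "normal", "fixed")


class ParameterisationError(ValueError):
    """Raised for an unsupported family or invalid family parameters."""


class InfeasibleMomentsError(ValueError):
    """Raised when (mean, sd) cannot be matched within a family's support."""


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution with family-specific parameters ``(a, b)``.

    ``note`` is free text recording how ``(a, b)`` map to moments (useful
    when transcribing published tables with idiosyncratic conventions).
    """

    family: str
    a: float
    b: float = 0.0
    note: str = ""
    log_scale_params: bool = False  # lognormal only: (a, b) = (mu, sigma) of log(X)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterisationError(
                f"unsupported distribution family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        a, b = self.a, self.b
        if self.family == "beta" and not (a > 0 and b > 0):
            raise ParameterisationError(f"beta requires a>0, b>0, got ({a}, {b})")
        if self.family == "gamma" and not (a > 0 and b > 0):
            raise ParameterisationError(
                f"gamma requires shape>0, scale>0, got ({a}, {b})"
            )
        if self.family == "normal" and not b >= 0:
            raise ParameterisationError(f"normal requires sd>=0, got sd={b}")
        if self.family == "lognormal":
            if self.log_scale_params:
                if not b >= 0:
                    raise ParameterisationError(f"lognormal sigma must be >=0, got {b}")
            elif not (a > 0 and b >= 0):
                raise ParameterisationError(
                    f"lognormal natural-scale mean must be >0 and sd>=0, got ({a}, {b})"
                )

    # -- internal helpers -------------------------------------------------

    def _lognormal_mu_sigma(self) -> tuple[float, float]:
        if self.log_scale_params:
            return self.a, self.b
        m, s = self.a, self.b
        if s == 0.0:
            return math.log(m), 0.0
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def frozen(self):
        """scipy frozen distribution; ``None`` for degenerate (point-mass) specs."""
        if self.family == "fixed":
            return None
        if self.family == "beta":
            return stats.beta(self.a, self.b)
        if self.family == "gamma":
            return stats.gamma(self.a, scale=self.b)
        if self.family == "normal":
            if self.b == 0.0:
                return None
            return stats.norm(self.a, self.b)
        mu, sigma = self._lognormal_mu_sigma()
        if sigma == 0.0:
            return None
        return stats.lognorm(s=sigma, scale=math.exp(mu))


def dist_moments(dist: DistributionSpec) -> tuple[float, float]:
    """Analytic (mean, sd) of a distribution spec.

    Closed forms per family: beta ``a/(a+b)``; gamma (shape-scale) ``a*b``
    and ``sqrt(a)*b``; normal ``(a, b)``; lognormal per the parameterisation
    convention; fixed ``(a, 0)``.
    """
    f = dist.family
    a, b = dist.a, dist.b
    if f == "fixed":
        return a, 0.0
    if f == "beta":
        n = a + b
        return a / n, math.sqrt(a * b / (n * n * (n + 1.0)))
    if f == "gamma":
        return a * b, math.sqrt(a) * b
    if f == "normal":
        return a, b
    # lognormal
    mu, sigma = dist._lognormal_mu_sigma()
    mean = math.exp(mu + sigma**2 / 2.0)
    sd = mean * math.sqrt(math.expm1(sigma**2))
    return mean, sd


def fit_from_moments(mean: float, sd: float, family: str) -> DistributionSpec:
    """Method-of-moments fit of ``family`` to a target (mean, sd).

    Round-trips with :func:`dist_moments` to 1e-9 relative on feasible
    inputs.  Raises :class:`InfeasibleMomentsError` when the moments fall
    outside the family's feasible region (e.g. a beta needs
    ``sd**2 < mean * (1 - mean)``).
    """
    if family not in FAMILIES:
        raise ParameterisationError(f"unsupported family {family!r}")
    if family == "fixed":
        return DistributionSpec("fixed", mean)
    if family == "normal":
        return DistributionSpec("normal", mean, sd)
    if family == "lognormal":
        if mean <= 0:
            raise InfeasibleMomentsError(
                f"lognormal requires mean>0, got mean={mean}"
            )
        return DistributionSpec("lognormal", mean, sd)
    if sd <= 0:
        raise InfeasibleMomentsError(
            f"{family} moment fit requires sd>0, got sd={sd}"
        )
    if family == "gamma":
        if mean <= 0:
            raise InfeasibleMomentsError(f"gamma requires mean>0, got {mean}")
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return DistributionSpec("gamma", shape, scale)
    # beta
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta requires 0<mean<1, got {mean}")
    if sd**2 >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"beta infeasible: need sd^2 < mean*(1-mean) = {mean * (1 - mean):.6g}, "
            f"got sd^2 = {sd**2:.6g}"
        )
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return DistributionSpec("beta", mean * nu, (1.0 - mean) * nu)


def sample(
    dist: DistributionSpec,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """``n`` seeded draws from ``dist``; identical seed gives identical draws."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = dist.family
    if f == "beta":
        return rng.beta(dist.a, dist.b, size=n)
    if f == "gamma":
        return rng.gamma(dist.a, dist.b, size=n)
    if f == "normal":
        return rng.normal(dist.a, dist.b, size=n)
    if f == "lognormal":
        mu, sigma = dist._lognormal_mu_sigma()
        return rng.lognormal(mu, sigma, size=n)
    return np.full(n, dist.a)  # fixed


def quantile(dist: DistributionSpec, p: float) -> float:
    """Inverse CDF at ``p`` in (0, 1); a fixed spec returns its point for any p."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must lie strictly in (0, 1), got {p}")
    fr = dist.frozen()
    if fr is None:  # point mass (fixed, or zero-sd normal/lognormal)
        return float(dist.a)
    return float(fr.ppf(p))


def assumed_sd(mean: float, fraction: float = 0.1) -> float:
    """The 'SD assumed to be 10% of the reported mean' convention, as a helper."""
    return abs(mean) * fraction


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Deterministic per-parameter random stream.

    The stream is keyed by ``(master_seed, sha256(name))`` so adding or
    removing a parameter never perturbs another parameter's draws, and the
    derivation is stable across processes (unlike the builtin ``hash``).
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


_SUPPORT_CHECKS = {
    "beta": lambda x: 0.0 <= x <= 1.0,
    "gamma": lambda x: x >= 0.0,
    "lognormal": lambda x: x > 0.0,
    "normal": lambda x: True,
    "fixed": lambda x: True,
}


@dataclass(frozen=True)
class ParamSpec:
    """A named model parameter: point estimate + PSA distribution.

    ``sd_reported`` is the SD quoted alongside the point (kept for display
    and validation; the PSA draws from ``dist`` as quoted).
    """

    name: str
    point: float
    dist: DistributionSpec
    sd_reported: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not _SUPPORT_CHECKS[self.dist.family](self.point):
            raise ParameterisationError(
                f"parameter {self.name!r}: point {self.point} outside the "
                f"support of a {self.dist.family} distribution"
            )
        if self.dist.family == "fixed" and self.dist.a != self.point:
            # keep the point authoritative for degenerate specs
            object.__setattr__(self, "dist", replace(self.dist, a=self.point))


class ParamRegistry:
    """Named collection of :class:`ParamSpec` with seeded sampling.

    Parameters
    ----------
    entries:
        Initial specs; names must be unique.
    provenance:
        Where the values came from (config path or ``"published-defaults"``).
    """

    def __init__(self, entries: Iterable[ParamSpec] = (), provenance: str = "in-memory"):
        self.provenance = provenance
        self._entries: dict[str, ParamSpec] = {}
        for spec in entries:
            self.add(spec)

    # -- container protocol ------------------------------------------------

    def add(self, spec: ParamSpec) -> None:
        if spec.name in self._entries:
            raise ValueError(f"duplicate parameter name {spec.name!r}")
        self._entries[spec.name] = spec

    def __getitem__(self, name: str) -> ParamSpec:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; known: {sorted(self._entries)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[ParamSpec]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def names(self) -> list[str]:
        return list(self._entries)

    # -- evaluation --------------------------------------------------------

    def point(self, name: str) -> float:
        return self[name].point

    def sample_param(self, name: str, n: int, master_seed: int) -> np.ndarray:
        """Draws from the parameter's own sub-stream; fixed specs return the point."""
        spec = self[name]
        if spec.dist.family == "fixed":
            return np.full(n, spec.point)
        return sample(spec.dist, n, substream(master_seed, name))

    def quantile_param(self, name: str, p: float) -> float:
        spec = self[name]
        if spec.dist.family == "fixed":
            return spec.point
        return quantile(spec.dist, p)

    def validate_complete(self, required: Iterable[str]) -> None:
        missing = sorted(set(required) - set(self._entries))
        if missing:
            raise KeyError(f"registry is missing required parameters: {missing}")

    def validation_report(self, rtol: float = 0.01) -> pd.DataFrame:
        """Flag parameters whose quoted distribution disagrees with the
        quoted point / SD.

        Source tables sometimes print distribution parameters whose analytic
        moments do not reproduce the printed point estimate or SD; this
        report makes every such mismatch visible without altering the specs.
        """
        rows = []
        for spec in self:
            mean, sd = dist_moments(spec.dist)
            mean_ok = math.isclose(mean, spec.point, rel_tol=rtol, abs_tol=1e-12)
            if spec.sd_reported is None:
                sd_ok = True
            else:
                sd_ok = math.isclose(sd, spec.sd_reported, rel_tol=rtol, abs_tol=1e-12)
            rows.append(
                {
                    "name": spec.name,
                    "point": spec.point,
                    "analytic_mean": mean,
                    "sd_reported": spec.sd_reported,
                    "analytic_sd": sd,
                    "mean_consistent": mean_ok,
                    "sd_consistent": sd_ok,
                }
            )
        return pd.DataFrame(rows)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for spec in self:
            d = {
                "point": float(spec.point),
                "family": spec.dist.family,
                "a": float(spec.dist.a),
                "b": float(spec.dist.b),
            }
            if spec.sd_reported is not None:
                d["sd"] = float(spec.sd_reported)
            if spec.source:
                d["source"] = spec.source
            if spec.dist.note:
                d["note"] = spec.dist.note
            if spec.dist.log_scale_params:
                d["log_scale_params"] = True
            out[spec.name] = d
        return out

    @classmethod
    def from_dict(cls, d: dict, provenance: str = "dict") -> "ParamRegistry":
        entries = []
        for name, v in d.items():
            dist = DistributionSpec(
                family=v["family"],
                a=float(v["a"]),
                b=float(v.get("b", 0.0)),
                note=v.get("note", ""),
                log_scale_params=bool(v.get("log_scale_params", False)),
            )
            entries.append(
                ParamSpec(
                    name=name,
                    point=float(v["point"]),
                    dist=dist,
                    sd_reported=(float(v["sd"]) if "sd" in v else None),
                    source=v.get("source", ""),
                )
            )
        return cls(entries, provenance=provenance)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"parameters": self.to_dict()}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ParamRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw["parameters"], provenance=str(path))
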