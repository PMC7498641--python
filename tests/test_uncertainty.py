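"""PSA machinery, one-way sweeps and threshold search vs independent oracles."""

from dataclasses import dataclass, field

import numpy as np
import pytest

import vitdcea as v
from vitdcea.cea import CEAResult, nmb
from vitdcea.parameters import DistributionSpec, ParamRegistry, ParamSpec
from vitdcea.uncertainty import (
    ABOVE_RANGE,
    BELOW_RANGE,
    PSAConfig,
    run_psa,
    threshold_search,
    univariate_sweep,
)


@dataclass
class LinearBundle:
    """Toy model linear in a single parameter: dQALYs = c0 + c1 * theta."""

    c0: float = 1e-4
    c1: float = 2e-3
    dc: float = 5.0
    theta0: float = 0.3
    registry_map: dict = field(default_factory=lambda: {"theta": "theta"})

    def cea(self, overrides=None):
        theta = (overrides or {}).get("theta", self.theta0)
        return CEAResult.from_increments(self.dc, self.c0 + self.c1 * theta)


def fixed_registry(cfg, bundle):
    """Clone of the default registry with every mapped parameter degenerate."""
    reg = ParamRegistry(provenance="degenerate")
    for name in bundle.registry_map:
        point = cfg.registry.point(name)
        reg.add(ParamSpec(name, point, DistributionSpec("fixed", point)))
    return reg


class TestRunPSA:
    def test_degenerate_distributions_reproduce_deterministic_run(self, cfg, bundles):
        bundle = bundles["medium"]
        det = bundle.cea()
        res = run_psa(bundle, fixed_registry(cfg, bundle), PSAConfig(n_samples=25, master_seed=4))
        assert np.all(res.delta_cost == det.delta_cost)
        assert np.all(res.delta_qalys == det.delta_qalys)

    def test_linear_model_mean_within_monte_carlo_error(self):
        """For a model linear in one beta parameter the PSA mean has the
        closed form c0 + c1*E[theta]; at n=1e5 the sample mean must land
        within 3 Monte-Carlo standard errors of it."""
        theta = DistributionSpec("beta", 3.0, 7.0)
        registry = ParamRegistry([ParamSpec("theta", 0.3, theta)])
        bundle = LinearBundle()
        n = 100_000
        res = run_psa(bundle, registry, PSAConfig(n_samples=n, master_seed=11))
        mean_theta, sd_theta = v.dist_moments(theta)
        closed_form = bundle.c0 + bundle.c1 * mean_theta
        se = bundle.c1 * sd_theta / np.sqrt(n)
        assert abs(res.mean_delta_qalys - closed_form) < 3.0 * se

    def test_same_seed_identical_ceac(self, cfg, bundles):
        bundle = bundles["medium"]
        psa_cfg = PSAConfig(n_samples=150, master_seed=21)
        a = run_psa(bundle, cfg.registry, psa_cfg)
        b = run_psa(bundle, cfg.registry, psa_cfg)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert [p.probability_ce for p in a.ceac] == [p.probability_ce for p in b.ceac]

    def test_icer_of_means_and_interval(self, cfg, bundles):
        res = run_psa(bundles["medium"], cfg.registry, PSAConfig(n_samples=300, master_seed=5))
        assert res.icer_of_means == pytest.approx(
            res.mean_delta_cost / res.mean_delta_qalys
        )
        lo, hi = res.nmb_interval(20_000.0)
        assert lo < hi

    def test_correlation_hook_not_silently_ignored(self, cfg, bundles):
        with pytest.raises(NotImplementedError):
            run_psa(
                bundles["medium"], cfg.registry, PSAConfig(n_samples=5),
                rank_correlation=np.eye(2),
            )


class TestUnivariateSweep:
    def test_fixed_parameter_no_flip(self, cfg, bundles):
        bundle = bundles["medium"]
        reg = fixed_registry(cfg, bundle)
        sw = univariate_sweep(bundle, reg, "treatment_cost_medium")
        assert sw.result_low.icer == sw.result_high.icer
        assert not sw.decision_changed

    def test_risk_sweep_flips_decision_in_medium_subgroup(self, cfg, bundles):
        """The rickets risk is the only driver able to change the adoption
        decision, and only where the point ICER sits near the threshold."""
        sw = univariate_sweep(bundles["medium"], cfg.registry, "annual_risk_medium")
        assert sw.decision_changed
        sw_dark = univariate_sweep(bundles["dark"], cfg.registry, "annual_risk_dark")
        assert not sw_dark.decision_changed  # dominant throughout

    def test_sweep_equals_direct_evaluation_at_quantiles(self, cfg, bundles):
        bundle = bundles["medium"]
        name = "rickets_utility"
        sw = univariate_sweep(bundle, cfg.registry, name)
        lo = cfg.registry.quantile_param(name, 0.025)
        hi = cfg.registry.quantile_param(name, 0.975)
        assert sw.result_low.icer == bundle.cea({name: lo}).icer
        assert sw.result_high.icer == bundle.cea({name: hi}).icer

    def test_symmetric_distribution_median_reproduces_point_icer(self, cfg, bundles):
        bundle = bundles["medium"]
        reg = ParamRegistry(
            [ParamSpec("rickets_utility", 0.621, DistributionSpec("normal", 0.621, 0.05))]
        )
        sw = univariate_sweep(bundle, reg, "rickets_utility", 0.5, 0.5)
        assert sw.result_low.icer == pytest.approx(bundle.cea().icer, rel=1e-12)

    def test_unknown_parameter(self, cfg, bundles):
        with pytest.raises(KeyError):
            univariate_sweep(bundles["medium"], cfg.registry, "nonexistent")


class TestThresholdSearch:
    def test_linear_nmb_crossing_in_closed_form(self):
        """NMB = lam*(c0 + c1*theta) - dc crosses zero at a known theta."""
        bundle = LinearBundle(c0=-1e-4, c1=2e-3, dc=5.0)
        lam = 20_000.0
        # lam*(c0 + c1*theta) = dc  =>  theta = (dc/lam - c0) / c1
        expected = (bundle.dc / lam - bundle.c0) / bundle.c1
        tr = threshold_search(bundle, "theta", lam, (0.0, 1.0))
        assert tr.crossing_value == pytest.approx(expected, rel=1e-6)
        assert tr.direction == 1

    def test_agrees_with_grid_scan_oracle(self, bundles):
        """Bisection agrees with a 10^4-point scan for the NMB sign change."""
        bundle = bundles["medium"]
        lam, bracket = 20_000.0, (0.01, 10.0)
        tr = threshold_search(bundle, "rickets_duration", lam, bracket)
        grid = np.linspace(*bracket, 10_001)
        signs = np.array(
            [nmb(bundle.cea({"rickets_duration": x}), lam) > 0 for x in grid]
        )
        (flips,) = np.nonzero(signs[1:] != signs[:-1])
        assert flips.size == 1
        step = grid[1] - grid[0]
        assert grid[flips[0]] <= tr.crossing_value <= grid[flips[0] + 1] + step

    def test_dominant_configuration_returns_sentinel(self, bundles):
        """Where the intervention dominates throughout the bracket the
        decision never changes inside it: the crossing lies below the range."""
        tr = threshold_search(bundles["dark"], "rickets_duration", 20_000.0, (0.01, 60.0))
        assert tr.crossing_value == BELOW_RANGE

    def test_sentinel_above_range(self):
        bundle = LinearBundle(c0=-1.0, c1=1e-3, dc=5.0)  # NMB < 0 over [0, 1]
        tr = threshold_search(bundle, "theta", 20_000.0, (0.0, 1.0))
        assert tr.crossing_value == ABOVE_RANGE

    def test_bracket_widening_invariance(self, bundles):
        bundle = bundles["medium"]
        narrow = threshold_search(bundle, "rickets_or", 20_000.0, (0.2, 0.8))
        wide = threshold_search(bundle, "rickets_or", 20_000.0, (0.05, 0.95))
        assert narrow.crossing_value == pytest.approx(wide.crossing_value, rel=1e-5)

    def test_non_monotone_response_diagnosed(self):
        @dataclass
        class Parabola:
            registry_map: dict = field(default_factory=lambda: {"theta": "theta"})

            def cea(self, overrides=None):
                th = (overrides or {}).get("theta", 0.0)
                return CEAResult.from_increments(5.0, 1e-3 * (th - 0.5) ** 2 + 1e-5)

        with pytest.raises(ValueError, match="not monotone"):
            threshold_search(Parabola(), "theta", 20_000.0, (0.0, 1.0))

    def test_infinite_bracket_rejected(self, bundles):
        with pytest.raises(ValueError):
            threshold_search(bundles["medium"], "rickets_duration", 2e4, (0.0, np.inf))
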