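"""Decision-tree engine vs independent path-enumeration / cycle oracles."""

import math

import numpy as np
import pytest

import vitdcea as v
from vitdcea.decision_model import STAGE1_YEARS, evaluate_arm, lifetime_extension


def clip01(x):
    return min(max(x, 0.0), 1.0)


def mixed_baseline_oracle(age, male_share=0.5):
    """The quoted age-squared baseline-utility equation, sex-mixed, clipped."""
    base = 0.950857 - 0.000259 * age * age
    return male_share * clip01(base + 0.021213) + (1 - male_share) * clip01(base)


def stage1_path_oracle(p, duration, cost, q, rq, rc, u_rickets, male_share=0.5):
    """Brute-force enumeration of stage-1 onset paths (onset year 0..3, never).

    Independent of the engine's cohort recursion: each path's probability,
    utilities and costs are written out explicitly and summed.
    """
    S = [1.0]
    for t in range(STAGE1_YEARS):
        S.append(S[-1] * (1.0 - q[t]))
    paths = [(s, (1.0 - p) ** s * p) for s in range(STAGE1_YEARS)]
    paths.append((None, (1.0 - p) ** STAGE1_YEARS))
    qalys = 0.0
    costs = 0.0
    whole = math.floor(duration)
    frac = duration - whole
    for onset, prob in paths:
        for t in range(STAGE1_YEARS):
            ub = mixed_baseline_oracle(t, male_share)
            if onset is None or t < onset:
                u = ub
            elif t - onset < whole:
                u = u_rickets
            elif t - onset == whole:
                u = frac * u_rickets + (1 - frac) * ub
            else:
                u = ub
            qalys += prob * S[t] * u * (1.0 + rq) ** -t
        if onset is not None:
            costs += prob * S[onset] * cost * (1.0 + rc) ** -onset
    return costs, qalys


@pytest.fixture
def toy_subgroup():
    return v.Subgroup("toy", annual_rickets_risk=0.3, treatment_cost_mean=1000.0)


class TestBaselineUtility:
    def test_newborn_female(self):
        assert v.baseline_utility(0, 0) == pytest.approx(0.950857, abs=1e-9)

    def test_newborn_male(self):
        assert v.baseline_utility(0, 1) == pytest.approx(0.972070, abs=1e-6)

    @pytest.mark.parametrize("age", [62, 70, 90, 100])
    def test_clipped_never_negative_at_high_ages(self, age):
        for g in (0, 1):
            assert v.baseline_utility(age, g) == 0.0

    def test_population_norm_variant_plausible_in_old_age(self):
        params = v.BaselineUtilityParams.population_norm()
        u70 = v.baseline_utility(70, 0, params)
        assert 0.5 < u70 < 1.0

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            v.baseline_utility(-1, 0)


class TestStage1:
    def test_zero_risk_equals_discounted_baseline_annuity(self, no_mortality_model):
        """A risk-free cohort accrues exactly the discounted baseline annuity."""
        sub = v.Subgroup("none", 0.0, 1000.0)
        out = evaluate_arm(
            v.ArmSpec("comparator"), sub, v.HealthStateParams(), v.CostConfig(),
            horizon=4, model_cfg=no_mortality_model,
        )
        expected = sum(
            mixed_baseline_oracle(t) * 1.035 ** -t for t in range(4)
        )
        assert out.expected_cost == 0.0
        assert out.expected_qalys == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "p, duration, rates",
        [
            (0.3, 2.0, 0.035),
            (0.12, 1.5, 0.0),
            (0.02, 2.4, 0.015),
        ],
    )
    def test_matches_path_enumeration_oracle(self, p, duration, rates):
        q = v.ModelConfig().life_table
        sub = v.Subgroup("toy", p, 1000.0)
        health = v.HealthStateParams(rickets_duration=duration)
        costcfg = v.CostConfig(discount_rate_costs=rates)
        model_cfg = v.ModelConfig(discount_rate_qalys=rates)
        out = evaluate_arm(v.ArmSpec("comparator"), sub, health, costcfg, 4, model_cfg)
        costs, qalys = stage1_path_oracle(
            p, duration, 1000.0, q, rates, rates, health.rickets_utility
        )
        assert out.expected_cost == pytest.approx(costs, abs=1e-12)
        assert out.expected_qalys == pytest.approx(qalys, abs=1e-12)

    def test_path_probabilities_sum_to_one(self, toy_subgroup):
        out = evaluate_arm(
            v.ArmSpec("comparator"), toy_subgroup, v.HealthStateParams(), v.CostConfig()
        )
        assert out.trace["path_probability_total"] == pytest.approx(1.0, abs=1e-12)

    def test_protective_or_weakly_improves_qalys(self, toy_subgroup):
        comp = evaluate_arm(
            v.ArmSpec("comparator"), toy_subgroup, v.HealthStateParams(), v.CostConfig()
        )
        less = evaluate_arm(
            v.ArmSpec("intervention", or_effect=0.41),
            toy_subgroup, v.HealthStateParams(), v.CostConfig(),
        )
        assert less.expected_qalys >= comp.expected_qalys
        assert less.expected_cost <= comp.expected_cost  # no programme costs borne

    def test_qalys_monotone_in_risk_duration_and_discount(self, bundles):
        b = bundles["medium"]
        base = b.evaluate()[0].expected_qalys
        riskier = b.with_overrides({"annual_rickets_risk": 0.02}).evaluate()[0]
        longer = b.with_overrides({"rickets_duration": 3.5}).evaluate()[0]
        heavier_discount = b.with_overrides({"discount_rate_qalys": 0.07}).evaluate()[0]
        assert riskier.expected_qalys < base
        assert longer.expected_qalys < base
        assert heavier_discount.expected_qalys < base
        better_state = b.with_overrides({"rickets_utility": 0.9}).evaluate()[0]
        assert better_state.expected_qalys > b.with_overrides(
            {"rickets_utility": 0.5}
        ).evaluate()[0].expected_qalys

    def test_missing_prices_for_funded_arm(self, toy_subgroup):
        with pytest.raises(ValueError, match="prices"):
            evaluate_arm(
                v.ArmSpec("intervention", bears_intervention_cost=True),
                toy_subgroup, v.HealthStateParams(), v.CostConfig(),
            )

    def test_invalid_horizon(self, toy_subgroup):
        with pytest.raises(ValueError, match="horizon"):
            evaluate_arm(
                v.ArmSpec("c"), toy_subgroup, v.HealthStateParams(), v.CostConfig(),
                horizon=10,
            )


class TestLifetime:
    def test_no_deficiency_no_complications_is_survival_annuity(self):
        """Stage 2 with every decrement off reduces to the survival-weighted
        discounted baseline annuity over the whole lifetime."""
        cfgm = v.ModelConfig(max_age=100)
        q = cfgm.life_table
        sub = v.Subgroup("none", 0.0, 0.0)
        health = v.HealthStateParams(
            complication_probability=0.0, deficiency_prevalence_baseline=0.0
        )
        out = evaluate_arm(
            v.ArmSpec("comparator"), sub, health, v.CostConfig(), "lifetime", cfgm
        )
        S, expected = 1.0, 0.0
        for age in range(101):
            expected += S * mixed_baseline_oracle(age) * 1.035 ** -age
            S *= 1.0 - q[age]
        assert out.expected_qalys == pytest.approx(expected, abs=1e-12)
        assert out.expected_cost == 0.0

    def test_unit_mortality_rr_leaves_survival_unchanged(self, toy_subgroup):
        kw = dict(mortality_rr=1.0, complication_probability=0.1)
        with_def = v.HealthStateParams(deficiency_prevalence_baseline=0.5, **kw)
        without = v.HealthStateParams(deficiency_prevalence_baseline=0.0, **kw)
        outs = [
            evaluate_arm(
                v.ArmSpec("c"), toy_subgroup, h, v.CostConfig(), "lifetime"
            ).trace["stage2"]["survival_start"]
            for h in (with_def, without)
        ]
        assert np.allclose(outs[0], outs[1], atol=1e-15)

    def test_small_grid_matches_cycle_oracle(self):
        """Three stage-2 cycles (max_age 6), every channel on, vs an explicit
        cycle-by-cycle expectation coded out by hand."""
        cfgm = v.ModelConfig(max_age=6, discount_rate_qalys=0.03)
        q = cfgm.life_table
        p, d, cost = 0.2, 2.0, 500.0
        health = v.HealthStateParams(
            rickets_duration=d,
            complication_probability=0.25,
            complication_disutility=0.05,
            complication_cost_annual=200.0,
            deficiency_prevalence_baseline=0.3,
            deficiency_disutility=0.01,
            deficiency_disutility_onset_age=5.0,  # active inside the grid
            mortality_rr=2.0,
            mortality_rr_onset_age=6.0,
        )
        sub = v.Subgroup("toy", p, cost)
        costcfg = v.CostConfig(discount_rate_costs=0.03)
        out = evaluate_arm(v.ArmSpec("c"), sub, health, costcfg, "lifetime", cfgm)

        # --- independent hand computation -------------------------------
        costs, qalys = stage1_path_oracle(p, d, cost, q, 0.03, 0.03, 0.621)
        onsets = [(1 - p) ** s * p for s in range(4)]
        ever = sum(onsets)
        comp = ever * 0.25
        S = 1.0
        for t in range(4):
            S *= 1.0 - q[t]
        for age in (4, 5, 6):
            active = onsets[3] if age == 4 and d == 2.0 else 0.0  # onset yr 3 spills
            ub = mixed_baseline_oracle(age)
            u = (1 - active) * ub + active * 0.621
            u -= comp * 0.05
            if age >= 5.0:
                u -= 0.3 * 0.01
            u = max(u, 0.0)
            qalys += S * u * 1.03 ** -age
            costs += comp * 200.0 * S * 1.03 ** -age
            q_age = q[age] * (1.0 + 0.3 * (2.0 - 1.0)) if age >= 6.0 else q[age]
            S *= 1.0 - q_age
        assert out.expected_qalys == pytest.approx(qalys, abs=1e-12)
        assert out.expected_cost == pytest.approx(costs, abs=1e-12)

    def test_lifetime_extension_requires_stage1_trace(self, toy_subgroup):
        stage1 = evaluate_arm(
            v.ArmSpec("c"), toy_subgroup, v.HealthStateParams(), v.CostConfig()
        )
        extended = lifetime_extension(stage1, v.HealthStateParams(), v.CostConfig())
        assert extended.expected_qalys > stage1.expected_qalys
        assert extended.trace["horizon"] == "lifetime"

    def test_life_table_shorter_than_max_age_rejected(self):
        with pytest.raises(ValueError, match="life table"):
            v.ModelConfig(max_age=100, life_table=np.zeros(50))


class TestBundleOverrides:
    def test_override_changes_target_field(self, bundles):
        b = bundles["medium"].with_overrides({"rickets_or": 0.8, "rickets_utility": 0.7})
        assert b.intervention.or_effect == 0.8
        assert b.health.rickets_utility == 0.7

    def test_unknown_override_rejected(self, bundles):
        with pytest.raises(KeyError, match="unknown model parameter"):
            bundles["medium"].with_overrides({"not_a_parameter": 1.0})

    def test_scenario_icer_below_basecase(self, cfg):
        """Enabling lifelong complications can only improve the intervention's
        value: scenario ICERs sit strictly below base-case ICERs."""
        for label in ("light", "medium"):
            base = v.build_bundle(cfg, label).cea()
            scen = v.build_bundle(cfg, label, scenario=True).cea()
            assert scen.icer < base.icer
        assert v.build_bundle(cfg, "dark", scenario=True).cea().status == "dominant"
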