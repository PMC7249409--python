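"""Response probabilities, augmented vs binary estimates, response weights."""
import math

import numpy as np
import pytest
from scipy import special, stats

from augbin import (
    ComponentRule,
    CompositeRule,
    Direction,
    JointParams,
    TrialData,
    augbin_analysis,
    binary_analysis,
    default_effect_scenario,
    fit_joint_model,
    response_probability,
    response_weights,
    simulate_trial,
)
from conftest import make_trial


class TestResponseProbability:
    def test_independence_factorisation(self, independent_params, median_rule):
        """gamma2 = 0, symmetric threshold and symmetric logistic:
        P = P(y >= 0) * P(b = 1) = 0.5 * 0.5."""
        p = response_probability(independent_params, 0, median_rule)
        assert p == pytest.approx(0.25, abs=1e-10)

    def test_limiting_cases(self, independent_params):
        far = CompositeRule(ComponentRule(Direction.AT_LEAST, 50.0))
        assert response_probability(independent_params, 0, far) < 1e-12
        sure = CompositeRule(ComponentRule(Direction.AT_LEAST, -50.0))
        certain_b = JointParams(0, 0, 1, 30.0, 0, 0)
        assert response_probability(certain_b, 0, sure) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_when_independent(self):
        """gamma2 = 0 factorises exactly: Phi term times logistic term."""
        p = JointParams(0.3, 0.5, 1.7, 0.8, -0.2, 0.0)
        rule = CompositeRule(ComponentRule(Direction.AT_LEAST, 1.1))
        for z in (0, 1):
            mu = 0.3 + 0.5 * z
            closed = stats.norm.sf((1.1 - mu) / 1.7) * special.expit(0.8 - 0.2 * z)
            assert response_probability(p, z, rule) == pytest.approx(closed, abs=1e-8)
        down = CompositeRule(ComponentRule(Direction.AT_MOST, 1.1))
        closed = stats.norm.cdf((1.1 - 0.3) / 1.7) * special.expit(0.8)
        assert response_probability(p, 0, down) == pytest.approx(closed, abs=1e-8)

    def test_against_monte_carlo(self):
        """Quadrature vs direct simulation of (y, b) pairs."""
        p = JointParams(0.0, 0.5, 1.0, 1.0, 0.0, 0.8)
        rule = CompositeRule(ComponentRule(Direction.AT_LEAST, 0.0))
        rng = np.random.default_rng(99)
        n = 1_000_000
        y = rng.normal(0.5, 1.0, n)
        b = rng.random(n) < special.expit(1.0 + 0.8 * y)
        mc = np.mean((y >= 0.0) & b)
        mc_se = math.sqrt(mc * (1 - mc) / n)
        assert response_probability(p, 1, rule) == pytest.approx(mc, abs=3 * mc_se)

    def test_monotone_in_threshold(self, independent_params):
        taus = np.linspace(-3, 3, 25)
        up = [
            response_probability(
                independent_params, 0, CompositeRule(ComponentRule(Direction.AT_LEAST, t))
            )
            for t in taus
        ]
        assert all(a >= b for a, b in zip(up, up[1:]))
        down = [
            response_probability(
                independent_params, 0, CompositeRule(ComponentRule(Direction.AT_MOST, t))
            )
            for t in taus
        ]
        assert all(a <= b for a, b in zip(down, down[1:]))


class TestBinaryAnalysis:
    def test_two_by_two_hand_values(self, median_rule):
        """30/100 responders vs 50/100: log OR = log((50*70)/(50*30))."""
        y0 = np.where(np.arange(100) < 30, 1.0, -1.0)
        y1 = np.where(np.arange(100) < 50, 1.0, -1.0)
        data = make_trial(
            np.repeat([0, 1], 100), np.concatenate([y0, y1]), np.ones(200)
        )
        est = binary_analysis(data, median_rule)
        assert est.p0 == pytest.approx(0.30)
        assert est.p1 == pytest.approx(0.50)
        assert est.log_or == pytest.approx(math.log(7 / 3), abs=1e-12)
        assert est.se_log_or == pytest.approx(
            math.sqrt(1 / 50 + 1 / 50 + 1 / 30 + 1 / 70), abs=1e-12
        )
        assert est.se_diff == pytest.approx(
            math.sqrt(0.3 * 0.7 / 100 + 0.5 * 0.5 / 100), abs=1e-12
        )

    def test_equal_counts_give_zero_effect(self, median_rule):
        y = np.tile(np.where(np.arange(50) < 20, 1.0, -1.0), 2)
        data = make_trial(np.repeat([0, 1], 50), y, np.ones(100))
        est = binary_analysis(data, median_rule)
        assert est.diff == 0.0
        assert est.log_or == 0.0

    def test_zero_cell_handling(self, median_rule):
        data = make_trial(
            np.repeat([0, 1], 50),
            np.concatenate([np.full(50, -1.0), np.where(np.arange(50) < 20, 1.0, -1.0)]),
            np.ones(100),
        )
        with pytest.raises(ValueError, match="degenerate"):
            binary_analysis(data, median_rule, zero_cell_correction=False)
        est = binary_analysis(data, median_rule, zero_cell_correction=True)
        assert np.isfinite(est.log_or) and np.isfinite(est.se_log_or)

    def test_undetermined_excluded(self, median_rule):
        data = make_trial(
            np.repeat([0, 1], 4),
            [1, 1, -1, np.nan, 1, -1, -1, 1],
            [1, 0, 1, 1, 1, 1, np.nan, 1],
        )
        est = binary_analysis(data, median_rule)
        assert est.extras["n_undetermined"] == 2
        assert est.n0 == 3 and est.n1 == 3

    def test_conf_level_validated(self, median_rule, toy_trial):
        with pytest.raises(ValueError, match="conf_level"):
            binary_analysis(toy_trial, median_rule, conf_level=1.2)


class TestAugmentedAnalysis:
    def test_identical_arms_give_null_effect(self, median_rule):
        rng = np.random.default_rng(10)
        y = rng.normal(0.2, 1.0, 120)
        b = (rng.random(120) < special.expit(1.5 + 0.5 * y)).astype(float)
        data = make_trial(
            np.repeat([0, 1], 120), np.tile(y, 2), np.tile(b, 2)
        )
        bin_est = binary_analysis(data, median_rule)
        assert bin_est.diff == 0.0 and bin_est.log_or == 0.0
        aug_est = augbin_analysis(data, median_rule)
        assert abs(aug_est.diff) < 1e-6
        assert abs(aug_est.log_or) < 1e-5

    def test_detects_large_effect_with_tighter_ci(self, median_rule):
        scen = default_effect_scenario(n_per_arm=500, seed=21)
        data = simulate_trial(scen, 0)
        aug = augbin_analysis(data, median_rule)
        bin_ = binary_analysis(data, median_rule)
        assert aug.diff > 0 and bin_.diff > 0  # same effect sign
        assert aug.ci_diff[0] > 0 and bin_.ci_diff[0] > 0
        assert aug.ci_width_diff < bin_.ci_width_diff
        assert 0 <= aug.p0 <= 1 and 0 <= aug.p1 <= 1
        assert aug.ci_diff[0] < aug.diff < aug.ci_diff[1]

    def test_missing_components_are_retained(self, median_rule):
        scen = default_effect_scenario(n_per_arm=200, seed=14).with_(
            miss_y=0.2, miss_b=0.2
        )
        data = simulate_trial(scen, 0)
        aug = augbin_analysis(data, median_rule)
        bin_ = binary_analysis(data, median_rule)
        # the joint model uses every subject with any observed component
        assert aug.extras["fit"].n_used > bin_.n0 + bin_.n1
        assert np.isfinite(aug.se_diff)

    def test_delta_method_matches_bootstrap(self, median_rule):
        """Delta-method SE of the difference vs a nonparametric bootstrap."""
        scen = default_effect_scenario(n_per_arm=200, seed=8)
        data = simulate_trial(scen, 0)
        est = augbin_analysis(data, median_rule)
        rng = np.random.default_rng(123)
        boot = []
        idx0 = np.flatnonzero(data.z == 0)
        idx1 = np.flatnonzero(data.z == 1)
        for _ in range(500):
            take = np.concatenate(
                [rng.choice(idx0, idx0.size), rng.choice(idx1, idx1.size)]
            )
            try:
                boot.append(augbin_analysis(data.subset(take), median_rule).diff)
            except (RuntimeError, ValueError):
                continue
        se_boot = float(np.std(boot, ddof=1))
        assert est.se_diff == pytest.approx(se_boot, rel=0.15)

    def test_boxcox_auto_recovers_skewed_scale(self):
        """Exponentiated data with threshold exp(0): the auto transform should
        land near log and reproduce the analysis on the original scale."""
        scen = default_effect_scenario(n_per_arm=300, seed=17)
        data = simulate_trial(scen, 0)
        skew = TrialData(data.ids, data.z, np.exp(data.y), data.b)
        rule_exp = CompositeRule(ComponentRule(Direction.AT_LEAST, 1.0))
        aug = augbin_analysis(skew, rule_exp, boxcox="auto")
        lam = aug.extras["boxcox_lambda"]
        assert abs(lam) < 0.2
        direct = augbin_analysis(data, scen.rule)
        assert aug.diff == pytest.approx(direct.diff, abs=0.02)

    def test_boxcox_requires_positive_threshold(self, median_rule):
        scen = default_effect_scenario(n_per_arm=100, seed=18)
        data = simulate_trial(scen, 0)
        with pytest.raises(ValueError, match="positive threshold"):
            augbin_analysis(data, median_rule, boxcox="auto")


class TestResponseWeights:
    @pytest.fixture()
    def fitted(self, median_rule):
        scen = default_effect_scenario(n_per_arm=200, seed=30)
        data = simulate_trial(scen, 0)
        return fit_joint_model(data), data

    def test_weight_anchors(self, fitted, median_rule):
        fit, _ = fitted
        s = fit.params.sigma
        probe = make_trial(
            [0, 0, 0],
            [7.0 * s, 0.0, 3.0],  # far above threshold; exactly at it; above
            [1, 1, 0],
        )
        w = response_weights(fit, probe, median_rule)
        assert w[0] > 0.999  # y - tau > 6 sigma
        assert w[1] == pytest.approx(0.5, abs=1e-12)  # at the threshold
        assert w[2] == 0.0  # binary criterion failed: hard gate

    def test_weights_bounded_and_monotone(self, fitted, median_rule):
        fit, data = fitted
        w = response_weights(fit, data, median_rule)
        assert np.all((w >= 0) & (w <= 1))
        sel = (data.b == 1.0) & ~np.isnan(data.y)
        order = np.argsort(data.y[sel])
        assert np.all(np.diff(w[sel][order]) >= 0)

    def test_missing_component_predictive(self, fitted, median_rule):
        fit, _ = fitted
        probe = make_trial(
            [0, 0, 0],
            [np.nan, np.nan, np.nan],
            [1, 0, np.nan],
        )
        w = response_weights(fit, probe, median_rule)
        assert 0 < w[0] < 1  # b=1, y unknown: posterior region probability
        assert w[1] == 0.0
        assert 0 < w[2] < 1  # nothing observed: marginal response probability

    def test_model_based_variant(self, fitted, median_rule):
        fit, data = fitted
        w = response_weights(fit, data, median_rule, variant="model_based")
        assert np.all((w >= 0) & (w <= 1))
        # the fitted gate is never exactly 0, unlike the observed one
        sel = (data.b == 0.0) & ~np.isnan(data.y)
        assert np.all(w[sel] > 0)
        with pytest.raises(ValueError, match="variant"):
            response_weights(fit, data, median_rule, variant="nope")
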