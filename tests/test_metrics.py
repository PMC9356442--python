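"""Operating-characteristic computations against analytic oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from rartrial.allocation import get_policy
from rartrial.engine import TrialHistory, run_batch, run_replicate
from rartrial.metrics import (
    aggregate,
    allocation_proportion,
    cell_counts_at,
    deaths_at,
    mse,
    neyman_allocation,
    relative_bias,
    treatment_test,
)
from rartrial.scenario import Scenario, default_schedule


def make_history(scenario, n, d, policy_name="FeR"):
    """Hand-built history from per-block cell arrays (no simulation)."""
    return TrialHistory(
        scenario, get_policy(policy_name, scenario.n_arms), default_schedule(),
        seed=0, n=np.asarray(n), d=np.asarray(d),
    )


@pytest.fixture(scope="module")
def tiny_scenario():
    return Scenario(("control", "drug"), ("i",), ((0.3, 0.2),), (1.0,), 10, 4)


class TestDeathsAndAllocation:
    def test_degenerate_outcomes(self, tiny_scenario):
        n = np.full((4, 1, 2), 5)
        zero = make_history(tiny_scenario, n, np.zeros_like(n))
        assert deaths_at(zero, 40) == 0
        all_dead = make_history(tiny_scenario, n, n.copy())
        assert deaths_at(all_dead, 40) == 40

    def test_partial_block_cut_consistent(self, tiny_scenario):
        hist = run_replicate(tiny_scenario, get_policy("FeR", 2),
                             schedule=None, seed=3)
        # deaths at a mid-block cut must interpolate between block boundaries
        d10, d15, d20 = (deaths_at(hist, c) for c in (10, 15, 20))
        assert d10 <= d15 <= d20
        sub, arm, out = hist.block_patients(2)
        assert d15 == d10 + out[:5].sum()

    def test_allocation_fractions_sum_to_one(self, two_arm):
        hist = run_replicate(two_arm, get_policy("FuR", 2), seed=4)
        total = sum(allocation_proportion(hist, arm, 6400) for arm in range(2))
        assert total == pytest.approx(1.0)

    def test_fer_mean_deaths_matches_mixture_oracle(self, batches):
        """Closed form: 6400 x sum_k mix_k (P_k0 + P_k1)/2 = 1556.6."""
        scen = batches.scenario("two-arm")
        oracle = 6400 * float(scen.mix @ scen.P.mean(axis=1))
        assert oracle == pytest.approx(1556.6, abs=0.1)
        oc = batches.oc("two-arm", "FeR", n_reps=1000)
        mean, se = oc.get("deaths")
        assert abs(mean - oracle) < 3 * se

    def test_fur_allocation_near_third(self, batches):
        oc = batches.oc("two-arm", "FuR", n_reps=1000)
        mean, se = oc.get("allocation", "cohort", "dexamethasone")
        assert abs(mean - 1 / 3) < 3 * se


class TestTreatmentTest:
    def test_equal_rates_not_rejected(self, tiny_scenario):
        n = np.full((4, 1, 2), 10)
        d = np.full((4, 1, 2), 3)
        res = treatment_test(make_history(tiny_scenario, n, d), 40, arm=1)
        assert not res.reject
        assert res.risk_difference == pytest.approx(0.0)

    def test_wald_matches_statsmodels_glm(self, tiny_scenario):
        """The closed-form fit equals a statsmodels binomial GLM Wald test."""
        import statsmodels.api as sm

        n = np.zeros((4, 1, 2), dtype=int)
        d = np.zeros_like(n)
        n[0, 0] = (200, 180)
        d[0, 0] = (58, 33)
        res = treatment_test(make_history(tiny_scenario, n, d), 380, arm=1)
        y = np.concatenate([np.repeat([1, 0], [58, 142]), np.repeat([1, 0], [33, 147])])
        x = sm.add_constant(np.repeat([0.0, 1.0], [200, 180]))
        glm = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        # agreement limited by the GLM's IRLS convergence tolerance
        assert res.p_value == pytest.approx(glm.pvalues[1], rel=1e-4)

    def test_separation_falls_back_to_score(self, tiny_scenario):
        n = np.zeros((4, 1, 2), dtype=int)
        d = np.zeros_like(n)
        n[0, 0] = (50, 50)
        d[0, 0] = (10, 0)  # no deaths on the drug arm
        res = treatment_test(make_history(tiny_scenario, n, d), 100, arm=1)
        assert res.method == "score"
        assert 0.0 <= res.p_value <= 1.0

    def test_power_matches_asymptotic_oracle(self):
        """Rejection rate for 0.414 vs 0.293 at ~500/arm tracks the
        normal-approximation power formula within 5 points."""
        scen = Scenario(("control", "drug"), ("iii",), ((0.414, 0.293),),
                        (1.0,), 1000, 1)
        batch = run_batch(scen, get_policy("FeR", 2), n_reps=400, base_seed=5)
        rate = np.mean([treatment_test(h, 1000, 1).reject for h in batch])
        p0, p1, m = 0.414, 0.293, 500
        log_or = math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))
        se = math.sqrt(1 / (m * p0 * (1 - p0)) + 1 / (m * p1 * (1 - p1)))
        power = stats.norm.cdf(abs(log_or) / se - stats.norm.ppf(0.975))
        assert abs(rate - power) < 0.05


class TestBiasAndMse:
    def test_exact_estimates_have_zero_bias(self):
        assert relative_bias([0.02, 0.02], 0.25, 0.23) == pytest.approx(0.0)

    def test_bias_arithmetic(self):
        assert relative_bias([0.022], 0.25, 0.23) == pytest.approx(0.1)

    def test_zero_true_difference_rejected(self):
        with pytest.raises(ValueError):
            relative_bias([0.0], 0.3, 0.3)

    def test_mse_arithmetic(self):
        assert mse([0.02], 0.02) == 0.0
        e = 0.003
        assert mse([0.02 + e, 0.02 - e], 0.02) == pytest.approx(e**2)

    def test_fer_mse_matches_binomial_variance_oracle(self, batches):
        """FeR cohort risk-difference MSE ~ p0 q0 / n0 + p1 q1 / n1."""
        scen = batches.scenario("two-arm")
        p0, p1 = scen.cohort_rate(0), scen.cohort_rate(1)
        oracle = p0 * (1 - p0) / 3200 + p1 * (1 - p1) / 3200
        oc = batches.oc("two-arm", "FeR", n_reps=1000)
        mean, _ = oc.get("mse", "cohort", "dexamethasone")
        assert mean == pytest.approx(oracle, rel=0.25)


class TestNeymanAllocation:
    def test_symmetry(self):
        assert neyman_allocation(0.3, 0.3) == 0.5

    def test_hand_example(self):
        assert neyman_allocation(0.5, 0.1) == pytest.approx(0.625)

    def test_boundary_rates_rejected(self):
        with pytest.raises(ValueError):
            neyman_allocation(0.0, 0.5)


class TestAggregate:
    def test_identical_histories_zero_se(self, tiny_scenario):
        n = np.full((4, 1, 2), 10)
        d = np.full((4, 1, 2), 2)
        hist = make_history(tiny_scenario, n, d)
        oc = aggregate([hist, hist, hist], n_cut=40)
        assert oc.get("deaths") == (16.0, 0.0)
        _, alloc_se = oc.get("allocation", "cohort", "drug")
        assert alloc_se == 0.0

    def test_subgroup_power_rows_present_for_subgroup_policies(self, batches):
        oc = batches.oc("two-arm", "T_s", n_reps=1000)
        table = oc.table
        rows = table[(table["metric"] == "rejection_rate") & (table["scope"] == "iii")]
        assert len(rows) == 1

    def test_cumulative_deaths_monotone(self, two_arm):
        hist = run_replicate(two_arm, get_policy("FeR", 2), seed=6)
        series = [deaths_at(hist, c) for c in range(80, 8001, 800)]
        assert all(a <= b for a, b in zip(series, series[1:]))

    def test_cell_counts_match_totals(self, two_arm):
        hist = run_replicate(two_arm, get_policy("T_f", 2), seed=6)
        n_kl, d_kl = cell_counts_at(hist, 6400)
        assert n_kl.sum() == 6400
        assert d_kl.sum() == deaths_at(hist, 6400)
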