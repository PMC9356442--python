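"""Trial engine: scheduling, lagged adaptation, determinism, history shape."""

import numpy as np
import pytest

from rartrial.allocation import get_policy
from rartrial.engine import (
    adaptation_blocks,
    observed_window,
    run_batch,
    run_replicate,
)
from rartrial.posterior import compute_theta
from rartrial.scenario import AdaptationSchedule, Scenario, default_schedule


class TestAdaptationBlocks:
    def test_study_schedule(self):
        blocks = adaptation_blocks(default_schedule(), 100)
        assert blocks == [35, 42, 49, 56, 63, 70, 77, 84, 91, 98]

    def test_truncation(self):
        assert adaptation_blocks(default_schedule(), 36) == [35]

    def test_burn_in_patient_count(self, two_arm):
        sched = default_schedule()
        assert sched.burn_in_blocks * two_arm.block_size == 2720
        # 42.5% on the RECOVERY-calibrated axis, where 100% = 6400 patients
        assert sched.burn_in_blocks * two_arm.block_size / two_arm.metric_cut_patients \
            == 0.425


class TestObservedWindow:
    @pytest.mark.parametrize("j, lag, expected", [
        (35, 28, range(1, 8)),
        (28, 28, range(1, 1)),
        (98, 28, range(1, 71)),
    ])
    def test_window_arithmetic(self, j, lag, expected):
        assert observed_window(j, lag) == expected


class TestRunReplicate:
    def test_fixed_policy_snapshots(self, two_arm):
        hist = run_replicate(two_arm, get_policy("FeR", 2), seed=1)
        assert len(hist.snapshots) == 10
        assert all(s.allocation == (0.5, 0.5) for s in hist.snapshots)
        assert all(s.theta is None for s in hist.snapshots)

    def test_burn_in_has_no_adaptations(self, two_arm):
        hist = run_replicate(two_arm, get_policy("T_f", 2), seed=2)
        assert min(s.block for s in hist.snapshots) == 35

    def test_patient_conservation_per_block(self, two_arm):
        hist = run_replicate(two_arm, get_policy("T_s", 2), seed=3)
        np.testing.assert_array_equal(hist.n.sum(axis=(1, 2)), 80)
        assert hist.total_patients == 8000
        assert (hist.d <= hist.n).all()

    def test_deterministic_from_seed(self, two_arm):
        a = run_replicate(two_arm, get_policy("RMC_f", 2), seed=42)
        b = run_replicate(two_arm, get_policy("RMC_f", 2), seed=42)
        assert np.array_equal(a.n, b.n) and np.array_equal(a.d, b.d)
        assert a.snapshots == b.snapshots

    def test_lag_honesty_theta_recomputable_from_window(self, two_arm):
        """Every recorded theta equals the quadrature posterior of the lagged
        window only: outcomes after block j - 28 cannot have leaked in."""
        hist = run_replicate(two_arm, get_policy("T_f", 2), seed=7)
        for snap in hist.snapshots:
            w_end = snap.block - hist.schedule.outcome_lag_blocks
            win_n, win_d = hist.window_cells(w_end)
            arm_d = win_d.sum(axis=0)
            arm_s = win_n.sum(axis=0) - arm_d
            assert snap.theta == pytest.approx(compute_theta(arm_d, arm_s), abs=1e-9)

    def test_subgroup_scope_theta_recomputable(self, two_arm):
        hist = run_replicate(two_arm, get_policy("RMC_s", 2), seed=8)
        by_scope = {}
        for snap in hist.snapshots:
            by_scope.setdefault(snap.scope, []).append(snap)
        assert set(by_scope) == set(two_arm.subgroup_names)
        for scope, snaps in by_scope.items():
            k = two_arm.subgroup_names.index(scope)
            for snap in snaps:
                w_end = snap.block - hist.schedule.outcome_lag_blocks
                win_n, win_d = hist.window_cells(w_end)
                arm_d = win_d[k]
                arm_s = win_n[k] - arm_d
                assert snap.theta == pytest.approx(compute_theta(arm_d, arm_s),
                                                   abs=1e-9)

    def test_arm_count_mismatch_rejected(self, two_arm):
        with pytest.raises(ValueError):
            run_replicate(two_arm, get_policy("T_f", 4), seed=0)

    def test_bandit_reduction_with_theta_stub(self):
        """With no burn-in, no lag, per-block updates and a deterministic
        theta stub the engine is a plain bandit loop whose allocation follows
        the stub exactly."""
        scen = Scenario(("a", "b"), ("i",), ((0.5, 0.5),), (1.0,), 20, 10)
        sched = AdaptationSchedule(0, 1, 0)
        stub = lambda d, s, scope, frac: (0.1, 0.9)
        hist = run_replicate(scen, get_policy("T_f", 2), sched, seed=0, theta_fn=stub)
        assert [s.block for s in hist.snapshots] == list(range(1, 11))
        from rartrial.allocation import clip_two, tuning_prob_two
        for snap in hist.snapshots:
            expected = clip_two(tuning_prob_two(0.9, snap.block / 10))
            assert snap.allocation[1] == pytest.approx(expected)


class TestRunBatch:
    def test_batch_reproducible_and_prefix_stable(self, two_arm):
        small = run_batch(two_arm, get_policy("FeR", 2), n_reps=2, base_seed=9)
        again = run_batch(two_arm, get_policy("FeR", 2), n_reps=2, base_seed=9)
        larger = run_batch(two_arm, get_policy("FeR", 2), n_reps=4, base_seed=9)
        for a, b in zip(small, again):
            assert np.array_equal(a.d, b.d)
        for a, b in zip(small, larger):
            assert np.array_equal(a.d, b.d)

    def test_replicates_differ(self, two_arm):
        batch = run_batch(two_arm, get_policy("FeR", 2), n_reps=3, base_seed=9)
        assert not np.array_equal(batch[0].d, batch[1].d)


class TestHistoryTables:
    def test_patient_table_shape_and_content(self, two_arm):
        hist = run_replicate(two_arm, get_policy("FuR", 2), seed=5)
        table = hist.patient_table()
        assert len(table) == 8000
        assert table["outcome"].sum() == hist.total_deaths
        assert (table.groupby("block").size() == 80).all()
        assert set(table["arm"]) <= set(two_arm.arm_names)

    def test_block_patients_reproducible(self, two_arm):
        hist = run_replicate(two_arm, get_policy("FuR", 2), seed=5)
        a = hist.block_patients(3)
        b = hist.block_patients(3)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_adaptations_table(self, two_arm):
        hist = run_replicate(two_arm, get_policy("T_f", 2), seed=5)
        table = hist.adaptations_table()
        assert set(table["block"]) == {35, 42, 49, 56, 63, 70, 77, 84, 91, 98}
        assert ((table["alloc_prob"] >= 0) & (table["alloc_prob"] <= 1)).all()
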