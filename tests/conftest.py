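"""Shared fixtures: scenarios and memoized replicate batches.

Replicate batches are expensive, and several tests interrogate the same
policy's batch (metrics, invariants, orderings), so a session-scoped
memoizing runner hands out each (scenario, policy, reps, null) batch exactly
once.  The base seed is fixed so the suite is fully deterministic.
"""

from __future__ import annotations

import pytest

from rartrial import (
    aggregate,
    default_schedule,
    get_policy,
    null_variant,
    recovery_four_arm,
    recovery_two_arm,
    run_batch,
)

BASE_SEED = 1234


@pytest.fixture(scope="session")
def two_arm():
    return recovery_two_arm()


@pytest.fixture(scope="session")
def four_arm():
    return recovery_four_arm()


class BatchRunner:
    """Memoized access to simulated replicate batches and their aggregates."""

    def __init__(self):
        self._scenarios = {
            ("two-arm", False): recovery_two_arm(),
            ("two-arm", True): null_variant(recovery_two_arm()),
            ("four-arm", False): recovery_four_arm(),
            ("four-arm", True): null_variant(recovery_four_arm()),
        }
        self._batches = {}
        self._ocs = {}

    def scenario(self, scenario_name: str, null: bool = False):
        return self._scenarios[(scenario_name, null)]

    def batch(self, scenario_name: str, policy_name: str, n_reps: int = 1000,
              null: bool = False):
        key = (scenario_name, policy_name, n_reps, null)
        if key not in self._batches:
            scen = self.scenario(scenario_name, null)
            self._batches[key] = run_batch(
                scen, get_policy(policy_name, scen.n_arms), default_schedule(),
                n_reps=n_reps, base_seed=BASE_SEED,
            )
        return self._batches[key]

    def oc(self, scenario_name: str, policy_name: str, n_reps: int = 1000,
           null: bool = False):
        key = (scenario_name, policy_name, n_reps, null)
        if key not in self._ocs:
            self._ocs[key] = aggregate(self.batch(*key))
        return self._ocs[key]


@pytest.fixture(scope="session")
def batches():
    return BatchRunner()
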