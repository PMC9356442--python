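"""Block-by-block trial engine: burn-in, lagged adaptation, history capture.

One replicate walks the trial's blocks in order.  Before the first adaptation
every block is allocated with the policy's burn-in vector; at each scheduled
adaptation block the probability-of-best vector is recomputed from the
outcomes that have matured (blocks ``1..j - lag``) and the allocation vector
is refreshed, then held constant until the next adaptation.  Subgroup-scope
policies run one independent adaptive allocation per subgroup.

Metrics are computed post hoc from the returned :class:`TrialHistory`; the
engine itself only simulates and records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .allocation import AllocationInputs, AllocationPolicy, full_allocation_vector
from .outcomes import replicate_seed, rng_stream
from .posterior import compute_theta
from .scenario import AdaptationSchedule, Scenario, default_schedule

__all__ = [
    "AdaptationSnapshot",
    "TrialHistory",
    "adaptation_blocks",
    "observed_window",
    "run_batch",
    "run_replicate",
]

# Optional override for theta computation (testing hook); called as
# theta_fn(deaths_per_arm, survivors_per_arm, scope, s) -> theta vector.
ThetaFn = Callable[[np.ndarray, np.ndarray, str, float], Sequence[float]]


def adaptation_blocks(schedule: AdaptationSchedule, n_blocks: int) -> list[int]:
    """Blocks (1-based) at which the allocation vector is refreshed.

    First adaptation at ``burn_in_blocks + 1``, then every
    ``update_cadence_blocks`` blocks, truncated at ``n_blocks``.
    """
    first = schedule.burn_in_blocks + 1
    return list(range(first, n_blocks + 1, schedule.update_cadence_blocks))


def observed_window(j: int, lag: int) -> range:
    """Inclusive 1-based block range ``1..j - lag`` visible at block ``j``
    (empty when ``j <= lag``)."""
    if j < 1:
        raise ValueError("block index must be >= 1")
    return range(1, max(j - lag, 0) + 1)


@dataclass(frozen=True)
class AdaptationSnapshot:
    """Allocation state recorded at one adaptation block for one scope."""

    block: int
    scope: str  # "cohort" or a subgroup name
    theta: tuple[float, ...] | None  # None for fixed policies
    allocation: tuple[float, ...]


@dataclass
class TrialHistory:
    """Complete record of one simulated replicate.

    ``n`` and ``d`` are ``(n_blocks, n_subgroups, n_arms)`` integer arrays of
    allocated patients and deaths per block and cell; per-patient rows can be
    reconstructed deterministically with :meth:`patient_table`.
    """

    scenario: Scenario
    policy: AllocationPolicy
    schedule: AdaptationSchedule
    seed: int
    n: np.ndarray
    d: np.ndarray
    snapshots: list[AdaptationSnapshot] = field(default_factory=list)

    @property
    def total_patients(self) -> int:
        return int(self.n.sum())

    @property
    def total_deaths(self) -> int:
        return int(self.d.sum())

    def window_cells(self, last_block: int) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative (patients, deaths) per (subgroup, arm) over blocks
        ``1..last_block``."""
        return self.n[:last_block].sum(axis=0), self.d[:last_block].sum(axis=0)

    def block_patients(self, j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-patient (subgroup, arm, outcome) arrays for block ``j``.

        The within-block order is a deterministic seeded shuffle: a block is
        one day's admissions, whose internal order carries no information, but
        a fixed unshuffled order would bias metrics taken at cuts inside a
        block.
        """
        counts = self.n[j - 1]
        deaths = self.d[j - 1]
        K, L = counts.shape
        sub = np.repeat(np.arange(K), counts.sum(axis=1))
        arm = np.concatenate([np.repeat(np.arange(L), counts[k]) for k in range(K)])
        out = np.concatenate(
            [
                np.concatenate([np.ones(deaths[k, l], dtype=np.int8),
                                np.zeros(counts[k, l] - deaths[k, l], dtype=np.int8)])
                for k in range(K)
                for l in range(L)
            ]
        ) if counts.sum() else np.zeros(0, dtype=np.int8)
        order = rng_stream(self.seed, "block-order", j).permutation(len(sub))
        return sub[order], arm[order], out[order]

    def patient_table(self) -> pd.DataFrame:
        """Per-patient DataFrame (block, subgroup, arm, outcome), CSV-ready."""
        frames = []
        for j in range(1, self.scenario.n_blocks + 1):
            sub, arm, out = self.block_patients(j)
            frames.append(
                pd.DataFrame(
                    {
                        "block": j,
                        "subgroup": [self.scenario.subgroup_names[k] for k in sub],
                        "arm": [self.scenario.arm_names[l] for l in arm],
                        "outcome": out.astype(int),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def adaptations_table(self) -> pd.DataFrame:
        """Tidy DataFrame of adaptation snapshots (block, scope, arm, theta,
        alloc_prob)."""
        rows = []
        for snap in self.snapshots:
            for l, name in enumerate(self.scenario.arm_names):
                rows.append(
                    {
                        "block": snap.block,
                        "scope": snap.scope,
                        "arm": name,
                        "theta": None if snap.theta is None else snap.theta[l],
                        "alloc_prob": snap.allocation[l],
                    }
                )
        return pd.DataFrame(rows)


def _scope_keys(policy: AllocationPolicy, scenario: Scenario) -> list[str]:
    if policy.scope == "subgroup":
        return list(scenario.subgroup_names)
    return ["cohort"]


def run_replicate(
    scenario: Scenario,
    policy: AllocationPolicy,
    schedule: AdaptationSchedule | None = None,
    seed: int = 0,
    n_posterior_draws: int = 10_000,
    theta_fn: ThetaFn | None = None,
) -> TrialHistory:
    """Simulate one complete trial replicate.

    Randomness is split into four named streams (subgroups, allocation,
    outcomes, posterior) so that each component's draws are independent and
    individually reproducible.  ``theta_fn`` replaces the posterior
    computation (testing hook, e.g. a deterministic bandit stub).
    """
    if policy.n_arms != scenario.n_arms:
        raise ValueError(
            f"policy is for {policy.n_arms} arms but scenario has {scenario.n_arms}"
        )
    schedule = schedule or default_schedule()
    J, K, L = scenario.n_blocks, scenario.n_subgroups, scenario.n_arms
    P = scenario.P
    mix = scenario.mix
    bs = scenario.block_size

    rng_sub = rng_stream(seed, "subgroups")
    rng_alloc = rng_stream(seed, "allocation")
    rng_out = rng_stream(seed, "outcomes")
    rng_post = rng_stream(seed, "posterior")

    n = np.zeros((J, K, L), dtype=np.int64)
    d = np.zeros((J, K, L), dtype=np.int64)
    snapshots: list[AdaptationSnapshot] = []

    scopes = _scope_keys(policy, scenario)
    burn = policy.burn_in_vector()
    current: dict[str, tuple[float, ...]] = {key: burn for key in scopes}
    adapt = set(adaptation_blocks(schedule, J))
    lag = schedule.outcome_lag_blocks

    for j in range(1, J + 1):
        if j in adapt:
            s = j / J
            w_end = max(j - lag, 0)
            win_n = n[:w_end].sum(axis=0) if w_end else np.zeros((K, L), np.int64)
            win_d = d[:w_end].sum(axis=0) if w_end else np.zeros((K, L), np.int64)
            for key in scopes:
                if not policy.adaptive:
                    snapshots.append(AdaptationSnapshot(j, key, None, current[key]))
                    continue
                if key == "cohort":
                    arm_n, arm_d = win_n.sum(axis=0), win_d.sum(axis=0)
                else:
                    k = scenario.subgroup_names.index(key)
                    arm_n, arm_d = win_n[k], win_d[k]
                arm_s = arm_n - arm_d
                if theta_fn is not None:
                    theta = tuple(float(t) for t in theta_fn(arm_d, arm_s, key, s))
                else:
                    theta = compute_theta(arm_d, arm_s, rng=rng_post,
                                          n_draws=n_posterior_draws)
                inputs = AllocationInputs(theta, tuple(int(c) for c in arm_n), s)
                vec = full_allocation_vector(policy, inputs)
                current[key] = vec
                snapshots.append(AdaptationSnapshot(j, key, theta, vec))

        counts_k = rng_sub.multinomial(bs, mix)
        if policy.scope == "cohort":
            vec = np.asarray(current["cohort"])
            if L == 2:
                n1 = rng_alloc.binomial(counts_k, vec[1])
                n[j - 1, :, 0] = counts_k - n1
                n[j - 1, :, 1] = n1
            else:
                n[j - 1] = rng_alloc.multinomial(counts_k, vec)
        else:
            for k, key in enumerate(scenario.subgroup_names):
                vec = np.asarray(current[key])
                if L == 2:
                    n1 = rng_alloc.binomial(counts_k[k], vec[1])
                    n[j - 1, k] = (counts_k[k] - n1, n1)
                else:
                    n[j - 1, k] = rng_alloc.multinomial(counts_k[k], vec)
        d[j - 1] = rng_out.binomial(n[j - 1], P)

    assert n.sum() == scenario.total_patients
    return TrialHistory(scenario, policy, schedule, seed, n, d, snapshots)


def run_batch(
    scenario: Scenario,
    policy: AllocationPolicy,
    schedule: AdaptationSchedule | None = None,
    n_reps: int = 1000,
    base_seed: int = 0,
    n_posterior_draws: int = 10_000,
) -> list[TrialHistory]:
    """Run ``n_reps`` independent replicates.

    Per-replicate seeds are hash-derived from ``(base_seed, index)``, so
    replicate ``i`` is identical whether the batch holds 10 or 10000
    replicates and regardless of execution order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    return [
        run_replicate(
            scenario,
            policy,
            schedule,
            seed=replicate_seed(base_seed, i),
            n_posterior_draws=n_posterior_draws,
        )
        for i in range(n_reps)
    ]
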