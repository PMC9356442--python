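"""High-level interface: configure a simulation, run it, inspect results.

:class:`TrialSimulation` bundles a scenario, an allocation policy and an
adaptation schedule; :meth:`TrialSimulation.run` executes the replicate batch
and returns a :class:`SimulationResults` carrying the histories, the
aggregated operating characteristics, a ``summary()`` table and trajectory /
plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .allocation import AllocationPolicy, get_policy
from .engine import TrialHistory, run_batch
from .metrics import OperatingCharacteristics, aggregate, cell_counts_at
from .scenario import AdaptationSchedule, Scenario, default_schedule

__all__ = ["SimulationResults", "TrialSimulation"]


@dataclass
class TrialSimulation:
    """A configured simulation study for one scenario/policy pair.

    ``policy`` may be a policy name (resolved against the scenario's arm
    count) or an :class:`AllocationPolicy` instance.
    """

    scenario: Scenario
    policy: AllocationPolicy | str
    schedule: AdaptationSchedule = field(default_factory=default_schedule)
    n_reps: int = 1000
    n_posterior_draws: int = 10_000

    def __post_init__(self) -> None:
        if isinstance(self.policy, str):
            self.policy = get_policy(self.policy, self.scenario.n_arms)
        if self.policy.n_arms != self.scenario.n_arms:
            raise ValueError("policy and scenario arm counts differ")

    def run(self, seed: int = 0) -> "SimulationResults":
        """Simulate ``n_reps`` replicates and aggregate their metrics."""
        histories = run_batch(
            self.scenario,
            self.policy,
            self.schedule,
            n_reps=self.n_reps,
            base_seed=seed,
            n_posterior_draws=self.n_posterior_draws,
        )
        return SimulationResults(self, histories, aggregate(histories), seed)


@dataclass
class SimulationResults:
    """Replicate batch plus aggregated operating characteristics."""

    simulation: TrialSimulation
    histories: list[TrialHistory]
    oc: OperatingCharacteristics
    seed: int

    @property
    def scenario(self) -> Scenario:
        return self.simulation.scenario

    @property
    def policy(self) -> AllocationPolicy:
        policy = self.simulation.policy
        assert isinstance(policy, AllocationPolicy)
        return policy

    def summary(self) -> str:
        """Human-readable operating-characteristics table."""
        scen = self.scenario
        lines = [
            f"Trial simulation: {self.policy.name} "
            f"({scen.n_arms}-arm, {self.oc.n_reps} replicates, seed {self.seed})",
            f"Metrics at the first {self.oc.n_cut} of {scen.total_patients} patients",
            "-" * 72,
        ]
        deaths, deaths_se = self.oc.get("deaths")
        rate = self.oc.value("death_rate")
        lines.append(f"Deaths: {deaths:.1f} +/- {deaths_se:.1f} ({100 * rate:.1f}%)")
        for arm in scen.arm_names:
            m, se = self.oc.get("allocation", "cohort", arm)
            lines.append(f"Allocation to {arm}: {100 * m:.1f}% +/- {100 * se:.1f}")
        for arm in scen.arm_names[1:]:
            m, se = self.oc.get("rejection_rate", "cohort", arm)
            lines.append(f"Rejection rate ({arm} vs standard care): "
                         f"{100 * m:.1f}% +/- {100 * se:.1f}")
        table = self.oc.table
        if (table["metric"] == "fwer").any():
            m, se = self.oc.get("fwer")
            lines.append(f"Familywise rejection rate: {100 * m:.1f}% +/- {100 * se:.1f}")
        for _, row in table[table["metric"] == "bias"].iterrows():
            lines.append(
                f"Relative bias ({row['arm']}, {row['scope']}): "
                f"{100 * row['mean']:.2f} x 10^-2 +/- {100 * row['se']:.2f}"
            )
        return "\n".join(lines)

    def trajectory(self, every_blocks: int = 1) -> pd.DataFrame:
        """Across-trial metric series: deaths and allocation at the end of
        every ``every_blocks``-th block, averaged over replicates.

        These are the data behind trajectory-style figures (allocation
        ramp-up, cumulative mortality); cumulative deaths are non-decreasing
        in the cut by construction.
        """
        scen = self.scenario
        blocks = range(every_blocks, scen.n_blocks + 1, every_blocks)
        rows = []
        for j in blocks:
            n_cut = j * scen.block_size
            deaths = np.empty(len(self.histories))
            alloc = np.empty((len(self.histories), scen.n_arms))
            for i, hist in enumerate(self.histories):
                n_kl, d_kl = cell_counts_at(hist, n_cut)
                deaths[i] = d_kl.sum()
                alloc[i] = n_kl.sum(axis=0) / n_cut
            row = {"block": j, "n_cut": n_cut,
                   "deaths_mean": deaths.mean(),
                   "deaths_se": deaths.std(ddof=1) / np.sqrt(len(deaths))}
            for l, arm in enumerate(scen.arm_names):
                row[f"alloc_{arm}"] = alloc[:, l].mean()
                row[f"alloc_{arm}_se"] = alloc[:, l].std(ddof=1) / np.sqrt(len(deaths))
            rows.append(row)
        return pd.DataFrame(rows)

    def plot_allocation(self, ax=None, every_blocks: int = 1):
        """Plot mean allocation proportion per arm against trial progress."""
        import matplotlib.pyplot as plt

        traj = self.trajectory(every_blocks)
        if ax is None:
            _, ax = plt.subplots()
        frac = traj["n_cut"] / self.scenario.total_patients
        for arm in self.scenario.arm_names:
            ax.plot(100 * frac, 100 * traj[f"alloc_{arm}"], label=arm)
        ax.set_xlabel("trial progress (% of patients)")
        ax.set_ylabel("mean allocation (%)")
        ax.set_title(f"{self.policy.name} allocation trajectory")
        ax.legend()
        return ax
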