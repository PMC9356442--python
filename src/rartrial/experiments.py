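"""Experiment suites: run all policies of a scenario and emit result tables.

:func:`run_suite` reproduces the structure of the study's reporting: for each
policy it runs the replicate batch on the true scenario, aggregates the
operating characteristics at the 80% cut, additionally runs the null-rate
variant for type-I-error / familywise-error estimation, and writes tidy and
wide-format tables (allocation, mortality, power, error rate, bias x 10^-2,
MSE x 10^-4, deaths prevented relative to the 2:1 fixed scheme).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allocation import (
    FOUR_ARM_POLICY_NAMES,
    TWO_ARM_POLICY_NAMES,
    get_policy,
)
from .engine import run_batch
from .metrics import OperatingCharacteristics, aggregate
from .scenario import (
    AdaptationSchedule,
    Scenario,
    default_schedule,
    load_scenario,
    load_schedule,
    null_variant,
    recovery_four_arm,
    recovery_two_arm,
)
from .simulation import SimulationResults, TrialSimulation

__all__ = ["ExperimentSpec", "run_suite", "table_report"]


def _resolve_scenario(name_or_path: str) -> tuple[Scenario, AdaptationSchedule]:
    if name_or_path in ("two-arm", "two_arm", "2"):
        return recovery_two_arm(), default_schedule()
    if name_or_path in ("four-arm", "four_arm", "4"):
        return recovery_four_arm(), default_schedule()
    text = Path(name_or_path).read_text()
    return load_scenario(text), load_schedule(text)


def default_policies(scenario: Scenario) -> tuple[str, ...]:
    return TWO_ARM_POLICY_NAMES if scenario.n_arms == 2 else FOUR_ARM_POLICY_NAMES


@dataclass
class ExperimentSpec:
    """Declarative description of one experiment suite."""

    scenario: str = "two-arm"
    policies: tuple[str, ...] = ()
    schedule: AdaptationSchedule | None = None
    n_reps: int = 1000
    base_seed: int = 0
    out_dir: str | None = None
    trajectory: bool = False
    null_only: bool = False


def run_suite(spec: ExperimentSpec) -> dict:
    """Run one experiment suite; returns results and (optionally) writes files.

    Returns a dict with keys ``results`` (tidy DataFrame over all policies),
    ``tables`` (wide-format DataFrames), ``oc`` / ``null_oc`` (per-policy
    :class:`OperatingCharacteristics`) and ``manifest``.
    """
    scenario, schedule = _resolve_scenario(spec.scenario)
    if spec.schedule is not None:
        schedule = spec.schedule
    policy_names = tuple(spec.policies) or default_policies(scenario)
    for name in policy_names:  # fail before simulating anything
        get_policy(name, scenario.n_arms)
    null_scenario = null_variant(scenario)

    ocs: dict[str, OperatingCharacteristics] = {}
    null_ocs: dict[str, OperatingCharacteristics] = {}
    results: dict[str, SimulationResults] = {}
    for name in policy_names:
        if not spec.null_only:
            sim = TrialSimulation(scenario, name, schedule, n_reps=spec.n_reps)
            res = sim.run(seed=spec.base_seed)
            results[name] = res
            ocs[name] = res.oc
        null_hist = run_batch(
            null_scenario, get_policy(name, scenario.n_arms), schedule,
            n_reps=spec.n_reps, base_seed=spec.base_seed,
        )
        null_ocs[name] = aggregate(null_hist)

    tidy_frames = []
    for name, oc in {**ocs, **{f"{k} (null)": v for k, v in null_ocs.items()}}.items():
        frame = oc.table.copy()
        frame.insert(0, "policy", name)
        frame.insert(4, "cut", oc.n_cut)
        tidy_frames.append(frame)
    tidy = pd.concat(tidy_frames, ignore_index=True)

    tables = table_report(ocs, null_ocs, scenario) if ocs else {}
    manifest = {
        "package_version": __version__,
        "scenario": spec.scenario,
        "policies": list(policy_names),
        "n_reps": spec.n_reps,
        "base_seed": spec.base_seed,
        "schedule": {
            "burn_in": schedule.burn_in_blocks,
            "cadence": schedule.update_cadence_blocks,
            "lag": schedule.outcome_lag_blocks,
        },
        "metric_cut_patients": scenario.metric_cut_patients,
    }

    out = {"results": tidy, "tables": tables, "oc": ocs, "null_oc": null_ocs,
           "manifest": manifest}

    if spec.out_dir is not None:
        out_dir = Path(spec.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tidy.to_csv(out_dir / "results.csv", index=False)
        for key, frame in tables.items():
            frame.to_csv(out_dir / f"table_{key}.csv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        with (out_dir / "summary.txt").open("w") as fh:
            for name, res in results.items():
                fh.write(res.summary() + "\n\n")
        if spec.trajectory:
            traj_frames = []
            for name, res in results.items():
                frame = res.trajectory()
                frame.insert(0, "policy", name)
                traj_frames.append(frame)
            if traj_frames:
                pd.concat(traj_frames, ignore_index=True).to_csv(
                    out_dir / "trajectory.csv", index=False
                )
    return out


def _fmt(value: float, se: float | None = None, digits: int = 1) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if se is None:
        return f"{value:.{digits}f}"
    return f"{value:.{digits}f} +/- {se:.{digits}f}"


def table_report(
    ocs: dict[str, OperatingCharacteristics],
    null_ocs: dict[str, OperatingCharacteristics],
    scenario: Scenario,
) -> dict[str, pd.DataFrame]:
    """Wide-format report tables: ``operating`` (allocation %, mortality,
    power %, error rate %, bias x 10^-2, MSE x 10^-4) and ``mortality``
    (deaths and deaths prevented vs FuR; the FuR reference cell is a dash).

    Missing metrics render as empty cells, never as fabricated values.
    """
    policies = list(ocs)

    def cell(oc: OperatingCharacteristics | None, metric, scope="cohort", arm="",
             scale=1.0, digits=1):
        if oc is None:
            return ""
        try:
            mean, _ = oc.get(metric, scope, arm)
        except KeyError:
            return ""
        return _fmt(scale * mean, digits=digits)

    operating: dict[str, dict[str, str]] = {}
    for name in policies:
        oc = ocs[name]
        noc = null_ocs.get(name)
        col: dict[str, str] = {}
        for arm in scenario.arm_names:
            col[f"Proportion allocated to {arm} (%)"] = cell(
                oc, "allocation", "cohort", arm, scale=100.0)
        if oc.policy_name in ("T_s", "RMC_s"):
            for sub in scenario.subgroup_names:
                col[f"Proportion allocated to {scenario.arm_names[1]} "
                    f"in subgroup {sub} (%)"] = cell(
                        oc, "allocation", sub, scenario.arm_names[1], scale=100.0)
        deaths, deaths_se = oc.get("deaths")
        rate = oc.value("death_rate")
        col["Mortality (deaths and %)"] = (
            f"{deaths:.0f} ({100 * rate:.1f}%)")
        power_arms = (
            [scenario.arm_names[1]] if scenario.n_arms == 2
            else [scenario.arm_names[1], scenario.arm_names[3]]
        )
        for arm in power_arms:
            col[f"Statistical power {arm} (%)"] = cell(
                oc, "rejection_rate", "cohort", arm, scale=100.0)
        if oc.policy_name in ("T_s", "RMC_s"):
            for sub in scenario.subgroup_names[1:]:  # power only for ii and iii
                col[f"Statistical power subgroup {sub} (%)"] = cell(
                    oc, "rejection_rate", sub, scenario.arm_names[1], scale=100.0)
        if scenario.n_arms == 2:
            col["Type 1 error rate (%)"] = cell(
                noc, "rejection_rate", "cohort", scenario.arm_names[1], scale=100.0)
        else:
            col["Family-wise error rate (%)"] = cell(noc, "fwer", scale=100.0)
        for arm in scenario.arm_names[1:]:
            suffix = f" {arm}" if scenario.n_arms > 2 else ""
            col[f"Bias (x 10^-2){suffix}"] = cell(
                oc, "bias", "cohort", arm, scale=100.0, digits=1)
            col[f"Mean squared error (x 10^-4){suffix}"] = cell(
                oc, "mse", "cohort", arm, scale=1e4, digits=2)
        operating[name] = col
    operating_df = pd.DataFrame(operating)

    mortality: dict[str, dict[str, str]] = {}
    fur_deaths = ocs["FuR"].value("deaths") if "FuR" in ocs else None
    for name in policies:
        oc = ocs[name]
        deaths, se = oc.get("deaths")
        rate = oc.value("death_rate")
        row = {
            "Average deaths +/- SE (%)":
                f"{deaths:.0f} +/- {se:.1f} ({100 * rate:.1f}%)",
        }
        if fur_deaths is None:
            row["Deaths prevented vs FuR"] = ""
        elif name == "FuR":
            row["Deaths prevented vs FuR"] = "-"
        else:
            row["Deaths prevented vs FuR"] = f"{fur_deaths - deaths:.0f}"
        mortality[name] = row
    mortality_df = pd.DataFrame(mortality)

    return {"operating": operating_df, "mortality": mortality_df}
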