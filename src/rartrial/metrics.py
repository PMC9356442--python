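"""Operating characteristics computed from simulated trial histories.

All metrics are taken over the first ``n_cut`` allocated patients of each
replicate (default: the scenario's 80% cut, matching the sample size at
which RECOVERY published the dexamethasone result) and averaged across
replicates with Monte-Carlo standard errors:

* expected deaths E[N_Y] and per-arm allocation proportions;
* rejection rates (power on the true scenario, type-I error / familywise
  error on the null variant) from a Wald test on the treatment coefficient
  of a binomial log-odds model, Bonferroni-corrected in the multi-arm case;
* relative bias and mean squared error of the risk-difference estimate
  P-hat[k,0] - P-hat[k,l] built from raw cell proportions;
* Neyman's power-optimal two-arm allocation split.

The 28-day outcome lag constrains only adaptation inside the engine; metric
computation sees every generated outcome, so deaths are reported as a
full-cohort fraction (deaths / n_cut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import TrialHistory

__all__ = [
    "OperatingCharacteristics",
    "TestResult",
    "aggregate",
    "allocation_proportion",
    "cell_counts_at",
    "deaths_at",
    "mse",
    "neyman_allocation",
    "relative_bias",
    "treatment_test",
]


def cell_counts_at(
    history: TrialHistory, n_cut: int
) -> tuple[np.ndarray, np.ndarray]:
    """(patients, deaths) per (subgroup, arm) among the first ``n_cut``
    allocated patients.

    Cuts at block boundaries (the standard 80% cut always is) need only the
    stored per-block counts; a cut inside a block falls back to the
    deterministic per-patient reconstruction of that block.
    """
    if not 0 <= n_cut <= history.total_patients:
        raise ValueError("n_cut outside the simulated patient range")
    bs = history.scenario.block_size
    full, rem = divmod(n_cut, bs)
    n_kl, d_kl = history.window_cells(full)
    if rem:
        sub, arm, out = history.block_patients(full + 1)
        np.add.at(n_kl, (sub[:rem], arm[:rem]), 1)
        np.add.at(d_kl, (sub[:rem], arm[:rem]), out[:rem].astype(np.int64))
    return n_kl, d_kl


def deaths_at(history: TrialHistory, n_cut: int) -> int:
    """Deaths (eventual 28-day outcomes) among the first ``n_cut`` patients."""
    _, d_kl = cell_counts_at(history, n_cut)
    return int(d_kl.sum())


def allocation_proportion(
    history: TrialHistory, arm: int, n_cut: int, subgroup: int | None = None
) -> float:
    """Fraction of the first ``n_cut`` patients (within one subgroup, if
    given) assigned to ``arm``."""
    n_kl, _ = cell_counts_at(history, n_cut)
    if subgroup is None:
        return float(n_kl[:, arm].sum() / n_kl.sum())
    total = n_kl[subgroup].sum()
    if total == 0:
        return math.nan
    return float(n_kl[subgroup, arm] / total)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one treatment-vs-control hypothesis test."""

    reject: bool
    p_value: float
    risk_difference: float  # P-hat control - P-hat treatment
    method: str  # "wald" or "score" (separation fallback)


def _wald_or_score(d1: int, n1: int, d0: int, n0: int) -> tuple[float, str]:
    """Two-sided p-value for H0: equal death rates.

    The ML fit of a binomial log-odds model with a single arm indicator has
    closed form: the coefficient is the sample log odds ratio and its Wald
    variance is the sum of reciprocal cell counts.  With a zero cell
    (separation) the Wald statistic degenerates, so fall back to the pooled
    two-proportion score test.
    """
    s1, s0 = n1 - d1, n0 - d0
    if min(d1, s1, d0, s0) > 0:
        log_or = math.log(d1 * s0 / (d0 * s1))
        se = math.sqrt(1 / d1 + 1 / s1 + 1 / d0 + 1 / s0)
        z = log_or / se
        method = "wald"
    else:
        pooled = (d1 + d0) / (n1 + n0)
        if pooled in (0.0, 1.0):
            return 1.0, "score"
        se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n0))
        z = (d1 / n1 - d0 / n0) / se
        method = "score"
    return 2.0 * float(stats.norm.sf(abs(z))), method


def treatment_test(
    history: TrialHistory,
    n_cut: int,
    arm: int,
    level: float = 0.05,
    n_comparisons: int = 1,
    subgroup: int | None = None,
) -> TestResult:
    """Test ``arm`` against standard care among the first ``n_cut`` patients.

    Patients on other arms are excluded.  The test is two-sided at level
    ``level / n_comparisons`` (Bonferroni).  The returned risk difference
    (control minus treatment cell proportions) feeds the bias/MSE metrics.
    """
    if arm == 0:
        raise ValueError("arm 0 is the standard-care reference")
    n_kl, d_kl = cell_counts_at(history, n_cut)
    if subgroup is None:
        n0, d0 = int(n_kl[:, 0].sum()), int(d_kl[:, 0].sum())
        n1, d1 = int(n_kl[:, arm].sum()), int(d_kl[:, arm].sum())
    else:
        n0, d0 = int(n_kl[subgroup, 0]), int(d_kl[subgroup, 0])
        n1, d1 = int(n_kl[subgroup, arm]), int(d_kl[subgroup, arm])
    if n0 == 0 or n1 == 0:
        raise ValueError("both arms must be present among the first n_cut patients")
    p_value, method = _wald_or_score(d1, n1, d0, n0)
    risk_diff = d0 / n0 - d1 / n1
    return TestResult(p_value < level / n_comparisons, p_value, risk_diff, method)


def relative_bias(
    estimates: Sequence[float], true_p0: float, true_p1: float
) -> float:
    """Mean of (estimated difference - true difference) / true difference.

    ``estimates`` are per-replicate risk differences P-hat0 - P-hat1; the
    true difference ``true_p0 - true_p1`` must be non-zero.
    """
    true_diff = true_p0 - true_p1
    if true_diff == 0:
        raise ValueError("relative bias undefined for a zero true difference")
    est = np.asarray(estimates, dtype=float)
    return float(np.mean((est - true_diff) / true_diff))


def mse(estimates: Sequence[float], true_difference: float) -> float:
    """Mean squared deviation of replicate risk-difference estimates from
    the true difference."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise ValueError("need at least one estimate")
    return float(np.mean((est - true_difference) ** 2))


def neyman_allocation(p0: float, p1: float) -> float:
    """Power-optimal standard-care allocation fraction for a binary outcome.

    Proportional to the outcome standard deviation per arm:
    sqrt(p0 q0) / (sqrt(p0 q0) + sqrt(p1 q1)).
    """
    if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
        raise ValueError("rates must lie strictly inside (0, 1)")
    s0 = math.sqrt(p0 * (1 - p0))
    s1 = math.sqrt(p1 * (1 - p1))
    return s0 / (s0 + s1)


@dataclass
class OperatingCharacteristics:
    """Replicate-aggregated metrics for one policy at one patient cut.

    ``table`` is tidy: one row per (metric, scope, arm) with the replicate
    mean, its Monte-Carlo standard error (sample SD / sqrt(N)) and N.
    ``replicate_deaths`` keeps the per-replicate death counts so that
    between-policy differences (deaths prevented) can use paired standard
    errors under common random numbers.
    """

    policy_name: str
    n_cut: int
    n_reps: int
    table: pd.DataFrame
    replicate_deaths: np.ndarray

    def get(self, metric: str, scope: str = "cohort", arm: str = "") -> tuple[float, float]:
        """(mean, se) of one metric row; KeyError if absent."""
        rows = self.table[
            (self.table["metric"] == metric)
            & (self.table["scope"] == scope)
            & (self.table["arm"] == arm)
        ]
        if rows.empty:
            raise KeyError(f"no row for metric={metric!r}, scope={scope!r}, arm={arm!r}")
        row = rows.iloc[0]
        return float(row["mean"]), float(row["se"])

    def value(self, metric: str, scope: str = "cohort", arm: str = "") -> float:
        return self.get(metric, scope, arm)[0]


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = len(values)
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return float(values.mean()), se


def aggregate(
    histories: Sequence[TrialHistory],
    n_cut: int | None = None,
    level: float = 0.05,
) -> OperatingCharacteristics:
    """Summarise a replicate batch into an :class:`OperatingCharacteristics`.

    Computes, per replicate and then as mean +/- SE across replicates:
    deaths; allocation proportion per arm (cohort and per subgroup);
    rejection rate per experimental arm (cohort scope, and per subgroup for
    subgroup-scope two-arm policies, Bonferroni-corrected by the number of
    experimental arms); familywise error/rejection rate in the multi-arm
    case; relative bias and MSE of the risk difference per experimental arm
    (cohort and per subgroup).  Bias rows are omitted where the true
    difference is zero (the null scenario).
    """
    if len(histories) < 2:
        raise ValueError("need at least two replicates for standard errors")
    scenario = histories[0].scenario
    policy = histories[0].policy
    if n_cut is None:
        n_cut = scenario.metric_cut_patients
    K, L = scenario.n_subgroups, scenario.n_arms
    n_comparisons = L - 1 if L > 2 else 1
    N = len(histories)
    P = scenario.P
    mix = scenario.mix

    deaths = np.empty(N)
    alloc = np.empty((N, L))
    alloc_sub = np.empty((N, K, L))
    reject = np.zeros((N, L))
    reject_sub = np.full((N, K, L), np.nan)
    estimate = np.full((N, L), np.nan)
    estimate_sub = np.full((N, K, L), np.nan)
    any_reject = np.zeros(N)

    subgroup_scope = policy.scope == "subgroup"
    for i, hist in enumerate(histories):
        n_kl, d_kl = cell_counts_at(hist, n_cut)
        deaths[i] = d_kl.sum()
        tot = n_kl.sum()
        alloc[i] = n_kl.sum(axis=0) / tot
        with np.errstate(invalid="ignore"):
            alloc_sub[i] = n_kl / n_kl.sum(axis=1, keepdims=True)
        for arm in range(1, L):
            res = treatment_test(hist, n_cut, arm, level=level,
                                 n_comparisons=n_comparisons)
            reject[i, arm] = res.reject
            estimate[i, arm] = res.risk_difference
            for k in range(K):
                if n_kl[k, 0] and n_kl[k, arm]:
                    res_k = treatment_test(hist, n_cut, arm, level=level,
                                           n_comparisons=n_comparisons, subgroup=k)
                    reject_sub[i, k, arm] = res_k.reject
                    estimate_sub[i, k, arm] = res_k.risk_difference
        any_reject[i] = reject[i, 1:].any()

    rows: list[dict] = []

    def add(metric: str, scope: str, arm: str, values: np.ndarray) -> None:
        mean, se = _mean_se(values)
        rows.append({"metric": metric, "scope": scope, "arm": arm,
                     "mean": mean, "se": se, "n_reps": N})

    add("deaths", "cohort", "", deaths)
    add("death_rate", "cohort", "", deaths / n_cut)
    for l, arm_name in enumerate(scenario.arm_names):
        add("allocation", "cohort", arm_name, alloc[:, l])
        for k, sub_name in enumerate(scenario.subgroup_names):
            add("allocation", sub_name, arm_name, alloc_sub[:, k, l])
    for l in range(1, L):
        arm_name = scenario.arm_names[l]
        add("rejection_rate", "cohort", arm_name, reject[:, l])
        true_cohort = float(mix @ (P[:, 0] - P[:, l]))
        if true_cohort != 0.0:
            add("bias", "cohort", arm_name,
                (estimate[:, l] - true_cohort) / true_cohort)
        add("mse", "cohort", arm_name, (estimate[:, l] - true_cohort) ** 2)
        for k, sub_name in enumerate(scenario.subgroup_names):
            vals = reject_sub[:, k, l]
            if subgroup_scope and not np.isnan(vals).any():
                add("rejection_rate", sub_name, arm_name, vals)
            est_k = estimate_sub[:, k, l]
            true_k = float(P[k, 0] - P[k, l])
            if not np.isnan(est_k).any():
                if true_k != 0.0:
                    add("bias", sub_name, arm_name, (est_k - true_k) / true_k)
                add("mse", sub_name, arm_name, (est_k - true_k) ** 2)
    if L > 2:
        add("fwer", "cohort", "", any_reject)

    table = pd.DataFrame(rows)
    return OperatingCharacteristics(policy.name, int(n_cut), N, table, deaths)
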