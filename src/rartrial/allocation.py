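"""Allocation strategies: fixed randomisation and response-adaptive rules.

Two-arm strategies (probability of the experimental arm, then clipped to
[0.1, 0.9]):

* ``FeR`` - fixed 1:1 (probability 1/2);
* ``FuR`` - fixed 2:1 standard care : experimental (probability 1/3);
* ``T_f`` / ``T_s`` - tuning rule theta^s / (theta^s + (1 - theta)^s), at
  cohort / subgroup scope, where s is the fraction of the trial completed at
  the adaptation point (increasingly exploitative late in the trial);
* ``RMC_f`` / ``RMC_s`` - REMAP-CAP rule with weights sqrt(theta / (n + 1)),
  which discounts arms that have already accrued many patients.

Four-arm strategies: ``FeR`` (1:1:1:1), ``FuR`` (2:1:1:1), and ``T_f`` /
``RMC_f`` applied to the three experimental arms with the standard-care
probability fixed at 0.4; the experimental weights are normalized to a 0.6
budget and floored at 0.05, with the deficit taken from the largest arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FOUR_ARM_POLICY_NAMES",
    "TWO_ARM_POLICY_NAMES",
    "AllocationInputs",
    "AllocationPolicy",
    "clip_multi",
    "clip_two",
    "fixed_prob_two",
    "full_allocation_vector",
    "get_policy",
    "remapcap_prob_multi",
    "remapcap_prob_two",
    "tuning_prob_multi",
    "tuning_prob_two",
]


@dataclass(frozen=True)
class AllocationPolicy:
    """One of the ten allocation strategies, with its constants.

    ``kind`` is ``"fixed"``, ``"tuning"`` or ``"remapcap"``; ``scope`` is
    ``"cohort"`` or ``"subgroup"``.  ``fixed`` holds the full probability
    vector for fixed policies (and is None for adaptive ones).
    """

    name: str
    kind: str
    scope: str
    n_arms: int
    fixed: tuple[float, ...] | None = None
    clip_lo: float = 0.1
    clip_hi: float = 0.9
    floor: float = 0.05
    control_fraction: float = 0.4
    experimental_budget: float = 0.6

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "tuning", "remapcap"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.scope not in ("cohort", "subgroup"):
            raise ValueError(f"unknown policy scope {self.scope!r}")
        if not 0.0 <= self.clip_lo < self.clip_hi <= 1.0:
            raise ValueError("require 0 <= clip_lo < clip_hi <= 1")
        if self.floor < 0:
            raise ValueError("floor must be non-negative")
        if not 0.0 < self.control_fraction < 1.0:
            raise ValueError("control_fraction must be in (0, 1)")
        if self.kind == "fixed":
            if self.fixed is None or len(self.fixed) != self.n_arms:
                raise ValueError("fixed policy needs a full probability vector")
        elif self.n_arms > 2:
            if abs(self.control_fraction + self.experimental_budget - 1.0) > 1e-12:
                raise ValueError("control_fraction + experimental_budget must be 1")

    @property
    def adaptive(self) -> bool:
        return self.kind != "fixed"

    def burn_in_vector(self) -> tuple[float, ...]:
        """Allocation used before the first adaptation.

        Two-arm adaptive policies burn in at 1:1.  Four-arm adaptive policies
        keep the fixed 40% control with the 60% experimental budget split
        equally (0.2 each).  Fixed policies use their own vector throughout.
        """
        if not self.adaptive:
            assert self.fixed is not None
            return self.fixed
        if self.n_arms == 2:
            return (0.5, 0.5)
        per_arm = self.experimental_budget / (self.n_arms - 1)
        return (self.control_fraction,) + (per_arm,) * (self.n_arms - 1)


@dataclass(frozen=True)
class AllocationInputs:
    """Inputs to an adaptive rule at one adaptation point.

    ``theta``: probability-of-best vector over all arms (scope-specific);
    ``arm_counts``: patients per arm observed in the lagged window, within
    scope; ``s``: fraction of trial blocks completed, j / J.
    """

    theta: tuple[float, ...]
    arm_counts: tuple[int, ...]
    s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("s must be in [0, 1]")
        if any(c < 0 for c in self.arm_counts):
            raise ValueError("arm counts must be non-negative")


def _two_arm_fixed(name: str, prob_exp: float, **kw) -> AllocationPolicy:
    return AllocationPolicy(name, "fixed", "cohort", 2, fixed=(1.0 - prob_exp, prob_exp), **kw)


def _policies() -> dict[tuple[str, int], AllocationPolicy]:
    reg: dict[tuple[str, int], AllocationPolicy] = {}
    two = [
        _two_arm_fixed("FeR", 0.5),
        _two_arm_fixed("FuR", 1.0 / 3.0),
        AllocationPolicy("T_f", "tuning", "cohort", 2),
        AllocationPolicy("RMC_f", "remapcap", "cohort", 2),
        AllocationPolicy("T_s", "tuning", "subgroup", 2),
        AllocationPolicy("RMC_s", "remapcap", "subgroup", 2),
    ]
    four = [
        AllocationPolicy("FeR", "fixed", "cohort", 4, fixed=(0.25,) * 4),
        AllocationPolicy("FuR", "fixed", "cohort", 4, fixed=(0.4, 0.2, 0.2, 0.2)),
        AllocationPolicy("T_f", "tuning", "cohort", 4),
        AllocationPolicy("RMC_f", "remapcap", "cohort", 4),
    ]
    for pol in two:
        reg[(pol.name, 2)] = pol
    for pol in four:
        reg[(pol.name, 4)] = pol
    return reg


_REGISTRY = _policies()
TWO_ARM_POLICY_NAMES = ("FeR", "FuR", "T_f", "RMC_f", "T_s", "RMC_s")
FOUR_ARM_POLICY_NAMES = ("FeR", "FuR", "T_f", "RMC_f")


def get_policy(name: str, n_arms: int) -> AllocationPolicy:
    """Look up a named strategy for a 2- or 4-arm trial."""
    try:
        return _REGISTRY[(name, n_arms)]
    except KeyError:
        raise KeyError(f"no policy {name!r} for a {n_arms}-arm trial") from None


# -- two-arm rules ----------------------------------------------------------

def fixed_prob_two(policy: AllocationPolicy) -> float:
    """Experimental-arm probability of a fixed two-arm policy."""
    if policy.adaptive or policy.n_arms != 2:
        raise ValueError("fixed_prob_two requires a fixed two-arm policy")
    assert policy.fixed is not None
    return policy.fixed[1]


def tuning_prob_two(theta1: float, s: float) -> float:
    """Unclipped tuning-rule probability theta^s / (theta^s + (1-theta)^s)."""
    if not 0.0 <= theta1 <= 1.0:
        raise ValueError("theta1 must be in [0, 1]")
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must be in [0, 1]")
    num = theta1**s
    den = num + (1.0 - theta1) ** s
    return num / den


def remapcap_prob_two(theta1: float, theta0: float, n1: int, n0: int) -> float:
    """Unclipped REMAP-CAP probability sqrt(theta1/(n1+1)) over the sum."""
    if min(theta1, theta0) < 0 or max(theta1, theta0) > 1:
        raise ValueError("thetas must be in [0, 1]")
    if theta1 == 0.0 and theta0 == 0.0:
        raise ValueError("both thetas zero: allocation undefined")
    if n1 < 0 or n0 < 0:
        raise ValueError("counts must be non-negative")
    w1 = np.sqrt(theta1 / (n1 + 1.0))
    w0 = np.sqrt(theta0 / (n0 + 1.0))
    return float(w1 / (w1 + w0))


def clip_two(alpha: float, lo: float = 0.1, hi: float = 0.9) -> float:
    """Constrain a two-arm allocation probability to [lo, hi]."""
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("require 0 <= lo < hi <= 1")
    return min(hi, max(lo, alpha))


# -- multi-arm rules --------------------------------------------------------

def tuning_prob_multi(
    thetas: Sequence[float], s: float, experimental_budget: float = 0.6
) -> np.ndarray:
    """Unclipped tuning-rule vector over experimental arms.

    Per-arm weights theta^s / (theta^s + (1-theta)^s), normalized over the
    experimental arms and scaled to the budget; the output sums to the
    budget.
    """
    t = np.asarray(thetas, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("thetas must be in [0, 1]")
    if not 0.0 < experimental_budget < 1.0:
        raise ValueError("experimental_budget must be in (0, 1)")
    w = t**s / (t**s + (1.0 - t) ** s)
    total = w.sum()
    if total <= 0:
        raise ValueError("all tuning weights zero: allocation undefined")
    return experimental_budget * w / total


def remapcap_prob_multi(
    thetas: Sequence[float],
    arm_counts: Sequence[int],
    experimental_budget: float = 0.6,
) -> np.ndarray:
    """Unclipped REMAP-CAP vector sqrt(theta/(n+1)) over experimental arms,
    normalized to the budget."""
    t = np.asarray(thetas, dtype=float)
    n = np.asarray(arm_counts, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("thetas must be in [0, 1]")
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    if not 0.0 < experimental_budget < 1.0:
        raise ValueError("experimental_budget must be in (0, 1)")
    w = np.sqrt(t / (n + 1.0))
    total = w.sum()
    if total <= 0:
        raise ValueError("all REMAP-CAP weights zero: allocation undefined")
    return experimental_budget * w / total


def clip_multi(alphas: Sequence[float], floor: float = 0.05) -> np.ndarray:
    """Floor rule for the experimental arms of a multi-arm RAR vector.

    Every arm below ``floor`` is raised to it and the total deficit is
    subtracted from the single maximum arm (ties broken toward the lowest
    index), preserving the vector's sum exactly.
    """
    a = np.asarray(alphas, dtype=float).copy()
    below = a < floor
    if not below.any():
        return a
    deficit = float((floor - a[below]).sum())
    imax = int(a.argmax())  # argmax takes the lowest index on ties
    a[below] = floor
    a[imax] -= deficit
    if a[imax] < floor - 1e-12:
        raise ValueError("floor infeasible: maximum arm would drop below floor")
    return a


def full_allocation_vector(
    policy: AllocationPolicy,
    inputs: AllocationInputs | None = None,
) -> tuple[float, ...]:
    """Assemble the full per-arm allocation vector of a policy.

    Fixed policies return their constant vector.  Two-arm adaptive policies
    return ``(1 - alpha, alpha)`` with the clipped rule output; four-arm
    adaptive policies return the fixed 0.4 control probability followed by
    the clipped experimental vector.  The result always sums to 1.
    """
    if not policy.adaptive:
        assert policy.fixed is not None
        return policy.fixed
    if inputs is None:
        raise ValueError("adaptive policies require AllocationInputs")
    if len(inputs.theta) != policy.n_arms or len(inputs.arm_counts) != policy.n_arms:
        raise ValueError("theta / arm_counts dimension mismatch with policy")

    if policy.n_arms == 2:
        if policy.kind == "tuning":
            alpha = tuning_prob_two(inputs.theta[1], inputs.s)
        else:
            alpha = remapcap_prob_two(
                inputs.theta[1], inputs.theta[0],
                inputs.arm_counts[1], inputs.arm_counts[0],
            )
        alpha = clip_two(alpha, policy.clip_lo, policy.clip_hi)
        return (1.0 - alpha, alpha)

    if policy.kind == "tuning":
        raw = tuning_prob_multi(inputs.theta[1:], inputs.s, policy.experimental_budget)
    else:
        raw = remapcap_prob_multi(
            inputs.theta[1:], inputs.arm_counts[1:], policy.experimental_budget
        )
    clipped = clip_multi(raw, policy.floor)
    return (policy.control_fraction,) + tuple(float(x) for x in clipped)
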