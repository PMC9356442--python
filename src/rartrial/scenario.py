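"""Trial scenarios: arms, subgroups, true mortality rates and block structure.

A :class:`Scenario` fixes the data-generating model of a simulated platform
trial: patients arrive in daily blocks, each patient belongs to one of three
respiratory-support subgroups (i: no oxygen, ii: oxygen only, iii: invasive
ventilation), and the 28-day death indicator of a patient in subgroup ``k`` on
arm ``l`` is Bernoulli with probability ``P[k, l]``.  Arm 0 is always standard
care.

The two bundled defaults, :func:`recovery_two_arm` and
:func:`recovery_four_arm`, are calibrated to the mortality observed in the
RECOVERY trial (March-June 2020) for standard care, dexamethasone,
hydroxychloroquine and lopinavir-ritonavir.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "AdaptationSchedule",
    "Scenario",
    "ScenarioConfigError",
    "default_schedule",
    "load_scenario",
    "load_schedule",
    "null_variant",
    "recovery_four_arm",
    "recovery_two_arm",
]


class ScenarioConfigError(ValueError):
    """Raised when a scenario configuration is malformed or inconsistent."""


@dataclass(frozen=True)
class AdaptationSchedule:
    """When allocation probabilities may be updated.

    Parameters
    ----------
    burn_in_blocks : int
        Number of initial blocks allocated with the fixed burn-in vector,
        before the first adaptation.
    update_cadence_blocks : int
        Blocks between successive allocation updates.
    outcome_lag_blocks : int
        Follow-up lag: at an adaptation in block ``j`` only outcomes from
        blocks ``1..j - outcome_lag_blocks`` have matured and are usable.
    """

    burn_in_blocks: int = 34
    update_cadence_blocks: int = 7
    outcome_lag_blocks: int = 28

    def __post_init__(self) -> None:
        if self.burn_in_blocks < 0:
            raise ValueError("burn_in_blocks must be non-negative")
        if self.update_cadence_blocks < 1:
            raise ValueError("update_cadence_blocks must be at least 1")
        if self.outcome_lag_blocks < 0:
            raise ValueError("outcome_lag_blocks must be non-negative")
        if self.burn_in_blocks + 1 - self.outcome_lag_blocks < 1:
            raise ValueError(
                "first adaptation (block burn_in_blocks + 1) would have an "
                "empty observed window given outcome_lag_blocks"
            )


def default_schedule() -> AdaptationSchedule:
    """The RECOVERY-calibrated schedule: 34-block burn-in, 7-block cadence,
    28-block outcome lag."""
    return AdaptationSchedule(34, 7, 28)


def _as_tuple2(rows: Any) -> tuple[tuple[float, ...], ...]:
    return tuple(tuple(float(x) for x in row) for row in rows)


@dataclass(frozen=True)
class Scenario:
    """A fully specified trial data-generating scenario.

    Attributes
    ----------
    arm_names : tuple of str
        Ordered arm identifiers; index 0 is standard care.
    subgroup_names : tuple of str
        Ordered subgroup identifiers.
    mortality : tuple of tuple of float
        ``mortality[k][l]`` is the true 28-day death probability for subgroup
        ``k`` on arm ``l`` (stored as probabilities, e.g. 0.414).
    subgroup_mix : tuple of float
        Probability that an arriving patient belongs to each subgroup.
    block_size : int
        Patients recruited per block (one block = one day).
    n_blocks : int
        Total number of blocks in the simulation.
    metric_cut_fraction : float
        Fraction of total patients at which single-point operating
        characteristics are evaluated (default 0.80).
    """

    arm_names: tuple[str, ...]
    subgroup_names: tuple[str, ...]
    mortality: tuple[tuple[float, ...], ...]
    subgroup_mix: tuple[float, ...]
    block_size: int
    n_blocks: int
    metric_cut_fraction: float = 0.80

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm_names", tuple(str(a) for a in self.arm_names))
        object.__setattr__(self, "subgroup_names", tuple(str(s) for s in self.subgroup_names))
        object.__setattr__(self, "mortality", _as_tuple2(self.mortality))
        object.__setattr__(self, "subgroup_mix", tuple(float(m) for m in self.subgroup_mix))
        self._validate()

    def _validate(self) -> None:
        if len(self.arm_names) < 2:
            raise ScenarioConfigError("arm_names: need at least two arms")
        if len(self.mortality) != len(self.subgroup_names):
            raise ScenarioConfigError("mortality: one row per subgroup required")
        for row in self.mortality:
            if len(row) != len(self.arm_names):
                raise ScenarioConfigError("mortality: one column per arm required")
            for p in row:
                if not 0.0 <= p <= 1.0:
                    raise ScenarioConfigError(f"mortality: rate {p} outside [0, 1]")
        if len(self.subgroup_mix) != len(self.subgroup_names):
            raise ScenarioConfigError("subgroup_mix: one entry per subgroup required")
        if any(m < 0 for m in self.subgroup_mix):
            raise ScenarioConfigError("subgroup_mix: negative probability")
        if abs(sum(self.subgroup_mix) - 1.0) > 1e-12:
            raise ScenarioConfigError(
                f"subgroup_mix: sums to {sum(self.subgroup_mix)!r}, expected 1"
            )
        if self.block_size < 1 or self.n_blocks < 1:
            raise ScenarioConfigError("block_size and n_blocks must be positive")
        if not 0.0 < self.metric_cut_fraction <= 1.0:
            raise ScenarioConfigError("metric_cut_fraction must be in (0, 1]")

    # -- derived quantities -------------------------------------------------

    @property
    def n_arms(self) -> int:
        return len(self.arm_names)

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroup_names)

    @property
    def P(self) -> np.ndarray:
        """Mortality matrix as a ``(n_subgroups, n_arms)`` array."""
        return np.asarray(self.mortality, dtype=float)

    @property
    def mix(self) -> np.ndarray:
        return np.asarray(self.subgroup_mix, dtype=float)

    @property
    def total_patients(self) -> int:
        return self.block_size * self.n_blocks

    @property
    def metric_cut_patients(self) -> int:
        """Patient count at which single-point metrics are taken."""
        return int(round(self.metric_cut_fraction * self.total_patients))

    def cohort_rate(self, arm: int) -> float:
        """Mix-weighted marginal mortality rate of one arm."""
        return float(self.mix @ self.P[:, arm])


_SUBGROUPS = ("i", "ii", "iii")
_MIX = (0.24, 0.60, 0.16)

# RECOVERY 28-day mortality by subgroup (rows i, ii, iii) and arm
# (standard care, dexamethasone, hydroxychloroquine, lopinavir).
_RECOVERY_P4 = (
    (0.140, 0.178, 0.160, 0.167),
    (0.262, 0.233, 0.270, 0.247),
    (0.414, 0.293, 0.421, 0.400),
)


def recovery_two_arm() -> Scenario:
    """Two-arm RECOVERY scenario: standard care vs dexamethasone.

    100 blocks of 80 patients (8000 total); single-point metrics at the 80%
    cut, i.e. 6400 patients, matching the sample size at which RECOVERY's
    dexamethasone result was published.
    """
    return Scenario(
        arm_names=("standard care", "dexamethasone"),
        subgroup_names=_SUBGROUPS,
        mortality=tuple(row[:2] for row in _RECOVERY_P4),
        subgroup_mix=_MIX,
        block_size=80,
        n_blocks=100,
        metric_cut_fraction=0.80,
    )


def recovery_four_arm() -> Scenario:
    """Four-arm RECOVERY scenario adding hydroxychloroquine and lopinavir.

    100 blocks of 120 patients (12000 total); metrics at 9600 patients.
    """
    return Scenario(
        arm_names=("standard care", "dexamethasone", "hydroxychloroquine", "lopinavir"),
        subgroup_names=_SUBGROUPS,
        mortality=_RECOVERY_P4,
        subgroup_mix=_MIX,
        block_size=120,
        n_blocks=100,
        metric_cut_fraction=0.80,
    )


def null_variant(scenario: Scenario) -> Scenario:
    """Copy of *scenario* in which every arm inherits the standard-care rate.

    Within each subgroup all arms share ``P[k, 0]``, so there is no true
    treatment effect; used for type-I-error and familywise-error simulation.
    Idempotent; all other fields are unchanged.
    """
    null_rows = tuple(
        tuple(row[0] for _ in row) for row in scenario.mortality
    )
    return dataclasses.replace(scenario, mortality=null_rows)


# -- configuration loading --------------------------------------------------

_REQUIRED_KEYS = ("arms", "subgroups", "mortality", "mix", "block_size", "n_blocks")


def _parse_config(config: str | Mapping[str, Any]) -> Mapping[str, Any]:
    if isinstance(config, str):
        try:
            parsed = yaml.safe_load(config)
        except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
            raise ScenarioConfigError(f"could not parse configuration: {exc}") from exc
    else:
        parsed = config
    if not isinstance(parsed, Mapping):
        raise ScenarioConfigError("configuration must be a mapping")
    return parsed


def load_scenario(config: str | Mapping[str, Any]) -> Scenario:
    """Build a validated :class:`Scenario` from YAML text or a mapping.

    Required keys: ``arms``, ``subgroups``, ``mortality`` (subgroup-major
    matrix), ``mix``, ``block_size``, ``n_blocks``.  Optional:
    ``metric_cut_fraction`` (default 0.80).  A ``schedule`` key, if present,
    is ignored here; see :func:`load_schedule`.
    """
    parsed = _parse_config(config)
    missing = [k for k in _REQUIRED_KEYS if k not in parsed]
    if missing:
        raise ScenarioConfigError(f"missing configuration keys: {', '.join(missing)}")
    return Scenario(
        arm_names=tuple(parsed["arms"]),
        subgroup_names=tuple(parsed["subgroups"]),
        mortality=parsed["mortality"],
        subgroup_mix=parsed["mix"],
        block_size=int(parsed["block_size"]),
        n_blocks=int(parsed["n_blocks"]),
        metric_cut_fraction=float(parsed.get("metric_cut_fraction", 0.80)),
    )


def load_schedule(config: str | Mapping[str, Any]) -> AdaptationSchedule:
    """Read the ``schedule`` block (``burn_in``, ``cadence``, ``lag``) of a
    configuration; absent keys fall back to the RECOVERY defaults."""
    parsed = _parse_config(config)
    block = parsed.get("schedule", {}) or {}
    if not isinstance(block, Mapping):
        raise ScenarioConfigError("schedule: must be a mapping")
    base = default_schedule()
    try:
        return AdaptationSchedule(
            burn_in_blocks=int(block.get("burn_in", base.burn_in_blocks)),
            update_cadence_blocks=int(block.get("cadence", base.update_cadence_blocks)),
            outcome_lag_blocks=int(block.get("lag", base.outcome_lag_blocks)),
        )
    except ValueError as exc:
        raise ScenarioConfigError(f"schedule: {exc}") from exc
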