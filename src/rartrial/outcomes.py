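"""Synthetic patient data: subgroup arrival, arm assignment, 28-day mortality.

All randomness flows through named, seeded streams derived with
:func:`rng_stream`, so that e.g. changing the number of posterior Monte-Carlo
draws never perturbs the patient outcome stream of a replicate.  Every draw
is reproducible from ``(seed, stream labels)``.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np

from .scenario import Scenario

__all__ = [
    "allocate_counts",
    "draw_block_subgroups",
    "draw_cell_deaths",
    "draw_outcome",
    "replicate_seed",
    "rng_stream",
]


def _label_entropy(label: object) -> int:
    """Stable 64-bit integer derived from a stream label (hashlib, not
    ``hash()``, so values survive interpreter restarts)."""
    digest = hashlib.blake2b(repr(label).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little")


def rng_stream(seed: int, *labels: object) -> np.random.Generator:
    """Named random stream: a Generator determined by ``seed`` and labels.

    Identical ``(seed, labels)`` reproduce identical draws; distinct labels
    give statistically independent streams.
    """
    entropy = [int(seed)] + [_label_entropy(lab) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def replicate_seed(base_seed: int, index: int) -> int:
    """Derive the seed of replicate ``index`` from a batch base seed.

    Hash-based so replicate ``i`` is unchanged when the batch grows and
    independent of execution order; kept below 2**31.
    """
    return _label_entropy(("replicate", int(base_seed), int(index))) % (2**31)


def draw_block_subgroups(
    mix: Sequence[float], block_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Subgroup label (integer index) for each patient in one block.

    Each label is drawn independently with probabilities ``mix``; block
    composition is therefore stochastic (24/60/16% of 80 is non-integer, so
    fixed per-block counts would not be well defined).
    """
    p = np.asarray(mix, dtype=float)
    if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("mix must be a probability vector summing to 1")
    if block_size < 1:
        raise ValueError("block_size must be at least 1")
    return rng.choice(len(p), size=block_size, p=p)


def allocate_counts(
    alloc_probs: Sequence[float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Realize arm-assignment counts for ``n`` patients.

    Two arms: a single binomial draw on the experimental-arm probability;
    three or more arms: one multinomial draw.  Sampling (rather than rounding
    ``n * prob``) creates allocation variation between replicates and avoids
    rounding error, matching how a per-patient coin flip behaves in aggregate.
    """
    p = np.asarray(alloc_probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("allocation probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allocation probabilities sum to {p.sum()!r}, expected 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    if len(p) == 2:
        n1 = int(rng.binomial(n, p[1]))
        return np.array([n - n1, n1], dtype=np.int64)
    return rng.multinomial(n, p / p.sum()).astype(np.int64)


def draw_outcome(
    scenario: Scenario, k: int, l: int, rng: np.random.Generator
) -> int:
    """One patient's 28-day death indicator: Bernoulli(P[k, l])."""
    if not (0 <= k < scenario.n_subgroups and 0 <= l < scenario.n_arms):
        raise IndexError("subgroup or arm index out of range")
    return int(rng.random() < scenario.mortality[k][l])


def draw_cell_deaths(
    n_cells: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Death counts per (subgroup, arm) cell for one block.

    A binomial per cell is the aggregate of the per-patient Bernoulli draws;
    one vectorized call covers all cells.
    """
    return rng.binomial(n_cells, P)
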