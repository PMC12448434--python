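"""Counterfactual ANC scenario and stochastic visit redistribution.

The observed visit totals at served facilities embed the intervention effect;
the counterfactual removes it, and the microsimulation re-allocates the
intervention-attributable additional visits one at a time over the baseline
population.  A woman's chance of absorbing the next visit is weighted by the
baseline conditional continuation probability P(visits >= k+1 | visits >= k)
of her current category, which preserves the shape of the baseline
distribution while the mean shifts upward.  Population size and total visits
are conserved exactly in every replicate, and no woman's count ever decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ANCDistribution

__all__ = [
    "ShiftResult",
    "CapacityError",
    "counterfactual_total",
    "additional_visits",
    "infer_population_size",
    "threshold_crossers",
    "simulate_redistribution",
]


class CapacityError(RuntimeError):
    """All women are at the visit cap but additional visits remain."""


@dataclass(frozen=True)
class ShiftResult:
    """Replicate-level outcome of the visit-redistribution microsimulation."""

    baseline: ANCDistribution
    post_counts: np.ndarray  # (n_sims, cap + 1) integer counts per replicate
    crossers_8plus: np.ndarray  # per-replicate counts
    crossers_0to1: np.ndarray
    n_sims: int
    seed: int

    def _summary(self, x: np.ndarray) -> tuple[float, float, float]:
        return float(np.mean(x)), float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5))

    @property
    def crossers_8plus_summary(self) -> tuple[float, float, float]:
        """(mean, 2.5th, 97.5th percentile) of women newly reaching >=8 visits."""
        return self._summary(self.crossers_8plus)

    @property
    def crossers_0to1_summary(self) -> tuple[float, float, float]:
        """(mean, 2.5th, 97.5th percentile) of women moving from 0 to >=1 visits."""
        return self._summary(self.crossers_0to1)

    def post_mean(self) -> np.ndarray:
        return self.post_counts.mean(axis=0)

    def to_table(self):
        """Per-category table: baseline count, post mean and percentile band."""
        import pandas as pd

        lo = np.percentile(self.post_counts, 2.5, axis=0)
        hi = np.percentile(self.post_counts, 97.5, axis=0)
        return pd.DataFrame(
            {
                "category": np.arange(self.baseline.cap + 1),
                "baseline": self.baseline.counts,
                "post_mean": self.post_mean(),
                "post_low": lo,
                "post_high": hi,
            }
        )


def counterfactual_total(observed_visits: float, effect: float) -> float:
    """Visits that would have occurred without the intervention.

    Multiplicative removal of the effect: ``observed * (1 - effect)``.
    """
    if observed_visits < 0:
        raise ValueError("observed_visits must be >= 0")
    if not 0.0 <= effect < 1.0:
        raise ValueError("effect must be in [0, 1)")
    return observed_visits * (1.0 - effect)


def additional_visits(observed_visits: float, effect: float) -> float:
    """Intervention-attributable visits, with the effect read as a relative
    increase over the counterfactual: ``observed * effect / (1 + effect)``."""
    if observed_visits < 0:
        raise ValueError("observed_visits must be >= 0")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    return observed_visits * effect / (1.0 + effect)


def infer_population_size(total_visits: float, category_shares: np.ndarray) -> int:
    """Most likely population size given total visits and category shares."""
    shares = np.asarray(category_shares, dtype=float)
    if abs(shares.sum() - 1.0) > 1e-6:
        raise ValueError("category shares must sum to 1")
    mean = float(np.arange(shares.size) @ shares)
    if mean <= 0:
        raise ZeroDivisionError("mean visits per woman is zero")
    return int(round(total_visits / mean))


def threshold_crossers(before: ANCDistribution, after: ANCDistribution, threshold: int) -> int:
    """Net women newly at or above ``threshold`` visits, floored at 0."""
    if before.n_women != after.n_women:
        raise ValueError("before/after populations differ")
    return max(0, after.n_at_least(threshold) - before.n_at_least(threshold))


def _continuation_probs(baseline: ANCDistribution) -> np.ndarray:
    """Baseline conditional probabilities P(visits >= k+1 | visits >= k)."""
    surv = np.concatenate([np.cumsum(baseline.counts[::-1])[::-1], [0]]).astype(float)
    a = np.zeros(baseline.cap + 1)
    occupied = surv[:-1] > 0
    a[occupied] = surv[1:][occupied] / surv[:-1][occupied]
    a[baseline.cap] = 0.0  # the pooled top category cannot grow
    return a


def _allocate_once(
    counts: np.ndarray, accept: np.ndarray, budget: int, rng: np.random.Generator
) -> np.ndarray:
    """Allocate ``budget`` single-visit increments over category counts.

    Each increment moves one woman from category k to k+1, with k drawn with
    probability proportional to counts[k] * accept[k]; increments are applied
    in capped batches for speed, which leaves the conservation invariants
    exact.  If every acceptance weight vanishes while below-cap women remain
    (the baseline distribution carries no mass beyond the occupied
    categories), visits are granted to the women furthest behind: the lowest
    occupied category is filled first.  If all women sit at the cap, the
    budget cannot be spent and an error is raised.
    """
    counts = counts.astype(np.int64).copy()
    cap = counts.size - 1
    batch_cap = max(1, int(counts.sum()) // 50)
    while budget > 0:
        weights = counts[:-1].astype(float) * accept[:-1]
        if weights.sum() <= 0:
            movable = np.flatnonzero(counts[:-1] > 0)
            if movable.size == 0:
                raise CapacityError("all women are at the visit cap; budget cannot be allocated")
            k0 = int(movable[0])
            moved = min(budget, int(counts[k0]))
            counts[k0] -= moved
            counts[k0 + 1] += moved
            budget -= moved
            continue
        m = min(budget, batch_cap)
        draw = rng.multinomial(m, weights / weights.sum())
        moved = np.minimum(draw, counts[:-1])  # cannot move more women than a category holds
        counts[:-1] -= moved
        counts[1:] += moved
        budget -= int(moved.sum())
        if cap >= 1 and counts[:cap].sum() == 0 and budget > 0:
            raise CapacityError("all women are at the visit cap; budget cannot be allocated")
    return counts


def simulate_redistribution(
    baseline: ANCDistribution,
    additional: int,
    n_sims: int = 1000,
    seed: int = 0,
) -> ShiftResult:
    """Stochastically re-allocate ``additional`` visits over the baseline.

    Runs ``n_sims`` independent replicates (deterministic substreams of the
    master seed) and summarizes the threshold-crosser counts with mean and
    2.5/97.5 percentile intervals.
    """
    if additional < 0:
        raise ValueError("additional visits must be >= 0")
    if n_sims <= 0:
        raise ValueError("n_sims must be positive")
    capacity = baseline.n_women * baseline.cap - baseline.total_visits
    if additional > capacity:
        raise CapacityError(
            f"additional visits ({additional}) exceed remaining capacity ({capacity})"
        )
    accept = _continuation_probs(baseline)
    streams = np.random.SeedSequence(seed).spawn(n_sims)
    post = np.empty((n_sims, baseline.cap + 1), dtype=np.int64)
    c8 = np.empty(n_sims, dtype=np.int64)
    c01 = np.empty(n_sims, dtype=np.int64)
    for r in range(n_sims):
        rng = np.random.default_rng(streams[r])
        counts = _allocate_once(baseline.counts, accept, int(additional), rng)
        post[r] = counts
        after = ANCDistribution(counts=counts)
        c8[r] = threshold_crossers(baseline, after, 8)
        c01[r] = threshold_crossers(baseline, after, 1)
    return ShiftResult(
        baseline=baseline,
        post_counts=post,
        crossers_8plus=c8,
        crossers_0to1=c01,
        n_sims=n_sims,
        seed=seed,
    )
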