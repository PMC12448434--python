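"""Synthetic inputs: ANC visit distributions, flight manifests, truth cohorts.

The real analysis draws its population structure from DHS aggregate tables and
its delivery ledger from a private flight database; neither is distributable.
These generators produce inputs with the same statistical structure so every
downstream stage runs and is testable offline.  All generators are pure
functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "ANCDistribution",
    "ProductRecord",
    "Cohort",
    "generate_anc_distribution",
    "generate_flight_manifest",
    "generate_cohort_truth",
    "write_manifest",
    "read_manifest",
]

CATEGORY_TAGS = ("ANC", "PPH_PREVENTION", "PPH_TREATMENT")


@dataclass(frozen=True)
class ANCDistribution:
    """Counts of women per ANC visit category 0..cap (top category pooled)."""

    counts: np.ndarray  # integer counts, length cap + 1

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a 1-D vector")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def cap(self) -> int:
        return self.counts.size - 1

    @property
    def n_women(self) -> int:
        return int(self.counts.sum())

    @property
    def total_visits(self) -> int:
        return int(np.arange(self.counts.size) @ self.counts)

    @property
    def mean_visits(self) -> float:
        return self.total_visits / self.n_women

    def shares(self) -> np.ndarray:
        return self.counts / self.n_women

    def n_at_least(self, threshold: int) -> int:
        return int(self.counts[threshold:].sum())


@dataclass(frozen=True)
class ProductRecord:
    """One delivered product category in the last-mile-delivery ledger."""

    product_id: str
    category_tags: frozenset[str]
    occupancy_fraction: float  # share of flight payload volume, (0, 1]
    units_delivered: int

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy_fraction <= 1.0:
            raise ValueError("occupancy_fraction must be in (0, 1]")
        if self.units_delivered < 0:
            raise ValueError("units_delivered must be >= 0")
        bad = set(self.category_tags) - set(CATEGORY_TAGS)
        if bad:
            raise ValueError(f"unknown category tags: {sorted(bad)}")


@dataclass(frozen=True)
class Cohort:
    """Individual-level synthetic cohort with known group risks."""

    exposed: np.ndarray  # 0/1 exposure indicator
    outcome: np.ndarray  # 0/1 outcome indicator
    true_risk_exposed: float
    true_risk_unexposed: float

    @property
    def n(self) -> int:
        return self.exposed.size

    @property
    def true_odds_ratio(self) -> float:
        p, q = self.true_risk_exposed, self.true_risk_unexposed
        return (p / (1 - p)) / (q / (1 - q))

    def empirical_odds_ratio(self) -> float:
        e, o = self.exposed.astype(bool), self.outcome.astype(bool)
        a = np.sum(e & o)
        b = np.sum(e & ~o)
        c = np.sum(~e & o)
        d = np.sum(~e & ~o)
        if min(a, b, c, d) == 0:
            raise ZeroDivisionError("empty contingency cell; cohort too small")
        return (a * d) / (b * c)


def _truncated_nbinom_probs(mean_visits: float, dispersion: float, cap: int) -> np.ndarray:
    """Category probabilities of a negative binomial pooled at ``cap``.

    The untruncated mean is raised by root finding so that the pooled-category
    mean matches ``mean_visits`` exactly; pooling the tail into the top
    category would otherwise bias the mean downward.
    """

    ks = np.arange(cap + 1)

    def pooled(mu: float) -> np.ndarray:
        p = dispersion / (dispersion + mu)
        probs = stats.nbinom.pmf(ks, dispersion, p)
        probs[cap] = stats.nbinom.sf(cap - 1, dispersion, p)
        return probs

    def pooled_mean(mu: float) -> float:
        return float(ks @ pooled(mu))

    if mean_visits == 0:
        probs = np.zeros(cap + 1)
        probs[0] = 1.0
        return probs
    hi = float(mean_visits)
    while pooled_mean(hi) < mean_visits:
        hi *= 1.5
        if hi > 100 * cap:
            raise ValueError("mean_visits not reachable under the visit cap")
    mu = brentq(lambda m: pooled_mean(m) - mean_visits, mean_visits * 0.5, hi + 1e-9)
    return pooled(mu)


def generate_anc_distribution(
    n_women: int,
    mean_visits: float,
    dispersion: float = 2.6,
    cap: int = 13,
    seed: int = 0,
) -> ANCDistribution:
    """Draw a right-truncated overdispersed ANC visit distribution.

    Counts are multinomial over categories 0..cap with negative-binomial cell
    probabilities whose pooled mean equals ``mean_visits``; the realized sample
    mean is within sampling error of the target (about +/-2% for n >= 5000).
    """
    if n_women <= 0:
        raise ValueError("n_women must be positive")
    if not 0 <= mean_visits <= cap:
        raise ValueError(f"mean_visits must be in [0, cap={cap}]")
    probs = _truncated_nbinom_probs(mean_visits, dispersion, cap)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_women, probs)
    return ANCDistribution(counts=counts)


def generate_flight_manifest(
    n_products: int,
    share_anc: float = 0.04,
    share_pph_prevention_extra: float = 0.01,
    share_pph_treatment_extra: float = 0.02,
    seed: int = 0,
) -> list[ProductRecord]:
    """Generate a product/flight ledger with nested maternal-health tags.

    Tag sets are nested by construction — every ANC product is also a
    PPH-prevention and a PPH-treatment product, and every PPH-prevention
    product is also a PPH-treatment product — mirroring how prevention bundles
    include all ANC supplies and treatment bundles add blood products.
    """
    for s in (share_anc, share_pph_prevention_extra, share_pph_treatment_extra):
        if not 0.0 <= s <= 1.0:
            raise ValueError("category shares must be in [0, 1]")
    if share_anc + share_pph_prevention_extra + share_pph_treatment_extra > 1.0 + 1e-12:
        raise ValueError("category shares sum to more than 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n_products)
    occupancy = np.clip(rng.beta(2.0, 5.0, n_products), 1e-6, 1.0)
    units = rng.geometric(1.0 / 5000.0, n_products)
    records = []
    t1 = share_anc
    t2 = t1 + share_pph_prevention_extra
    t3 = t2 + share_pph_treatment_extra
    for i in range(n_products):
        if u[i] < t1:
            tags = frozenset(CATEGORY_TAGS)
        elif u[i] < t2:
            tags = frozenset({"PPH_PREVENTION", "PPH_TREATMENT"})
        elif u[i] < t3:
            tags = frozenset({"PPH_TREATMENT"})
            occupancy[i] = 1.0  # blood products fill the payload
        else:
            tags = frozenset()
        records.append(
            ProductRecord(
                product_id=f"P{i:04d}",
                category_tags=tags,
                occupancy_fraction=float(occupancy[i]),
                units_delivered=int(units[i]),
            )
        )
    return records


def generate_cohort_truth(
    n: int,
    risk_exposed: float,
    risk_unexposed: float,
    exposed_share: float,
    seed: int = 0,
) -> Cohort:
    """Simulate per-woman exposure and outcome from known group risks.

    Used as a parameter-recovery fixture for the two-group risk solver: the
    empirical odds ratio of the cohort converges to the true OR implied by the
    group risks as n grows.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    for r in (risk_exposed, risk_unexposed):
        if not 0.0 < r < 1.0:
            raise ValueError("group risks must be in (0, 1)")
    if not 0.0 <= exposed_share <= 1.0:
        raise ValueError("exposed_share must be in [0, 1]")
    rng = np.random.default_rng(seed)
    exposed = (rng.random(n) < exposed_share).astype(np.int8)
    risk = np.where(exposed == 1, risk_exposed, risk_unexposed)
    outcome = (rng.random(n) < risk).astype(np.int8)
    return Cohort(
        exposed=exposed,
        outcome=outcome,
        true_risk_exposed=risk_exposed,
        true_risk_unexposed=risk_unexposed,
    )


# ---------------------------------------------------------------------- I/O
def write_manifest(records: list[ProductRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("product_id\ttags\toccupancy_fraction\tunits_delivered\n")
        for r in records:
            tags = "|".join(sorted(r.category_tags))
            fh.write(f"{r.product_id}\t{tags}\t{r.occupancy_fraction!r}\t{r.units_delivered}\n")


def read_manifest(path: str) -> list[ProductRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("product_id"):
            raise ValueError("not a manifest file")
        for line in fh:
            pid, tags, occ, units = line.rstrip("\n").split("\t")
            records.append(
                ProductRecord(
                    product_id=pid,
                    category_tags=frozenset(t for t in tags.split("|") if t),
                    occupancy_fraction=float(occ),
                    units_delivered=int(units),
                )
            )
    return records
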