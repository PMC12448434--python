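"""Life-years saved and discounted DALYs from averted deaths.

Mortality-only burden: each averted death contributes its remaining life
expectancy at the age of death, undiscounted for LYS and as a discounted
stream for DALYs.  Discrete annual discounting is the default — one life year
received at the end of each year, so L years at rate r are worth
(1 - (1+r)^-L) / r — with a continuous-exponential form selectable.  No age
weighting is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .outcomes import DeathsAverted

__all__ = ["DALYResult", "discounted_years", "aggregate_dalys"]


@dataclass(frozen=True)
class DALYResult:
    lys_undiscounted: float
    dalys_discounted: float
    discount_rate: float
    by_cause: dict[str, tuple[float, float]] = field(default_factory=dict)  # cause -> (lys, dalys)

    def __post_init__(self) -> None:
        if self.discount_rate > 0 and self.dalys_discounted > self.lys_undiscounted * (1 + 1e-12) + 1e-9:
            raise ValueError("discounted DALYs cannot exceed undiscounted LYS")
        for total, idx in ((self.lys_undiscounted, 0), (self.dalys_discounted, 1)):
            s = sum(v[idx] for v in self.by_cause.values())
            if self.by_cause and abs(s - total) > 1e-6 * max(1.0, total):
                raise ValueError("per-cause breakdown does not sum to the total")


def discounted_years(remaining_life_expectancy: float, rate: float, *, form: str = "annual") -> float:
    """Present value of one life year per year over the remaining expectancy.

    ``form='annual'`` uses the discrete annuity (1 - (1+r)^-L)/r; ``form=
    'continuous'`` uses (1 - e^(-rL))/r.  Both reduce to L at rate 0, and the
    value is continuous in the rate at that limit.
    """
    L = remaining_life_expectancy
    if L < 0:
        raise ValueError("life expectancy must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return L
    # expm1/log1p keep the small-rate limit accurate
    if form == "annual":
        return -math.expm1(-L * math.log1p(rate)) / rate
    if form == "continuous":
        return -math.expm1(-rate * L) / rate
    raise ValueError(f"unknown discounting form {form!r}")


def aggregate_dalys(
    deaths: list[DeathsAverted],
    life_expectancy_at_age: dict[float, float],
    rate: float,
    *,
    form: str = "annual",
) -> DALYResult:
    """Sum LYS and discounted DALYs over averted deaths.

    ``life_expectancy_at_age`` maps age at death (years) to remaining life
    expectancy; every death's age must have an entry.
    """
    by_cause: dict[str, tuple[float, float]] = {}
    lys = dalys = 0.0
    for d in deaths:
        if d.age_at_death not in life_expectancy_at_age:
            raise KeyError(f"no life-expectancy entry for age {d.age_at_death}")
        le = life_expectancy_at_age[d.age_at_death]
        c_lys = d.count * le
        c_dalys = d.count * discounted_years(le, rate, form=form)
        prev = by_cause.get(d.cause, (0.0, 0.0))
        by_cause[d.cause] = (prev[0] + c_lys, prev[1] + c_dalys)
        lys += c_lys
        dalys += c_dalys
    return DALYResult(
        lys_undiscounted=lys, dalys_discounted=dalys, discount_rate=rate, by_cause=by_cause
    )
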