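"""Health outcome pathways: LBW, PPH, facility-delivery mortality, sepsis.

Two reconstruction routes convert a published odds ratio plus an overall
incidence into group-specific risks:

* :func:`solve_two_group_risks` — the exact mixture solve: find the unique
  pair (risk_exposed, risk_unexposed) in (0,1) satisfying both the odds-ratio
  equation and the population mixture equation.  Reduces to a quadratic in the
  unexposed risk.
* :func:`odds_shift_prevalence` — the odds-multiplication approximation:
  multiply the overall odds by the OR and convert back to a prevalence.  This
  ignores the mixture weighting but is the convention behind the published
  LBW chain, so it is the default on that pathway.

Averted deaths come from three mechanisms: a relative risk applied to births
shifted into facilities, severity-specific hazard ratios applied to averted
LBW cases, and a counterfactual reconstruction of observed maternal deaths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "RiskPair",
    "OutcomeImpact",
    "DeathsAverted",
    "solve_two_group_risks",
    "odds_shift_prevalence",
    "lbw_reduction",
    "split_severity",
    "facility_delivery_deaths_averted",
    "lbw_mortality_averted",
    "maternal_counterfactual",
    "sepsis_reduction",
    "pph_reduction",
]

LBW_SEVERITIES = ("moderate", "very", "extreme")
LBW_PERIODS = ("neonatal", "early_infancy", "late_infancy")


def _odds(p: float) -> float:
    return p / (1.0 - p)


@dataclass(frozen=True)
class RiskPair:
    """Group-specific risks consistent with an effect measure and a mixture."""

    risk_exposed: float
    risk_unexposed: float
    measure: str  # "odds_ratio" or "relative_risk"
    measure_value: float
    exposed_share: float

    def __post_init__(self) -> None:
        for r in (self.risk_exposed, self.risk_unexposed):
            if not 0.0 < r < 1.0:
                raise ValueError("risks must be in (0, 1)")
        if self.measure == "odds_ratio":
            implied = _odds(self.risk_exposed) / _odds(self.risk_unexposed)
        elif self.measure == "relative_risk":
            implied = self.risk_exposed / self.risk_unexposed
        else:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not math.isclose(implied, self.measure_value, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"risks imply {self.measure} {implied:.12g}, stated {self.measure_value:.12g}"
            )

    @property
    def overall(self) -> float:
        s = self.exposed_share
        return s * self.risk_exposed + (1.0 - s) * self.risk_unexposed

    @property
    def risk_difference(self) -> float:
        return self.risk_exposed - self.risk_unexposed


@dataclass(frozen=True)
class OutcomeImpact:
    """Averted cases of one condition, optionally split by severity."""

    condition: str  # LBW | PPH | NEONATAL_DEATH_FACILITY | EONS
    cases_averted: float
    severity_split: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cases_averted < 0:
            raise ValueError("cases_averted must be >= 0")
        if self.severity_split:
            total = sum(self.severity_split.values())
            if abs(total - self.cases_averted) > 1e-6 * max(1.0, self.cases_averted):
                raise ValueError("severity split does not sum to cases_averted")


@dataclass(frozen=True)
class DeathsAverted:
    """Averted deaths of one cause, with the age at death used for discounting."""

    cause: str  # MATERNAL | NEONATAL_FACILITY | LBW_NEONATAL | LBW_EARLY_INFANCY | LBW_LATE_INFANCY
    count: float
    age_at_death: float  # years; 0 for infant strata

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("averted deaths must be >= 0")


def solve_two_group_risks(
    overall_incidence: float,
    exposed_share: float,
    odds_ratio: float,
) -> RiskPair:
    """Reconstruct group risks from an overall incidence, a group share and an OR.

    Solves the system
        share * p + (1 - share) * q = overall
        odds(p) = OR * odds(q)
    exactly: substituting p = OR*q / (1 + (OR-1)*q) yields a quadratic in q
    whose unique root in (0, 1) is selected.
    """
    if not 0.0 < overall_incidence < 1.0:
        raise ValueError("overall_incidence must be in (0, 1)")
    if not 0.0 < exposed_share < 1.0:
        raise ValueError("exposed_share must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    s, m, k = exposed_share, overall_incidence, odds_ratio
    if abs(k - 1.0) < 1e-12:
        q = m
    else:
        # s*k*q/(1+(k-1)q) + (1-s)q = m  =>  a q^2 + b q + c = 0
        a = (k - 1.0) * (1.0 - s)
        b = s * k + (1.0 - s) - m * (k - 1.0)
        c = -m
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("inconsistent inputs: no real root")
        # numerically stable root pair (avoids cancellation as k -> 1)
        t = -0.5 * (b + math.copysign(math.sqrt(disc), b))
        roots = [t / a, c / t]
        valid = [r for r in roots if 0.0 < r < 1.0]
        if not valid:
            raise ValueError("inconsistent inputs: no risk root in (0, 1)")
        q = min(valid)  # the mixture function is monotone: a single admissible root
    p = k * q / (1.0 + (k - 1.0) * q)
    return RiskPair(
        risk_exposed=p,
        risk_unexposed=q,
        measure="odds_ratio",
        measure_value=k,
        exposed_share=s,
    )


def odds_shift_prevalence(overall_prevalence: float, odds_ratio: float) -> float:
    """Prevalence whose odds equal the overall odds multiplied by the OR."""
    if not 0.0 < overall_prevalence < 1.0:
        raise ValueError("overall_prevalence must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    shifted = _odds(overall_prevalence) * odds_ratio
    return shifted / (1.0 + shifted)


def split_severity(total: float, shares: dict[str, float]) -> dict[str, float]:
    """Allocate a case total over severity labels; shares are renormalized so
    the labelled counts sum to the total exactly."""
    if total < 0:
        raise ValueError("total must be >= 0")
    if any(v < 0 for v in shares.values()):
        raise ValueError("shares must be non-negative")
    norm = sum(shares.values())
    if abs(norm - 1.0) > 0.01:
        raise ValueError(f"shares sum to {norm:.4f}, expected 1 +/- 0.01")
    return {label: total * share / norm for label, share in shares.items()}


def lbw_reduction(
    movers_8plus: float,
    prev_below: float,
    prev_above: float,
    severity_shares: dict[str, float] | None = None,
) -> OutcomeImpact:
    """Averted LBW cases from women newly reaching >=8 ANC visits."""
    if movers_8plus < 0:
        raise ValueError("movers must be >= 0")
    if prev_below < prev_above:
        raise ValueError("prevalence below threshold must be >= prevalence above")
    cases = movers_8plus * (prev_below - prev_above)
    split = split_severity(cases, severity_shares) if severity_shares else {}
    return OutcomeImpact(condition="LBW", cases_averted=cases, severity_split=split)


def facility_delivery_deaths_averted(
    additional_births: float,
    baseline_nmr_per_1000: float,
    rr: float,
    override: bool = False,
) -> DeathsAverted:
    """Neonatal deaths averted by births shifted from home to facility.

    deaths = births * (NMR / 1000) * (1 - RR).
    """
    if additional_births < 0 or baseline_nmr_per_1000 < 0:
        raise ValueError("births and mortality rate must be >= 0")
    if rr <= 0:
        raise ValueError("rr must be > 0")
    if rr > 1.0 and not override:
        raise ValueError("rr > 1 contradicts the protective assumption (pass override=True to force)")
    count = additional_births * (baseline_nmr_per_1000 / 1000.0) * (1.0 - rr)
    return DeathsAverted(cause="NEONATAL_FACILITY", count=max(count, 0.0), age_at_death=0.0)


def lbw_mortality_averted(
    cases_by_severity: dict[str, float],
    hazard_ratios: dict[str, dict[str, float]],
    reference_rates: dict[str, float],
) -> list[DeathsAverted]:
    """Deaths averted by the LBW reduction, per mortality period.

    For severity s and period p: deaths = cases_s * rate_p * (HR_{s,p} - 1),
    the excess-mortality contribution of LBW relative to the reference group.
    """
    out = []
    for period in LBW_PERIODS:
        if period not in reference_rates:
            raise KeyError(f"missing reference rate for period {period!r}")
        rate = reference_rates[period]
        if not 0.0 < rate < 1.0:
            raise ValueError("reference rates must be in (0, 1)")
        total = 0.0
        for severity, cases in cases_by_severity.items():
            try:
                hr = hazard_ratios[severity][period]
            except KeyError:
                raise KeyError(f"missing hazard ratio for ({severity}, {period})")
            if hr < 1.0:
                raise ValueError("LBW hazard ratios must be >= 1")
            total += cases * rate * (hr - 1.0)
        out.append(DeathsAverted(cause=f"LBW_{period.upper()}", count=total, age_at_death=0.0))
    return out


def maternal_counterfactual(observed_deaths: float, reduction: float) -> tuple[float, float]:
    """Counterfactual maternal deaths and deaths averted.

    The observed count already reflects the intervention, so the
    counterfactual is observed / (1 - reduction).
    """
    if observed_deaths < 0:
        raise ValueError("observed deaths must be >= 0")
    if not 0.0 <= reduction < 1.0:
        raise ValueError("reduction must be in [0, 1)")
    counterfactual = observed_deaths / (1.0 - reduction)
    return counterfactual, counterfactual - observed_deaths


def sepsis_reduction(shifted_births: float, risk_pair: RiskPair) -> OutcomeImpact:
    """Averted early-onset sepsis cases from births shifted into facilities.

    ``risk_exposed`` is the home-delivery risk, ``risk_unexposed`` the
    facility risk.
    """
    if shifted_births < 0:
        raise ValueError("shifted_births must be >= 0")
    if risk_pair.risk_exposed <= risk_pair.risk_unexposed:
        raise ValueError("home risk must exceed facility risk")
    cases = shifted_births * risk_pair.risk_difference
    return OutcomeImpact(condition="EONS", cases_averted=cases)


def pph_reduction(
    women_moved_from_zero: float,
    risk_pair: RiskPair,
    severe_share: float | None = None,
) -> OutcomeImpact:
    """Averted PPH cases from women gaining a first ANC contact.

    ``risk_exposed`` is the 0-visit risk, ``risk_unexposed`` the >=1-visit
    risk; optionally split into mild/severe.
    """
    if women_moved_from_zero < 0:
        raise ValueError("movers must be >= 0")
    if risk_pair.risk_exposed <= risk_pair.risk_unexposed:
        raise ValueError("0-ANC risk must exceed >=1-ANC risk")
    cases = women_moved_from_zero * risk_pair.risk_difference
    split = {}
    if severe_share is not None:
        split = split_severity(cases, {"mild": 1.0 - severe_share, "severe": severe_share})
    return OutcomeImpact(condition="PPH", cases_averted=cases, severity_split=split)
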