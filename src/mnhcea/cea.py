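"""Net costs per perspective and incremental cost-effectiveness ratios.

The government (health-system) perspective nets NHIS and program flows; the
societal perspective adds household flows.  Denominator conventions for the
service-utilization ICERs follow the published ratios: the ANC-user and
ANC-visit ratios use the ANC-product LMD cost alone, the facility-birth ratio
uses ANC+PPH-prevention LMD plus the incremental NHIS ANC cost, and the
death/LYS/DALY ratios use the full perspective net cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .costing import CostLine

__all__ = ["ICERSet", "net_cost", "icer", "compute_all_icers"]

PERSPECTIVES = ("GOVERNMENT", "SOCIETAL")


@dataclass(frozen=True)
class ICERSet:
    per_anc_user: float
    per_anc_visit: float
    per_facility_birth: float
    per_death_averted: float
    per_lys: float
    per_daly_gov: float
    per_daly_societal: float
    net_cost_gov: float
    net_cost_societal: float

    def as_dict(self) -> dict[str, float]:
        return {
            "per_anc_user": self.per_anc_user,
            "per_anc_visit": self.per_anc_visit,
            "per_facility_birth": self.per_facility_birth,
            "per_death_averted": self.per_death_averted,
            "per_lys": self.per_lys,
            "per_daly_gov": self.per_daly_gov,
            "per_daly_societal": self.per_daly_societal,
            "net_cost_gov": self.net_cost_gov,
            "net_cost_societal": self.net_cost_societal,
        }


def net_cost(ledger: list[CostLine], perspective: str) -> float:
    """Signed net cost of the ledger from one perspective.

    GOVERNMENT: NHIS + PROGRAM incurred minus NHIS averted.
    SOCIETAL: government plus HOUSEHOLD incurred minus HOUSEHOLD averted.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    payers = {"NHIS", "PROGRAM"} if perspective == "GOVERNMENT" else {"NHIS", "PROGRAM", "HOUSEHOLD"}
    total = 0.0
    for line in ledger:
        if line.payer not in payers:
            continue
        total += line.amount if line.direction == "INCURRED" else -line.amount
    return total


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost per unit of incremental effect."""
    if delta_effect < 0:
        raise ValueError("delta_effect must be positive")
    if math.isclose(delta_effect, 0.0, abs_tol=1e-12):
        if math.isclose(delta_cost, 0.0, abs_tol=1e-12):
            raise ValueError("0/0 ICER is undefined")
        return math.inf
    return delta_cost / delta_effect


def compute_all_icers(
    ledger: list[CostLine],
    effects: dict[str, float],
    lmd_cost_anc: float,
    lmd_cost_anc_pph_prevention: float,
    incremental_anc_cost: float,
) -> ICERSet:
    """Populate the full ICER set from a ledger and effect denominators.

    ``effects`` must contain anc_users, anc_visits, facility_births,
    deaths_averted, lys and dalys, all positive.
    """
    required = ("anc_users", "anc_visits", "facility_births", "deaths_averted", "lys", "dalys")
    missing = [k for k in required if k not in effects]
    if missing:
        raise KeyError(f"missing effect denominators: {missing}")
    for k in required:
        if effects[k] <= 0:
            raise ValueError(f"effect {k!r} must be > 0")
    gov = net_cost(ledger, "GOVERNMENT")
    soc = net_cost(ledger, "SOCIETAL")
    return ICERSet(
        per_anc_user=icer(lmd_cost_anc, effects["anc_users"]),
        per_anc_visit=icer(lmd_cost_anc, effects["anc_visits"]),
        per_facility_birth=icer(
            lmd_cost_anc_pph_prevention + incremental_anc_cost, effects["facility_births"]
        ),
        per_death_averted=icer(gov, effects["deaths_averted"]),
        per_lys=icer(gov, effects["lys"]),
        per_daly_gov=icer(gov, effects["dalys"]),
        per_daly_societal=icer(soc, effects["dalys"]),
        net_cost_gov=gov,
        net_cost_societal=soc,
    )
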