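"""Cost ledger: averted treatment costs, service-demand costs, OOP, LMD.

Every monetary flow is a signed, payer-tagged :class:`CostLine`; any
perspective's net cost is assembled from the ledger at aggregation time
(incurred minus averted over the payers the perspective includes).  Aerial
last-mile-delivery (LMD) cost is allocated to products by flight occupancy and
aggregated over the nested intervention categories ANC ⊆ ANC+PPH-prevention ⊆
ANC+PPH-prevention&treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .synthetic import ProductRecord

__all__ = [
    "CostLine",
    "LMDCosting",
    "averted_pph_costs",
    "averted_lbw_costs",
    "averted_sepsis_costs",
    "service_demand_costs",
    "lmd_costing",
    "build_ledger",
]

PAYERS = ("NHIS", "HOUSEHOLD", "PROGRAM")
DIRECTIONS = ("INCURRED", "AVERTED")


@dataclass(frozen=True)
class CostLine:
    label: str
    payer: str
    direction: str
    amount: float  # 2024 USD, always >= 0; the direction carries the sign

    def __post_init__(self) -> None:
        if self.payer not in PAYERS:
            raise ValueError(f"unknown payer {self.payer!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.amount < 0:
            raise ValueError("amount must be >= 0; use direction AVERTED for savings")


@dataclass(frozen=True)
class LMDCosting:
    cost_per_flight: float
    per_product_cost: dict[str, float]  # product_id -> total LMD cost
    category_totals: dict[str, float]  # nested category -> USD

    def __post_init__(self) -> None:
        anc = self.category_totals.get("ANC", 0.0)
        prev = self.category_totals.get("ANC_PPH_PREVENTION", 0.0)
        treat = self.category_totals.get("ANC_PPH_PREVENTION_TREATMENT", 0.0)
        if not anc <= prev + 1e-9 or not prev <= treat + 1e-9:
            raise ValueError("LMD category totals must be non-decreasing along the nesting")


def averted_pph_costs(
    mild_cases: float,
    severe_cases: float,
    nhis_mild: float,
    nhis_severe: float,
    oop_mild: float,
    oop_severe: float,
) -> list[CostLine]:
    """NHIS and household costs averted by the PPH reduction."""
    if mild_cases < 0 or severe_cases < 0:
        raise ValueError("case counts must be >= 0")
    return [
        CostLine("Averted NHIS cost of PPH treatment", "NHIS", "AVERTED",
                 mild_cases * nhis_mild + severe_cases * nhis_severe),
        CostLine("Averted OOP cost of PPH treatment", "HOUSEHOLD", "AVERTED",
                 mild_cases * oop_mild + severe_cases * oop_severe),
    ]


def averted_lbw_costs(
    cases: dict[str, float],
    hosp_rate_elbw: float,
    hosp_rate_lbw_vlbw: float,
    hospital_cost: float,
    nonmedical_household: float,
    medical_oop: float,
) -> list[CostLine]:
    """Immediate-care costs averted by the LBW reduction.

    All extremely-LBW infants are hospitalized; moderate and very LBW share a
    joint hospitalization rate.  Household lines cover caretaker medical OOP
    and non-medical (transport, wages) costs per hospitalized case.
    """
    for key in ("moderate", "very", "extreme"):
        if key not in cases:
            raise KeyError(f"missing LBW severity category {key!r}")
    for r in (hosp_rate_elbw, hosp_rate_lbw_vlbw):
        if not 0.0 <= r <= 1.0:
            raise ValueError("hospitalization rates must be in [0, 1]")
    hospitalized = cases["extreme"] * hosp_rate_elbw + (
        cases["moderate"] + cases["very"]
    ) * hosp_rate_lbw_vlbw
    return [
        CostLine("Averted hospital cost of LBW care", "NHIS", "AVERTED",
                 hospitalized * hospital_cost),
        CostLine("Averted nonmedical household cost of LBW care", "HOUSEHOLD", "AVERTED",
                 hospitalized * nonmedical_household),
        CostLine("Averted medical OOP cost of LBW care", "HOUSEHOLD", "AVERTED",
                 hospitalized * medical_oop),
    ]


def averted_sepsis_costs(cases: float, system_cost: float, household_cost: float) -> list[CostLine]:
    """Health-system and household costs averted by the sepsis reduction."""
    if cases < 0:
        raise ValueError("case count must be >= 0")
    return [
        CostLine("Averted health system cost of neonatal sepsis", "NHIS", "AVERTED",
                 cases * system_cost),
        CostLine("Averted household cost of neonatal sepsis", "HOUSEHOLD", "AVERTED",
                 cases * household_cost),
    ]


def service_demand_costs(
    additional_visits: float,
    additional_births: float,
    tariff_anc: float,
    tariff_vaginal: float,
    tariff_csection: float,
    oop_anc: float,
    oop_vaginal: float,
    oop_csection: float,
    vaginal_share: float,
) -> list[CostLine]:
    """Incremental service-demand costs of additional ANC visits and births.

    NHIS reimburses at G-DRG tariffs; households pay the OOP analogues.  The
    per-birth cost is the vaginal/C-section tariff weighted by the vaginal
    share.
    """
    if not 0.0 <= vaginal_share <= 1.0:
        raise ValueError("vaginal_share must be in [0, 1]")
    if additional_visits < 0 or additional_births < 0:
        raise ValueError("service counts must be >= 0")
    nhis_birth = vaginal_share * tariff_vaginal + (1.0 - vaginal_share) * tariff_csection
    oop_birth = vaginal_share * oop_vaginal + (1.0 - vaginal_share) * oop_csection
    return [
        CostLine("Incremental NHIS cost of ANC visits", "NHIS", "INCURRED",
                 additional_visits * tariff_anc),
        CostLine("Incremental NHIS cost of facility births", "NHIS", "INCURRED",
                 additional_births * nhis_birth),
        CostLine("Incremental OOP cost of ANC visits", "HOUSEHOLD", "INCURRED",
                 additional_visits * oop_anc),
        CostLine("Incremental OOP cost of facility births", "HOUSEHOLD", "INCURRED",
                 additional_births * oop_birth),
    ]


def lmd_costing(
    manifest: list[ProductRecord],
    monthly_opex_plus_depreciation: float,
    flights: int,
    n_months: int = 24,
) -> LMDCosting:
    """Allocate distribution-center cost to products by flight occupancy.

    cost/flight = total cost / flights; a product's per-unit LMD cost is its
    average occupancy fraction times the cost per flight, and its total is
    per-unit cost times units delivered.  Category totals aggregate product
    totals over the nested maternal-health tags.
    """
    if not manifest:
        raise ValueError("manifest is empty")
    if flights <= 0:
        raise ValueError("flights must be > 0")
    cost_per_flight = monthly_opex_plus_depreciation * n_months / flights
    per_product = {
        r.product_id: r.occupancy_fraction * cost_per_flight * r.units_delivered
        for r in manifest
    }
    totals = {"ANC": 0.0, "ANC_PPH_PREVENTION": 0.0, "ANC_PPH_PREVENTION_TREATMENT": 0.0}
    for r in manifest:
        if "ANC" in r.category_tags:
            totals["ANC"] += per_product[r.product_id]
        if "PPH_PREVENTION" in r.category_tags:
            totals["ANC_PPH_PREVENTION"] += per_product[r.product_id]
        if "PPH_TREATMENT" in r.category_tags:
            totals["ANC_PPH_PREVENTION_TREATMENT"] += per_product[r.product_id]
    return LMDCosting(
        cost_per_flight=cost_per_flight,
        per_product_cost=per_product,
        category_totals=totals,
    )


def build_ledger(*components: list[CostLine] | CostLine) -> list[CostLine]:
    """Assemble cost lines into a single ledger; duplicate labels rejected."""
    ledger: list[CostLine] = []
    seen: set[str] = set()
    for comp in components:
        lines = [comp] if isinstance(comp, CostLine) else list(comp)
        for line in lines:
            if line.label in seen:
                raise ValueError(f"duplicate ledger label {line.label!r}")
            seen.add(line.label)
            ledger.append(line)
    return ledger
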