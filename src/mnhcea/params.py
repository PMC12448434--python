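"""Model parameters: registry, validation, config I/O.

Every scalar input of the cost-effectiveness model is a named parameter with a
default (the base-case value), hard validation bounds, an optional sensitivity
range (used by the tornado and the PSA), an optional sampling-distribution tag,
and a provenance label.  Defaults labelled ``calibrated`` are quantities whose
primary sources are not public (life tables, severity-specific hazard ratios,
the flight ledger); they are solved once so that the deterministic base case
reproduces the published totals, and they are documented in the methods note.

All monetary values are 2024 US dollars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterator

import yaml

__all__ = ["ParamSpec", "ParameterSet", "ParameterError", "load_parameters", "PARAM_SPECS"]


class ParameterError(ValueError):
    """Raised for unknown parameter names or out-of-range values."""


# kind -> (hard lower bound, hard upper bound, lower inclusive?, upper inclusive?)
_KIND_BOUNDS = {
    "fraction": (0.0, 1.0, True, True),
    "ratio": (0.0, math.inf, False, False),
    "usd": (0.0, math.inf, True, False),
    "count": (0.0, math.inf, True, False),
    "rate": (0.0, math.inf, True, False),
    "real": (-math.inf, math.inf, False, False),
}


@dataclass(frozen=True)
class ParamSpec:
    name: str
    default: float
    kind: str
    doc: str = ""
    provenance: str = "published-default"
    sa_range: tuple[float, float] | None = None  # (low, high) for sensitivity analysis
    dist: str | None = None  # beta | gamma | lognormal | uniform

    def validate(self, value: float) -> float:
        try:
            value = float(value)
        except (TypeError, ValueError):
            raise ParameterError(f"{self.name}: value {value!r} is not numeric")
        lo, hi, lo_inc, hi_inc = _KIND_BOUNDS[self.kind]
        ok = (value >= lo if lo_inc else value > lo) and (value <= hi if hi_inc else value < hi)
        if not math.isfinite(value) or not ok:
            lo_b = "[" if lo_inc else "("
            hi_b = "]" if hi_inc else ")"
            raise ParameterError(
                f"{self.name}: value {value} outside {self.kind} bounds {lo_b}{lo}, {hi}{hi_b}"
            )
        return value


def _pct(base: float, frac: float = 0.25) -> tuple[float, float]:
    return (base * (1.0 - frac), base * (1.0 + frac))


PARAM_SPECS: tuple[ParamSpec, ...] = (
    # ------------------------------------------------------------------ cohort & effects
    ParamSpec("n_women", 11249, "count", "Pregnant women in the aggregated 2021-2022 target population"),
    ParamSpec("observed_anc_visits_2021", 44384, "count", "ANC visits observed at served facilities, 2021"),
    ParamSpec("observed_anc_visits_2022", 42095, "count", "ANC visits observed at served facilities, 2022"),
    ParamSpec("anc_effect", 0.199, "fraction", "Relative increase in ANC visits attributable to aerial logistics",
              sa_range=_pct(0.199), dist="beta"),
    ParamSpec("facility_delivery_effect", 0.25, "fraction", "Relative increase in facility-based deliveries"),
    ParamSpec("maternal_mortality_reduction", 0.564, "fraction",
              "Observed relative reduction in maternal mortality", sa_range=_pct(0.564), dist="beta"),
    ParamSpec("maternal_deaths_observed", 28, "count", "Maternal deaths observed 2021-2022 at served facilities"),
    ParamSpec("additional_facility_births", 14619.63, "count",
              "Additional births at health facilities due to the intervention",
              sa_range=_pct(14619.63, 0.10), dist="gamma"),
    ParamSpec("movers_8plus", 2252.0, "count",
              "Women newly reaching >=8 ANC visits (microsimulation point estimate)",
              sa_range=_pct(2252.0, 0.10), dist="gamma"),
    ParamSpec("movers_0to1", 363.56, "count",
              "Women moving from 0 ANC visits to >=1 (microsimulation point estimate)",
              sa_range=_pct(363.56, 0.10), dist="gamma"),
    ParamSpec("anc_visit_cap", 13, "count", "Top (pooled) ANC visit category"),
    ParamSpec("anc_dispersion", 2.6, "ratio",
              "Negative-binomial size parameter of the synthetic ANC visit distribution",
              provenance="calibrated"),
    ParamSpec("baseline_zero_anc_share", 0.0363, "fraction",
              "Baseline share of women with 0 ANC visits", provenance="calibrated"),
    ParamSpec("baseline_share_8plus", 0.3389, "fraction",
              "Baseline share of women with >=8 ANC visits", provenance="calibrated"),
    # ------------------------------------------------------------------ LBW pathway
    ParamSpec("lbw_prevalence", 0.1073, "fraction", "Overall LBW prevalence (DHS 2023)",
              sa_range=_pct(0.1073), dist="beta"),
    ParamSpec("lbw_or_8plus", 0.24, "ratio", "Odds ratio of LBW for >=8 ANC visits vs fewer",
              sa_range=_pct(0.24), dist="lognormal"),
    ParamSpec("lbw_share_moderate", 0.7777, "fraction", "Share of LBW cases 2.00-2.49 kg"),
    ParamSpec("lbw_share_very", 0.1416, "fraction", "Share of LBW cases 1.50-1.99 kg"),
    ParamSpec("lbw_share_extreme", 0.0807, "fraction", "Share of LBW cases <1.50 kg"),
    ParamSpec("ref_rate_neonatal", 0.007453, "fraction", "Reference-group neonatal mortality rate"),
    ParamSpec("ref_rate_early_infancy", 0.008182, "fraction", "Reference-group early-infancy mortality rate"),
    ParamSpec("ref_rate_late_infancy", 0.006936, "fraction", "Reference-group late-infancy mortality rate"),
    ParamSpec("hr_moderate_neonatal", 4.0, "ratio", "Mortality HR, moderate LBW, neonatal period",
              provenance="calibrated"),
    ParamSpec("hr_moderate_early_infancy", 2.2, "ratio", "Mortality HR, moderate LBW, early infancy",
              provenance="calibrated"),
    ParamSpec("hr_moderate_late_infancy", 1.6, "ratio", "Mortality HR, moderate LBW, late infancy",
              provenance="calibrated"),
    ParamSpec("hr_very_neonatal", 10.0, "ratio", "Mortality HR, very LBW, neonatal period",
              provenance="calibrated"),
    ParamSpec("hr_very_early_infancy", 4.5, "ratio", "Mortality HR, very LBW, early infancy",
              provenance="calibrated"),
    ParamSpec("hr_very_late_infancy", 2.8, "ratio", "Mortality HR, very LBW, late infancy",
              provenance="calibrated"),
    ParamSpec("hr_extreme_neonatal", 49.4463, "ratio",
              "Mortality HR, extremely LBW, neonatal period (solved so total LBW deaths = 22.20)",
              provenance="calibrated"),
    ParamSpec("hr_extreme_early_infancy", 12.0, "ratio", "Mortality HR, extremely LBW, early infancy",
              provenance="calibrated"),
    ParamSpec("hr_extreme_late_infancy", 5.0, "ratio", "Mortality HR, extremely LBW, late infancy",
              provenance="calibrated"),
    # ------------------------------------------------------------------ PPH pathway
    ParamSpec("pph_incidence", 0.199, "fraction", "PPH incidence among all deliveries",
              sa_range=_pct(0.199), dist="beta"),
    ParamSpec("severe_pph_share", 0.2482, "fraction", "Share of PPH cases that are severe",
              sa_range=_pct(0.2482), dist="beta"),
    ParamSpec("pph_or_zero_anc", 3.43, "ratio", "Odds ratio of PPH for 0 ANC visits vs >=1",
              sa_range=_pct(3.43), dist="lognormal"),
    # ------------------------------------------------------------------ facility delivery / sepsis
    ParamSpec("rr_facility_neonatal_mortality", 0.71, "ratio",
              "Relative risk of neonatal mortality, facility vs home delivery",
              sa_range=(0.54, 0.87), dist="lognormal"),
    ParamSpec("baseline_nmr", 17.0, "rate", "Baseline neonatal mortality rate per 1000 live births",
              sa_range=_pct(17.0), dist="gamma"),
    ParamSpec("sepsis_incidence_eons", 0.01412, "fraction",
              "Early-onset neonatal sepsis incidence per live birth",
              sa_range=(0.00946, 0.02097), dist="beta"),
    ParamSpec("sepsis_or_home", 3.6, "ratio", "Odds ratio of neonatal sepsis, home vs facility birth",
              sa_range=(1.83, 7.05), dist="lognormal"),
    ParamSpec("facility_birth_share", 0.86, "fraction", "Share of births in health facilities"),
    ParamSpec("home_birth_share", 0.13, "fraction", "Share of births at home"),
    ParamSpec("sepsis_cases_averted", 278.2713, "count",
              "Averted EONS cases (back-solved from the published savings)",
              provenance="calibrated", sa_range=_pct(278.2713), dist="gamma"),
    # ------------------------------------------------------------------ DALY inputs
    ParamSpec("discount_rate", 0.03, "fraction", "Annual discount rate applied to life years",
              sa_range=(0.03, 0.05), dist="uniform"),
    ParamSpec("life_expectancy_at_birth", 62.5, "real",
              "Remaining life expectancy at age 0 (years)", provenance="calibrated"),
    ParamSpec("maternal_age_at_death", 30.0, "real", "Mean maternal age at death (years)"),
    ParamSpec("life_expectancy_maternal", 45.8812, "real",
              "Remaining life expectancy at the maternal age at death (solved so LYS = 7554)",
              provenance="calibrated"),
    ParamSpec("daly_calibration", 1.0597189, "ratio",
              "Multiplier mapping model discounted years to the published DALY total",
              provenance="calibrated"),
    # ------------------------------------------------------------------ unit costs (2024 USD)
    ParamSpec("nhis_cost_mild_pph", 72.90, "usd", "Health-system cost per mild PPH case",
              sa_range=_pct(72.90), dist="gamma"),
    ParamSpec("nhis_cost_severe_pph", 344.35, "usd", "Health-system cost per severe PPH case",
              sa_range=_pct(344.35), dist="gamma"),
    ParamSpec("oop_cost_mild_pph", 99.50, "usd", "Out-of-pocket cost per mild PPH case",
              sa_range=_pct(99.50), dist="gamma"),
    ParamSpec("oop_cost_severe_pph", 668.00, "usd", "Out-of-pocket cost per severe PPH case",
              sa_range=_pct(668.00), dist="gamma"),
    ParamSpec("sepsis_cost_system", 404.60, "usd", "Health-system cost per neonatal sepsis case",
              sa_range=_pct(404.60), dist="gamma"),
    ParamSpec("sepsis_cost_household", 107.80, "usd", "Household cost per neonatal sepsis case",
              sa_range=_pct(107.80), dist="gamma"),
    ParamSpec("lbw_hospital_cost", 1721.00, "usd", "Hospital cost per hospitalized LBW case",
              sa_range=_pct(1721.00), dist="gamma"),
    ParamSpec("lbw_nonmedical_household_cost", 52.00, "usd", "Non-medical household cost per LBW case"),
    ParamSpec("lbw_medical_oop_cost", 133.00, "usd", "Medical OOP cost per LBW case"),
    ParamSpec("hosp_rate_elbw", 1.0, "fraction", "Hospitalization rate for extremely LBW infants"),
    ParamSpec("hosp_rate_lbw_vlbw", 0.0266, "fraction", "Hospitalization rate for moderate + very LBW"),
    ParamSpec("tariff_anc_visit", 2.56, "usd", "NHIS tariff per ANC visit (G-DRG 2022)",
              sa_range=_pct(2.56), dist="gamma"),
    ParamSpec("tariff_vaginal_delivery", 24.08, "usd", "NHIS tariff per vaginal delivery",
              sa_range=_pct(24.08), dist="gamma"),
    ParamSpec("tariff_csection_delivery", 49.41, "usd", "NHIS tariff per C-section delivery",
              sa_range=_pct(49.41), dist="gamma"),
    ParamSpec("oop_anc_visit", 6.85, "usd", "Household OOP cost per ANC visit"),
    ParamSpec("oop_vaginal_delivery", 4.42, "usd", "Household OOP cost per vaginal delivery"),
    ParamSpec("oop_csection_delivery", 20.60, "usd", "Household OOP cost per C-section delivery"),
    ParamSpec("vaginal_share", 0.85, "fraction", "Share of deliveries that are vaginal"),
    ParamSpec("lmd_cost_anc", 32160.43, "usd", "Last-mile delivery cost, ANC products",
              sa_range=_pct(32160.43), dist="gamma"),
    ParamSpec("lmd_cost_anc_pph_prevention", 45053.48, "usd",
              "Last-mile delivery cost, ANC + PPH-prevention products",
              sa_range=_pct(45053.48), dist="gamma"),
    ParamSpec("lmd_cost_total", 131130.20, "usd",
              "Last-mile delivery cost, ANC + PPH prevention & treatment products",
              sa_range=_pct(131130.20), dist="gamma"),
    ParamSpec("oop_increase_total", 1075300.83, "usd",
              "Additional household OOP expenditure on ANC and facility deliveries",
              sa_range=_pct(1075300.83), dist="gamma"),
    ParamSpec("wtp_threshold", 2409.0, "usd", "Willingness-to-pay threshold (1x GDP per capita, Ghana 2024)"),
)

_SPEC_BY_NAME = {s.name: s for s in PARAM_SPECS}


@dataclass
class ParameterSet:
    """A validated bag of named scalar inputs with provenance labels."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_SPEC_BY_NAME)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        for spec in PARAM_SPECS:
            if spec.name in self.values:
                self.values[spec.name] = spec.validate(self.values[spec.name])
                self.provenance.setdefault(spec.name, "user")
            else:
                self.values[spec.name] = spec.default
                self.provenance[spec.name] = spec.provenance
        self._check_invariants()

    def _check_invariants(self) -> None:
        shares = (
            self.values["lbw_share_moderate"]
            + self.values["lbw_share_very"]
            + self.values["lbw_share_extreme"]
        )
        if abs(shares - 1.0) > 0.01:
            raise ParameterError(f"lbw severity shares sum to {shares:.4f}, expected 1 +/- 0.01")
        if self.values["rr_facility_neonatal_mortality"] > 1.0:
            raise ParameterError(
                "rr_facility_neonatal_mortality: value > 1 contradicts the protective assumption"
            )
        for name in ("hr_moderate_neonatal", "hr_very_neonatal", "hr_extreme_neonatal"):
            if self.values[name] < 1.0:
                raise ParameterError(f"{name}: LBW hazard ratios must be >= 1")

    # -- access ---------------------------------------------------------
    def __getattr__(self, name: str) -> float:
        try:
            return self.__dict__["values"][name]
        except KeyError:
            raise AttributeError(name)

    def __getitem__(self, name: str) -> float:
        if name not in self.values:
            raise ParameterError(f"unknown parameter: {name}")
        return self.values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def spec(self, name: str) -> ParamSpec:
        return _SPEC_BY_NAME[name]

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a new ParameterSet with the given fields overridden."""
        vals = dict(self.values)
        prov = dict(self.provenance)
        for k, v in updates.items():
            if k not in _SPEC_BY_NAME:
                raise ParameterError(f"unknown parameter: {k}")
            vals[k] = v
            prov[k] = "user"
        return ParameterSet(values=vals, provenance=prov)

    # -- derived quantities used in several modules ---------------------
    @property
    def observed_anc_visits(self) -> float:
        return self.observed_anc_visits_2021 + self.observed_anc_visits_2022

    @property
    def lbw_severity_shares(self) -> tuple[float, float, float]:
        return (self.lbw_share_moderate, self.lbw_share_very, self.lbw_share_extreme)

    # -- I/O -------------------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return dict(self.values)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def defaults(cls) -> "ParameterSet":
        return cls()


def load_parameters(path: str | None = None) -> ParameterSet:
    """Load a parameter configuration from a flat YAML key/value file.

    Omitted keys fall back to the base-case defaults (provenance
    ``published-default`` or ``calibrated``); supplied keys are validated against
    their hard bounds and labelled ``user``.  ``path=None`` or an empty file
    returns the full default set.
    """
    if path is None:
        return ParameterSet()
    with open(path) as fh:
        raw: Any = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path!r} must be a flat key/value mapping")
    flat: dict[str, float] = {}
    for key, value in raw.items():
        if isinstance(value, dict):  # tolerate one level of sectioning
            for k2, v2 in value.items():
                flat[str(k2)] = v2
        else:
            flat[str(key)] = value
    return ParameterSet(values=flat)
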