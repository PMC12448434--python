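import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mnhcea.outcomes import (
    RiskPair,
    facility_delivery_deaths_averted,
    lbw_mortality_averted,
    lbw_reduction,
    maternal_counterfactual,
    odds_shift_prevalence,
    pph_reduction,
    sepsis_reduction,
    solve_two_group_risks,
    split_severity,
)
from mnhcea.synthetic import generate_cohort_truth

risks = st.floats(0.01, 0.8)
shares = st.floats(0.02, 0.98)


def _odds(p):
    return p / (1 - p)


class TestTwoGroupSolver:
    def test_reconstructs_published_pph_risks(self):
        # printed pair (0.44, 0.19) is rounded to 2 decimals; agree within 0.01
        pair = solve_two_group_risks(0.199, 0.0363, 3.43)
        assert pair.risk_exposed == pytest.approx(0.44, abs=0.01)
        assert pair.risk_unexposed == pytest.approx(0.19, abs=0.01)

    def test_unit_or_collapses_to_overall(self):
        pair = solve_two_group_risks(0.3, 0.4, 1.0)
        assert pair.risk_exposed == pair.risk_unexposed == pytest.approx(0.3)

    @given(risks, risks, shares)
    def test_exact_inverse_of_forward_mixture(self, p, q, s):
        """Constructing (overall, share, OR) from any risk pair and solving
        back recovers the risks to 1e-9."""
        overall = s * p + (1 - s) * q
        oratio = _odds(p) / _odds(q)
        pair = solve_two_group_risks(overall, s, oratio)
        assert math.isclose(pair.risk_exposed, p, rel_tol=1e-9, abs_tol=1e-12)
        assert math.isclose(pair.risk_unexposed, q, rel_tol=1e-9, abs_tol=1e-12)
        assert math.isclose(pair.overall, overall, rel_tol=1e-9)

    def test_parameter_recovery_on_synthetic_cohort(self):
        """Empirical group risks from a 50k-woman cohort, pushed through the
        forward mixture and solved back, agree within binomial error."""
        cohort = generate_cohort_truth(50000, 0.44, 0.19, exposed_share=0.0363, seed=17)
        exp = cohort.exposed == 1
        p_hat = cohort.outcome[exp].mean()
        q_hat = cohort.outcome[~exp].mean()
        overall = exp.mean() * p_hat + (1 - exp.mean()) * q_hat
        pair = solve_two_group_risks(overall, exp.mean(), _odds(p_hat) / _odds(q_hat))
        assert pair.risk_exposed == pytest.approx(p_hat, rel=1e-9)
        # binomial sampling error bound on the true risks (3 sigma)
        n_exp = exp.sum()
        assert abs(p_hat - 0.44) < 3 * math.sqrt(0.44 * 0.56 / n_exp)
        assert abs(q_hat - 0.19) < 3 * math.sqrt(0.19 * 0.81 / (50000 - n_exp))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_two_group_risks(0.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            solve_two_group_risks(0.2, 0.5, -1.0)


class TestOddsShift:
    def test_published_lbw_prevalence_for_high_attenders(self):
        # overall odds 0.12 * OR 0.24 -> prevalence printed as 0.03
        assert odds_shift_prevalence(0.1073, 0.24) == pytest.approx(0.028, abs=0.0005)

    def test_unit_or_is_identity(self):
        assert odds_shift_prevalence(0.25, 1.0) == pytest.approx(0.25)

    @given(risks, shares)
    def test_agrees_with_exact_solver_as_exposed_share_vanishes(self, overall, _):
        pair = solve_two_group_risks(overall, 1e-9, 0.24)
        assert odds_shift_prevalence(overall, 0.24) == pytest.approx(pair.risk_exposed, rel=1e-4)

    def test_systematic_gap_to_exact_solver_is_one_sided(self):
        """With OR < 1 and a non-trivial exposed share, the approximation
        understates the exposed-group risk of the exact mixture solve."""
        for overall in (0.05, 0.1073, 0.2):
            approx = odds_shift_prevalence(overall, 0.24)
            exact = solve_two_group_risks(overall, 0.34, 0.24).risk_exposed
            assert approx < exact


class TestSeveritySplit:
    def test_counts_sum_to_total_exactly(self):
        out = split_severity(270.04, {"moderate": 0.78, "very": 0.14, "extreme": 0.08})
        assert sum(out.values()) == pytest.approx(270.04, abs=1e-12)

    def test_published_severe_pph_count(self):
        out = split_severity(92.78, {"mild": 0.7518, "severe": 0.2482})
        assert out["severe"] == pytest.approx(23.03, abs=0.01)

    @pytest.mark.parametrize("total", [0.0, 100.0])
    def test_even_split(self, total):
        out = split_severity(total, {"a": 0.5, "b": 0.5})
        assert out["a"] == out["b"] == total / 2

    def test_negative_share_rejected(self):
        with pytest.raises(ValueError):
            split_severity(10, {"a": -0.1, "b": 1.1})


class TestLBW:
    def test_published_net_reduction(self):
        impact = lbw_reduction(2252, 0.15, 0.03)
        assert impact.cases_averted == pytest.approx(270.24, abs=0.01)

    def test_zero_movers(self):
        assert lbw_reduction(0, 0.15, 0.03).cases_averted == 0

    def test_inverted_prevalences_rejected(self):
        with pytest.raises(ValueError):
            lbw_reduction(100, 0.03, 0.15)

    def test_severity_split_near_published_counts(self):
        impact = lbw_reduction(2252, 0.15, 0.03, {"moderate": 0.78, "very": 0.14, "extreme": 0.08})
        assert impact.severity_split["moderate"] == pytest.approx(210.0, rel=0.015)
        assert impact.severity_split["extreme"] == pytest.approx(21.79, rel=0.015)


class TestDeaths:
    def test_published_facility_delivery_deaths(self):
        d = facility_delivery_deaths_averted(14619.63, 17, 0.71)
        assert d.count == pytest.approx(72.07, abs=0.01)

    def test_rr_one_averts_nothing(self):
        assert facility_delivery_deaths_averted(1000, 17, 1.0).count == 0

    def test_ci_bound_arithmetic(self):
        assert facility_delivery_deaths_averted(1000, 17, 0.54).count == pytest.approx(7.82)

    def test_harmful_rr_needs_override(self):
        with pytest.raises(ValueError):
            facility_delivery_deaths_averted(1000, 17, 1.1)
        assert facility_delivery_deaths_averted(1000, 17, 1.1, override=True).count == 0.0

    def test_lbw_mortality_unit_hr_averts_nothing(self):
        hr = {"only": {"neonatal": 1.0, "early_infancy": 1.0, "late_infancy": 1.0}}
        rates = {"neonatal": 0.01, "early_infancy": 0.01, "late_infancy": 0.01}
        deaths = lbw_mortality_averted({"only": 100.0}, hr, rates)
        assert all(d.count == 0 for d in deaths)

    def test_lbw_mortality_hand_arithmetic(self):
        hr = {"only": {"neonatal": 3.0, "early_infancy": 1.0, "late_infancy": 1.0}}
        rates = {"neonatal": 0.01, "early_infancy": 0.01, "late_infancy": 0.01}
        deaths = {d.cause: d.count for d in lbw_mortality_averted({"only": 100.0}, hr, rates)}
        assert deaths["LBW_NEONATAL"] == pytest.approx(2.0)

    def test_missing_hazard_ratio_reported(self):
        with pytest.raises(KeyError, match="early_infancy"):
            lbw_mortality_averted(
                {"only": 10.0},
                {"only": {"neonatal": 2.0}},
                {"neonatal": 0.01, "early_infancy": 0.01, "late_infancy": 0.01},
            )

    @pytest.mark.parametrize(
        "observed,reduction,expected",
        [(28, 0.564, (64.22, 36.22)), (10, 0.5, (20.0, 10.0)), (7, 0.0, (7.0, 0.0))],
    )
    def test_maternal_counterfactual(self, observed, reduction, expected):
        cf, averted = maternal_counterfactual(observed, reduction)
        assert cf == pytest.approx(expected[0], abs=0.005)
        assert averted == pytest.approx(expected[1], abs=0.005)

    def test_full_reduction_rejected(self):
        with pytest.raises(ValueError):
            maternal_counterfactual(10, 1.0)


def _pair(p, q, share):
    return RiskPair(
        risk_exposed=p,
        risk_unexposed=q,
        measure="odds_ratio",
        measure_value=_odds(p) / _odds(q),
        exposed_share=share,
    )


class TestSepsisAndPPH:
    def test_sepsis_arithmetic_on_published_risks(self):
        impact = sepsis_reduction(14619.63, _pair(0.0203, 0.0048, 0.13))
        assert impact.cases_averted == pytest.approx(14619.63 * 0.0155, rel=1e-9)

    def test_sepsis_zero_births(self):
        assert sepsis_reduction(0, _pair(0.02, 0.005, 0.13)).cases_averted == 0

    def test_sepsis_inverted_risks_rejected(self):
        with pytest.raises(ValueError):
            sepsis_reduction(100, _pair(0.004, 0.02, 0.13))

    def test_pph_reduction_near_published_total(self):
        impact = pph_reduction(363.56, _pair(0.44, 0.19, 0.0363), severe_share=0.2482)
        assert impact.cases_averted == pytest.approx(92.78, rel=0.021)
        assert impact.severity_split["severe"] == pytest.approx(
            impact.cases_averted * 0.2482, rel=1e-12
        )

    def test_pph_zero_movers(self):
        assert pph_reduction(0, _pair(0.44, 0.19, 0.0363)).cases_averted == 0

    @given(st.floats(0, 5000), risks, st.floats(1.1, 8.0))
    def test_averted_cases_scale_linearly_in_movers(self, movers, q, oratio):
        p = oratio * _odds(q) / (1 + oratio * _odds(q))
        pair = _pair(p, q, 0.1)
        base = pph_reduction(movers, pair).cases_averted
        double = pph_reduction(2 * movers, pair).cases_averted
        assert double == pytest.approx(2 * base, rel=1e-12, abs=1e-12)
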