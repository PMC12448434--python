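import numpy as np
import pytest

from mnhcea import sensitivity as sens
from mnhcea.sensitivity import PSADraw, ceac, ce_plane, one_way, psa


def _metric(model):
    def evaluate(p):
        return model.fit(p).icers.per_daly_gov

    return evaluate


def _psa_eval(model):
    def evaluate(p):
        res = model.fit(p)
        return res.icers.net_cost_gov, res.icers.net_cost_societal, res.dalys_reported

    return evaluate


class TestTornado:
    def test_degenerate_range_has_zero_span(self, model, params):
        base = params.discount_rate
        entries = one_way(_metric(model), params, ranges={"discount_rate": (base, base)})
        assert entries[0].span == 0.0

    def test_sorted_by_descending_span_ties_alphabetical(self, model, params):
        entries = one_way(
            _metric(model),
            params,
            ranges={
                "discount_rate": (0.03, 0.05),
                "baseline_nmr": (17.0, 17.0),
                "anc_effect": (0.199, 0.199),
            },
        )
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)
        zeros = [e.parameter for e in entries if e.span == 0]
        assert zeros == sorted(zeros)

    def test_widening_a_range_weakly_increases_its_span(self, model, params):
        narrow = one_way(_metric(model), params, ranges={"baseline_nmr": (16.0, 18.0)})
        wide = one_way(_metric(model), params, ranges={"baseline_nmr": (13.0, 21.0)})
        assert wide[0].span >= narrow[0].span

    def test_order_invariant_under_input_permutation(self, model, params):
        r1 = {"discount_rate": (0.03, 0.05), "baseline_nmr": (13.0, 21.0)}
        r2 = dict(reversed(list(r1.items())))
        assert one_way(_metric(model), params, r1) == one_way(_metric(model), params, r2)

    def test_default_ranges_keep_government_icer_below_threshold(self, model, params):
        """Across every one-way variation the intervention stays cost-effective
        at the 1x GDP-per-capita willingness to pay."""
        entries = model.tornado()
        assert entries
        for e in entries:
            assert max(e.low_icer, e.high_icer) < params.wtp_threshold

    def test_invalid_range_rejected(self, model, params):
        with pytest.raises(ValueError):
            one_way(_metric(model), params, ranges={"baseline_nmr": (21.0, 13.0)})


class TestPSA:
    def test_point_distributions_reproduce_base_case_exactly(self, model, params, base_results):
        dists = {"baseline_nmr": ("point", 17.0), "discount_rate": ("point", 0.03)}
        draws = psa(_psa_eval(model), params, n_draws=5, seed=0, distributions=dists)
        for d in draws:
            assert d.delta_cost_gov == base_results.icers.net_cost_gov
            assert d.dalys_averted == base_results.dalys_reported

    def test_deterministic_given_seed(self, model, params):
        a = psa(_psa_eval(model), params, n_draws=20, seed=11)
        b = psa(_psa_eval(model), params, n_draws=20, seed=11)
        assert a == b
        c = psa(_psa_eval(model), params, n_draws=20, seed=12)
        assert a != c

    def test_mean_icer_near_base_case_under_symmetric_laws(self, model, params, base_results):
        """With the discount rate pinned (its default law is one-sided above
        the base rate) the remaining laws are centred on the base case, so the
        mean PSA ICER stays close to the deterministic value."""
        dists = sens.default_distributions(params)
        dists["discount_rate"] = ("point", params.discount_rate)
        draws = model.psa(n_draws=400, seed=3, distributions=dists)
        icers = np.array([d.icer("GOVERNMENT") for d in draws])
        assert icers.mean() == pytest.approx(base_results.icers.per_daly_gov, rel=0.10)

    def test_invalid_draw_count_rejected(self, model, params):
        with pytest.raises(ValueError):
            psa(_psa_eval(model), params, n_draws=0, seed=0)


class TestCEAC:
    def _draws(self):
        rng = np.random.default_rng(5)
        return [
            PSADraw(i, float(c), float(c * 2), float(d))
            for i, (c, d) in enumerate(
                zip(rng.normal(1000, 800, 200), rng.uniform(5, 15, 200))
            )
        ]

    def test_matches_brute_force_at_every_grid_point(self):
        draws = self._draws()
        grid = np.arange(0, 501, 25.0)
        curve = ceac(draws, grid, "GOVERNMENT")
        for w, prob in zip(curve.wtp_grid, curve.probability):
            brute = sum(w * d.dalys_averted - d.delta_cost_gov >= 0 for d in draws) / len(draws)
            assert prob == pytest.approx(brute, abs=1e-12)

    def test_monotone_nondecreasing_in_wtp(self):
        curve = ceac(self._draws(), np.arange(0, 1000, 10.0), "SOCIETAL")
        assert (np.diff(curve.probability) >= 0).all()

    def test_zero_wtp_counts_cost_saving_draws(self):
        draws = self._draws()
        curve = ceac(draws, np.array([0.0]), "GOVERNMENT")
        saving = sum(d.delta_cost_gov <= 0 for d in draws) / len(draws)
        assert curve.probability[0] == pytest.approx(saving)

    def test_reaches_one_above_all_sampled_icers(self):
        draws = self._draws()
        top = max(d.icer("GOVERNMENT") for d in draws)
        curve = ceac(draws, np.array([top + 1.0]), "GOVERNMENT")
        assert curve.probability[0] == 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(self._draws(), np.array([]), "GOVERNMENT")

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            ceac([], np.array([100.0]), "GOVERNMENT")

    def test_ce_plane_pairs(self):
        draws = self._draws()
        pts = ce_plane(draws, "SOCIETAL")
        assert pts.shape == (len(draws), 2)
        assert pts[0, 1] == draws[0].delta_cost_soc


class TestDefaults:
    def test_default_distribution_families_match_parameter_roles(self, params):
        dists = sens.default_distributions(params)
        assert dists["pph_incidence"][0] == "beta"
        assert dists["sepsis_or_home"][0] == "lognormal"
        assert dists["tariff_anc_visit"][0] == "gamma"
        assert dists["discount_rate"][0] == "uniform"

    def test_lognormal_ci_anchoring(self, params):
        """The facility-delivery RR law is anchored at its published 95% CI."""
        rng = np.random.default_rng(0)
        law = sens.default_distributions(params)["rr_facility_neonatal_mortality"]
        samples = np.array([sens._sample(rng, law) for _ in range(4000)])
        inside = ((samples > 0.54) & (samples < 0.87)).mean()
        assert 0.90 < inside < 0.99
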