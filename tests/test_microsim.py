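import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnhcea.microsim import (
    CapacityError,
    additional_visits,
    counterfactual_total,
    infer_population_size,
    simulate_redistribution,
    threshold_crossers,
)
from mnhcea.synthetic import ANCDistribution, generate_anc_distribution


class TestCounterfactual:
    @pytest.mark.parametrize(
        "observed,effect,expected",
        [(44384, 0.199, 44384 * 0.801), (42095, 0.199, 42095 * 0.801), (1000, 0.0, 1000)],
    )
    def test_multiplicative_removal(self, observed, effect, expected):
        assert counterfactual_total(observed, effect) == pytest.approx(expected)

    def test_matches_published_counterfactuals_to_a_twentieth_percent(self):
        # printed counterfactual visit totals: 35 533 (2021) and 33 703 (2022)
        assert counterfactual_total(44384, 0.199) == pytest.approx(35533, rel=6e-4)
        assert counterfactual_total(42095, 0.199) == pytest.approx(33703, rel=6e-4)

    def test_effect_of_one_rejected(self):
        with pytest.raises(ValueError):
            counterfactual_total(100, 1.0)

    def test_additional_visits_uses_relative_increase_convention(self):
        # printed additional visits 14 353.06 for 86 479 observed
        assert additional_visits(44384 + 42095, 0.199) == pytest.approx(14353.06, rel=1e-5)
        assert additional_visits(500, 0.0) == 0.0


class TestInferPopulation:
    @pytest.mark.parametrize(
        "visits,mean,expected", [(35533, 6.2306, 5703), (33703, 6.0770, 5546)]
    )
    def test_published_population_sizes(self, visits, mean, expected):
        """Printed counterfactual visit totals and cohort mean visits imply
        the published 2021/2022 target population sizes."""
        shares = np.zeros(14)
        w = mean - 6.0  # two-point distribution on {6, 7} with the stated mean
        shares[7], shares[6] = w, 1.0 - w
        assert infer_population_size(visits, shares) == expected

    def test_all_mass_at_one(self):
        shares = np.zeros(14)
        shares[1] = 1.0
        assert infer_population_size(100, shares) == 100

    def test_zero_mean_rejected(self):
        shares = np.zeros(3)
        shares[0] = 1.0
        with pytest.raises(ZeroDivisionError):
            infer_population_size(10, shares)


class TestThresholdCrossers:
    def test_identical_distributions_give_zero(self):
        d = generate_anc_distribution(500, 5.0, seed=0)
        assert threshold_crossers(d, d, 8) == 0

    def test_single_mover(self):
        before = ANCDistribution(counts=np.array([5, 0]))
        after = ANCDistribution(counts=np.array([4, 1]))
        assert threshold_crossers(before, after, 1) == 1

    def test_mismatched_populations_rejected(self):
        a = ANCDistribution(counts=np.array([5, 0]))
        b = ANCDistribution(counts=np.array([4, 0]))
        with pytest.raises(ValueError):
            threshold_crossers(a, b, 1)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 9))
    @settings(max_examples=30)
    def test_matches_per_woman_brute_force(self, seed, threshold):
        """Category-count arithmetic equals counting individual women."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        before_visits = rng.integers(0, 10, n)
        increments = rng.integers(0, 4, n)
        after_visits = before_visits + increments
        cap = 13
        before = ANCDistribution(counts=np.bincount(before_visits, minlength=cap + 1))
        after = ANCDistribution(counts=np.bincount(np.minimum(after_visits, cap), minlength=cap + 1))
        brute = max(
            0,
            int((after_visits >= threshold).sum()) - int((before_visits >= threshold).sum()),
        )
        assert threshold_crossers(before, after, threshold) == brute


class TestRedistribution:
    def test_zero_budget_reproduces_baseline(self):
        base = generate_anc_distribution(300, 5.0, seed=2)
        res = simulate_redistribution(base, 0, n_sims=5, seed=1)
        assert (res.post_counts == base.counts).all()
        assert res.crossers_8plus_summary == (0.0, 0.0, 0.0)

    def test_forced_allocation_pushes_everyone_over_eight(self):
        counts = np.zeros(14, dtype=int)
        counts[7] = 10
        base = ANCDistribution(counts=counts)
        res = simulate_redistribution(base, 10, n_sims=20, seed=3)
        assert (res.crossers_8plus == 10).all()

    def test_conservation_and_monotonicity_in_every_replicate(self):
        base = generate_anc_distribution(2000, 6.0, seed=4)
        extra = 1500
        res = simulate_redistribution(base, extra, n_sims=50, seed=5)
        ks = np.arange(base.cap + 1)
        for rep in res.post_counts:
            assert rep.sum() == base.n_women
            assert int(ks @ rep) == base.total_visits + extra
            # no woman's visit count decreases: post survival dominates baseline
            post_surv = np.cumsum(rep[::-1])[::-1]
            base_surv = np.cumsum(base.counts[::-1])[::-1]
            assert (post_surv >= base_surv).all()

    def test_capacity_error_when_everyone_at_cap(self):
        counts = np.zeros(14, dtype=int)
        counts[13] = 5
        with pytest.raises(CapacityError):
            simulate_redistribution(ANCDistribution(counts=counts), 1, n_sims=1, seed=0)

    def test_deterministic_given_seed(self):
        base = generate_anc_distribution(1000, 6.0, seed=6)
        a = simulate_redistribution(base, 500, n_sims=10, seed=7)
        b = simulate_redistribution(base, 500, n_sims=10, seed=7)
        assert np.array_equal(a.post_counts, b.post_counts)

    def test_no_interior_category_empties_at_scale(self):
        """The reallocation preserves the distribution's shape: interior
        categories stay populated rather than being swept empty."""
        base = generate_anc_distribution(11249, 6.19, seed=8)
        extra = int(round(additional_visits(86479, 0.199)))
        res = simulate_redistribution(base, extra, n_sims=5, seed=9)
        occupied = base.counts[1:-1] > 50
        assert (res.post_counts[:, 1:-1][:, occupied] > 0).all()

    def test_replicate_mean_stabilizes_with_more_replicates(self):
        base = generate_anc_distribution(2000, 6.0, seed=10)
        res = simulate_redistribution(base, 1200, n_sims=200, seed=11)
        sem = res.crossers_8plus.std() / np.sqrt(res.n_sims)
        assert sem < 0.1 * res.crossers_8plus.mean()
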