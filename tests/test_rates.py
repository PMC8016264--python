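import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitorec.rates import (
    MutationPrior,
    ScreenCounts,
    bayes_mutation_posterior,
    meiotic_event_rate,
    mosaic_fraction,
    paired_rank_test,
    per_plant_gc_rate,
    segregation_test,
    standard_error,
    truncation_correction,
)
from mitorec.simulate import gen_read_counts


class TestScreenRates:
    def test_per_plant_gc_rate_screen_values(self):
        counts = ScreenCounts(n_plants=1_100_000, n_gc_events=6)
        assert per_plant_gc_rate(counts) == pytest.approx(1.3636e-6, rel=1e-4)

    def test_zero_events(self):
        assert per_plant_gc_rate(ScreenCounts(n_plants=100, n_gc_events=0)) == 0

    def test_random_counts_equal_direct_quotient(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 10**7))
            k = int(rng.integers(0, min(n, 50)))
            c = ScreenCounts(n_plants=n, n_gc_events=k)
            assert per_plant_gc_rate(c) == k / n / 2 / 2

    def test_meiotic_rates(self):
        assert meiotic_event_rate(24, 18_000) == pytest.approx(2.667e-3, abs=1e-5)
        assert meiotic_event_rate(26, 18_000) == pytest.approx(2.889e-3, abs=1e-5)
        assert meiotic_event_rate(0, 18_000) == 0

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            ScreenCounts(n_plants=0, n_gc_events=1)
        with pytest.raises(ValueError):
            meiotic_event_rate(1, 0)


class TestTruncationCorrection:
    def test_screen_cutoff(self):
        res = truncation_correction(149.04, 10.4, 130, 24)
        assert res.z == pytest.approx(-1.83, abs=0.005)
        assert res.missed_fraction == pytest.approx(0.0336, abs=5e-4)
        assert res.corrected_total >= 24

    def test_cutoff_at_mean_doubles_count(self):
        res = truncation_correction(100.0, 10.0, 100.0, 24)
        assert res.z == 0
        assert res.missed_fraction == pytest.approx(0.5)
        assert res.corrected_total == pytest.approx(48.0)

    def test_monotone_in_cutoff(self):
        corrected = [
            truncation_correction(149.04, 10.4, c, 24).corrected_total
            for c in np.linspace(110, 160, 20)
        ]
        assert np.all(np.diff(corrected) > 0)

    def test_cdf_accuracy(self):
        # the normal lower tail must be accurate well beyond table precision
        res = truncation_correction(0.0, 1.0, -5.0, 1)
        assert res.missed_fraction == pytest.approx(2.8665157e-7, abs=1e-10)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            truncation_correction(100, 0, 90, 5)


class TestBayesPosterior:
    def test_reversion_screen_posterior(self):
        prior = MutationPrior(mu=1e-8, n_plants=1.1e6, expected_mutants=0.003663)
        p_mut, p_none = bayes_mutation_posterior(prior, 24)
        assert p_mut == pytest.approx(1.53e-4, abs=1e-6)
        assert p_none == pytest.approx(0.996, abs=5e-4)

    def test_expected_mutants_recomputed_by_default(self):
        prior = MutationPrior(mu=1e-8, n_plants=1.1e6)
        assert prior.expected_mutants == pytest.approx(1.1e6 * 1e-8 / 3)

    def test_zero_observed_frequency_is_all_mutation(self):
        prior = MutationPrior(mu=1e-8, n_plants=1000, expected_mutants=0.0)
        p_mut, p_none = bayes_mutation_posterior(prior, 0)
        assert p_mut == 1.0
        assert p_none == 1.0

    def test_formula_oracle_random_parameters(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            mu = float(rng.uniform(1e-10, 1e-6))
            n_plants = float(rng.integers(10**4, 10**7))
            n_obs = int(rng.integers(1, 50))
            prior = MutationPrior(mu=mu, n_plants=n_plants)
            p_mut, p_none = bayes_mutation_posterior(prior, n_obs)
            f = max((n_obs - mu / 3 * n_plants) / n_plants, 0)
            want = (mu / 3) / (mu / 3 + f)
            assert p_mut == pytest.approx(want)
            assert p_none == pytest.approx((1 - want) ** n_obs)
            assert 0 <= p_mut <= 1

    def test_posterior_monotone_in_mutation_rate(self):
        # a stronger mutation prior must lower the chance that none of the
        # observed reversions are mutations
        p_none = [
            bayes_mutation_posterior(MutationPrior(mu=mu, n_plants=1.1e6), 24)[1]
            for mu in (1e-9, 1e-8, 1e-7, 1e-6)
        ]
        assert np.all(np.diff(p_none) < 0)

    def test_degenerate_prior_rejected(self):
        prior = MutationPrior(mu=0.0, n_plants=1000, expected_mutants=0.0)
        with pytest.raises(ValueError):
            bayes_mutation_posterior(prior, 0)


class TestMosaicFraction:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "tissue", "tiller", "n_rec", "n_nonrec"]
        )

    def test_pure_tissues(self):
        table = self._table(
            [("h1", "flag_leaf", "t1", 100, 0), ("c1", "root", "t1", 0, 100)]
        )
        frac = {s.sample_id: s.fraction_recombinant for s in mosaic_fraction(table)}
        assert frac == {"h1": 1.0, "c1": 0.0}

    def test_depth_flagging_and_zero_depth(self):
        table = self._table([("h1", "root", "t1", 1, 2)])
        (s,) = mosaic_fraction(table, min_depth=100)
        assert not s.pass_depth
        with pytest.raises(ValueError, match="zero read depth"):
            mosaic_fraction(self._table([("h1", "root", "t1", 0, 0)]))

    def test_coverage_of_binomial_ci(self):
        """The read-count estimate of a true mosaic fraction should fall
        inside its own 95% binomial CI in >= 93% of replicates."""
        rng = np.random.default_rng(19)
        true_f, depth, n_reps = 0.1338, 2_000, 400
        counts = gen_read_counts([true_f] * n_reps, depth, error_rate=0.0, seed=rng)
        hits = 0
        for n_rec, n_nonrec in counts:
            ci = stats.binomtest(int(n_rec), depth).proportion_ci(0.95)
            hits += ci.low <= true_f <= ci.high
        assert hits / n_reps >= 0.93

    def test_error_deconvolution(self):
        table = self._table([("h1", "root", "t1", 109, 891)])
        (s,) = mosaic_fraction(table, error_rate=0.01)
        assert s.corrected_fraction == pytest.approx((0.109 - 0.01) / 0.98)


class TestRankAndSegregationTests:
    def test_identical_samples_give_p_one(self):
        x = np.arange(1.0, 10.0)
        stat, p = paired_rank_test(x, x)
        assert (stat, p) == (0.0, 1.0)

    def test_exact_enumeration_uniformly_greater(self):
        # all 9 differences positive: two-sided exact p = 2/2^9
        x = np.arange(1.0, 10.0) + 1.0
        y = np.arange(1.0, 10.0)
        _, p = paired_rank_test(x, y)
        assert p == pytest.approx(2 / 2**9)

    def test_matches_scipy_exact(self):
        x = np.array([1.83, 0.50, 1.62, 2.48, 1.68, 1.88, 1.55, 3.06, 1.30])
        y = np.array([0.878, 0.647, 0.598, 2.05, 1.06, 1.29, 1.06, 3.14, 1.29])
        stat, p = paired_rank_test(x, y)
        ref = stats.wilcoxon(x, y, method="exact")
        assert (stat, p) == (ref.statistic, ref.pvalue)

    def test_perfect_segregation(self):
        stat, p, df = segregation_test((10, 20, 10))
        assert stat == 0 and p == pytest.approx(1.0) and df == 2

    def test_f2_counts_standard_pearson(self):
        # hand computation: expected (10.75, 21.5, 10.75)
        stat, p, df = segregation_test((12, 23, 8))
        assert stat == pytest.approx(0.9535, abs=5e-4)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(stat, 2))

    def test_type_i_error_calibration(self):
        """Under a true 1:2:1, the test should reject at alpha=0.05 about
        5% of the time."""
        rng = np.random.default_rng(23)
        n_reps, n = 2_000, 400
        draws = rng.multinomial(n, [0.25, 0.5, 0.25], size=n_reps)
        rejections = sum(
            segregation_test(tuple(d))[1] < 0.05 for d in draws
        )
        assert rejections / n_reps == pytest.approx(0.05, abs=0.02)


def test_standard_error_of_mean():
    assert standard_error(10.4, 24) == pytest.approx(2.123, abs=5e-4)
    with pytest.raises(ValueError):
        standard_error(1.0, 0)
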