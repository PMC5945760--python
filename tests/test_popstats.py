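"""Gain/loss bias, exact Poisson tests, propensity permutation, correlations."""

import math

import numpy as np
import pytest

from karyodepth.karyotype import study_records, tabulate_records
from karyodepth.popstats import (
    GainLossCounts,
    binomial_gain_loss,
    exact_poisson_test,
    frequency_factor_correlation,
    gain_loss_counts,
    propensity_classification,
    reciprocal_bias_test,
)


def binomial_oracle(k, n):
    """Two-sided binomial p (p0 = 0.5) by direct mass enumeration."""
    masses = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    p_obs = masses[k]
    return sum(m for m in masses if m <= p_obs * (1 + 1e-7))


def poisson_oracle(obs, mu, upper=400):
    """Two-sided exact Poisson p by direct mass enumeration.

    Masses are built by the recurrence m_{k+1} = m_k * mu / (k+1) to stay
    in float range for any usable rate.
    """
    masses = [math.exp(-mu)]
    for k in range(upper - 1):
        masses.append(masses[-1] * mu / (k + 1))
    p_obs = masses[obs]
    return min(1.0, sum(m for m in masses if m <= p_obs * (1 + 1e-7)))


class TestBinomial:
    def test_simple_gain_loss_counts_give_printed_p(self):
        p = binomial_gain_loss(GainLossCounts("simple", 49, 35))
        assert round(p, 3) == 0.156
        assert np.isclose(p, binomial_oracle(49, 84), rtol=1e-12)

    def test_compound_gain_loss_counts_give_printed_p(self):
        p = binomial_gain_loss(GainLossCounts("compound", 58, 20))
        assert float(f"{p:.4g}") == 1.952e-05
        assert np.isclose(p, binomial_oracle(58, 78), rtol=1e-12)

    def test_symmetry_gives_p_one(self):
        assert binomial_gain_loss(GainLossCounts("simple", 17, 17)) == 1.0

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 11), (30, 60), (80, 130), (199, 200)])
    def test_agrees_with_enumeration_oracle(self, k, n):
        p = binomial_gain_loss(GainLossCounts("x", k, n - k))
        assert np.isclose(p, binomial_oracle(k, n), atol=1e-12)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_gain_loss(GainLossCounts("x", 0, 0))


class TestExactPoisson:
    def test_observed_at_integer_rate_gives_p_one(self):
        assert exact_poisson_test(4, 4.0) == 1.0

    @pytest.mark.parametrize(
        "obs,mu", [(10, 2.0), (0, 0.1), (0, 5.0), (7, 7.5), (25, 13.0), (150, 100.0)]
    )
    def test_agrees_with_enumeration_oracle(self, obs, mu):
        assert np.isclose(exact_poisson_test(obs, mu), poisson_oracle(obs, mu), atol=1e-9)

    def test_near_null_small_rate(self):
        assert exact_poisson_test(0, 0.1) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_poisson_test(3, 0.0)
        with pytest.raises(ValueError):
            exact_poisson_test(-1, 2.0)


class TestPropensity:
    def test_equal_counts_are_all_neutral(self):
        res = propensity_classification([9] * 12, n_perm=4000, seed=1)
        assert all(c == "neutral" for c in res.classification)

    def test_tenfold_excess_flagged_prone(self):
        counts = [3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 30]
        res = propensity_classification(counts, n_perm=4000, seed=2)
        assert res.classification[11] == "prone"

    def test_classification_rule_matches_thresholds(self):
        counts = [1, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 40]
        res = propensity_classification(counts, n_perm=2000, seed=3)
        for obs, cls in zip(res.observed, res.classification):
            if cls == "prone":
                assert obs > res.upper_threshold
            elif cls == "resistant":
                assert obs < res.lower_threshold
            else:
                assert res.lower_threshold <= obs <= res.upper_threshold

    def test_doubling_permutations_keeps_classifications(self):
        counts = [2, 5, 6, 8, 9, 9, 10, 11, 12, 14, 16, 24]
        a = propensity_classification(counts, n_perm=5000, seed=4)
        b = propensity_classification(counts, n_perm=10000, seed=4)
        assert a.classification == b.classification

    def test_null_false_flag_rate_near_nominal(self):
        # iid Poisson populations: the pooled 95%/5% nearest-rank rule
        # flags each chromosome on each side at most ~12% of the time
        # (discreteness plus the estimated rate inflate it above 5%).
        rng = np.random.default_rng(7)
        n_pop, lam = 300, 12.0
        prone = resistant = 0
        for i in range(n_pop):
            counts = rng.poisson(lam, size=12)
            if counts.mean() == 0:
                continue
            res = propensity_classification(counts, n_perm=500, seed=1000 + i)
            prone += res.classification.count("prone")
            resistant += res.classification.count("resistant")
        assert prone / (12 * n_pop) <= 0.12
        assert resistant / (12 * n_pop) <= 0.12

    def test_zero_truncated_null_has_no_zero_draws_effectively(self):
        res = propensity_classification([1] * 11 + [4], n_perm=2000, seed=5,
                                        zero_truncated=True)
        assert res.lower_threshold >= 1

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            propensity_classification([0] * 12, n_perm=1000, seed=0)

    def test_study_table_combined_classification(self):
        summary = tabulate_records(study_records())
        counts = [summary["combined_counts"][c] for c in range(1, 13)]
        res = propensity_classification(counts, n_perm=10_000, seed=0)
        assert set(res.chromosomes("resistant")) == {1, 3}
        assert set(res.chromosomes("prone")) == {4, 9, 11}


class TestReciprocalBias:
    def test_identical_proportions_give_zero_statistic(self):
        stat, p = reciprocal_bias_test([[10, 30], [20, 60]])
        assert np.isclose(stat, 0.0)
        assert np.isclose(p, 1.0)

    def test_statistic_matches_brute_force(self):
        table = np.array([[49, 59], [75, 129]], dtype=float)
        stat, _ = reciprocal_bias_test(table)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        brute = ((table - expected) ** 2 / expected).sum()
        assert np.isclose(stat, brute, rtol=1e-12)

    def test_row_swap_invariance(self):
        t = [[49, 59], [75, 129]]
        assert np.isclose(reciprocal_bias_test(t)[0], reciprocal_bias_test(t[::-1])[0])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            reciprocal_bias_test([[0, 0], [5, 7]])


class TestCorrelation:
    def test_identity_gives_r_one(self):
        res = frequency_factor_correlation(range(12), range(12), "self")
        assert np.isclose(res.r, 1.0)

    def test_negated_gives_r_minus_one(self):
        freqs = np.arange(12.0)
        res = frequency_factor_correlation(freqs, -freqs + 100, "neg")
        assert np.isclose(res.r, -1.0)

    def test_noisy_negative_factor_recovered(self):
        rng = np.random.default_rng(11)
        freqs = rng.uniform(2, 30, size=12)
        factor = -3.0 * freqs + rng.normal(0, 2.0, size=12)
        res = frequency_factor_correlation(freqs, factor, "synthetic")
        assert res.r < -0.8
        assert res.p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            frequency_factor_correlation([1.0] * 12, range(12))


class TestGainLossCounts:
    def test_study_table_simple_counts(self):
        gl = gain_loss_counts(study_records())
        assert gl["simple"].gains == 49
        assert gl["simple"].losses == 35

    def test_both_compound_conventions_reported(self):
        gl = gain_loss_counts(study_records())
        # individuals: 40 parseable compound/segmental plants minus the
        # pure-loss ones carry a gain; events count chromosomes
        assert gl["compound_individuals"].gains <= 40
        assert gl["compound_events"].gains >= gl["compound_individuals"].gains
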