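import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pcdkit.prevalence import (
    FLAT,
    JEFFREYS,
    AlleleCount,
    CohortCounts,
    PriorSpec,
    aggregate_population_counts,
    average_prevalence,
    bayesian_prevalence,
    carrier_frequency,
    cohort_to_allele_count,
    hw_prevalence,
    load_cohort_counts,
    multi_population_bayesian,
    permutation_prevalence,
)


class TestCohortCounts:
    def test_sex_totals_must_add_up(self):
        with pytest.raises(ValueError):
            CohortCounts(100, 40, 50, 1, 1)

    def test_carriers_bounded_by_stratum(self):
        with pytest.raises(ValueError):
            CohortCounts(100, 40, 60, 41, 0)


class TestHardyWeinberg:
    def test_reference_cohort_ratio(self, cngp_cohort):
        est = hw_prevalence(cngp_cohort)
        assert est.ratio_n == 17_641
        assert est.rate == pytest.approx(5.6688e-5, rel=1e-4)

    def test_zero_carriers_give_zero_rate(self):
        est = hw_prevalence(CohortCounts(1000, 500, 500, 0, 0))
        assert est.rate == 0 and est.ratio_n is None

    def test_forced_allele_frequency(self):
        est = hw_prevalence(CohortCounts(1000, 500, 500, 10, 10))
        assert est.rate == pytest.approx(1e-4)
        assert est.ratio_n == 10_000

    @given(st.integers(0, 499), st.integers(1, 499))
    def test_strictly_increasing_in_carriers(self, c, dc):
        base = CohortCounts(1000, 500, 500, min(c, 500), 0)
        more_f = min(c + dc, 500)
        more_m = min(c + dc - more_f, 500)
        more = CohortCounts(1000, 500, 500, more_f, more_m)
        assert hw_prevalence(more).rate > hw_prevalence(base).rate


class TestPermutation:
    def test_reference_cohort_ratio(self, cngp_cohort):
        assert permutation_prevalence(cngp_cohort).ratio_n == 17_161

    def test_zero_carrier_stratum_gives_zero(self):
        est = permutation_prevalence(CohortCounts(200, 100, 100, 0, 10))
        assert est.rate == 0

    def test_closed_form(self):
        est = permutation_prevalence(CohortCounts(200, 100, 100, 10, 10))
        assert est.rate == pytest.approx(2.5e-3)
        assert est.ratio_n == 400

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            permutation_prevalence(CohortCounts(100, 0, 100, 0, 5))

    @given(
        st.integers(1, 5000),
        st.integers(1, 5000),
        st.data(),
    )
    def test_invariant_under_sex_label_swap(self, nf, nm, data):
        cf = data.draw(st.integers(0, nf))
        cm = data.draw(st.integers(0, nm))
        a = CohortCounts(nf + nm, nf, nm, cf, cm)
        b = CohortCounts(nf + nm, nm, nf, cm, cf)
        assert permutation_prevalence(a).rate == permutation_prevalence(b).rate


class TestBayesian:
    def test_reference_cohort_jeffreys_point(self):
        est = bayesian_prevalence(AlleleCount(269, 35_728, "CNGP"))
        assert est.ratio_n == 17_576
        # posterior mean squared, not posterior mean of the square
        assert est.rate == pytest.approx((269.5 / 35_729) ** 2)

    def test_flat_prior_closed_forms(self):
        est = bayesian_prevalence(AlleleCount(0, 1000), prior=FLAT)
        assert est.rate == pytest.approx((1 / 1002) ** 2)
        est = bayesian_prevalence(AlleleCount(1, 10), prior=FLAT)
        assert est.rate == pytest.approx((2 / 12) ** 2)

    def test_invalid_allele_count_rejected(self):
        with pytest.raises(ValueError):
            AlleleCount(11, 10)

    def test_prior_must_be_positive(self):
        with pytest.raises(ValueError):
            PriorSpec(0.0, 1.0)

    def test_interval_brackets_point_and_orders(self):
        est = bayesian_prevalence(AlleleCount(269, 35_728))
        assert est.ci_low_rate < est.rate < est.ci_high_rate

    def test_montecarlo_interval_close_to_quantile_interval(self):
        quantile = bayesian_prevalence(AlleleCount(269, 35_728))
        mc = bayesian_prevalence(
            AlleleCount(269, 35_728), ci_method="montecarlo", rng=7
        )
        assert mc.ci_low_rate == pytest.approx(quantile.ci_low_rate, rel=0.02)
        assert mc.ci_high_rate == pytest.approx(quantile.ci_high_rate, rel=0.02)

    @given(st.integers(0, 99))
    def test_strictly_increasing_in_allele_count(self, ac):
        lo = bayesian_prevalence(AlleleCount(ac, 1000))
        hi = bayesian_prevalence(AlleleCount(ac + 1, 1000))
        assert hi.rate > lo.rate

    @pytest.mark.parametrize("scale", [10, 100])
    def test_agrees_with_hardy_weinberg_at_large_samples(self, cngp_cohort, scale):
        cohort = CohortCounts(
            cngp_cohort.n_total * scale,
            cngp_cohort.n_female * scale,
            cngp_cohort.n_male * scale,
            cngp_cohort.carriers_female * scale,
            cngp_cohort.carriers_male * scale,
        )
        hw = hw_prevalence(cohort).rate
        bayes = bayesian_prevalence(cohort_to_allele_count(cohort)).rate
        assert abs(bayes - hw) / hw < 1e-3 / scale * 10

    def test_interval_coverage_under_binomial_sampling(self, rng):
        """The squared 95% interval covers the true rate ~95% of the time."""
        q, an, reps = 0.0075, 35_728, 1000
        ac = rng.binomial(an, q, size=reps)
        lo = stats.beta.ppf(0.025, 0.5 + ac, 0.5 + an - ac)
        hi = stats.beta.ppf(0.975, 0.5 + ac, 0.5 + an - ac)
        # monotone transform: covering q is covering q^2
        coverage = np.mean((lo <= q) & (q <= hi))
        assert 0.93 <= coverage <= 0.97


class TestAverage:
    def test_reference_cohort_average(self, cngp_cohort):
        ests = [
            hw_prevalence(cngp_cohort),
            permutation_prevalence(cngp_cohort),
            bayesian_prevalence(cohort_to_allele_count(cngp_cohort)),
        ]
        avg = average_prevalence(ests)
        assert avg.ratio_n in (17_456, 17_457)

    def test_single_estimate_identity(self):
        est = hw_prevalence(CohortCounts(1000, 500, 500, 10, 10))
        assert average_prevalence([est]).rate == est.rate

    def test_mean_of_rates(self):
        from pcdkit.prevalence import PrevalenceEstimate

        a = PrevalenceEstimate(1e-4, "hw")
        b = PrevalenceEstimate(3e-4, "hw")
        assert average_prevalence([a, b]).rate == pytest.approx(2e-4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_prevalence([])


class TestMultiPopulation:
    def test_identical_counts_give_identical_estimates(self):
        ests = multi_population_bayesian(
            [AlleleCount(5, 1000, "A"), AlleleCount(5, 1000, "B")]
        )
        assert ests["A"].rate == ests["B"].rate
        assert ests["A"].ci_low_rate == ests["B"].ci_low_rate

    def test_larger_sample_narrows_interval_at_same_af(self):
        ests = multi_population_bayesian(
            [AlleleCount(27, 3600, "small"), AlleleCount(270, 36_000, "large")]
        )
        w_small = ests["small"].ci_high_rate - ests["small"].ci_low_rate
        w_large = ests["large"].ci_high_rate - ests["large"].ci_low_rate
        assert w_large < w_small

    def test_single_population_consistent_with_direct_call(self):
        ac = AlleleCount(269, 35_728, "CNGP")
        assert (
            multi_population_bayesian([ac])["CNGP"].rate
            == bayesian_prevalence(ac).rate
        )

    def test_duplicate_population_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            multi_population_bayesian(
                [AlleleCount(1, 100, "A"), AlleleCount(2, 100, "A")]
            )


class TestTabularIO:
    def test_cohort_counts_round_trip(self, tmp_path, cngp_cohort):
        path = tmp_path / "cohort.tsv"
        path.write_text(
            "n_total\tn_female\tn_male\tcarriers_female\tcarriers_male\n"
            "17864\t7333\t10531\t125\t144\n"
        )
        assert load_cohort_counts(path) == cngp_cohort

    def test_population_aggregation_sums_ac_shares_an(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "variant": ["v1", "v2", "v1"],
                "population": ["X", "X", "Y"],
                "allele_count": [3, 4, 5],
                "allele_number": [1000, 1000, 2000],
            }
        )
        pooled = {ac.population: ac for ac in aggregate_population_counts(df)}
        assert pooled["X"].allele_count == 7
        assert pooled["X"].allele_number == 1000
        assert pooled["Y"].allele_count == 5

    def test_mismatched_allele_numbers_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "variant": ["v1", "v2"],
                "population": ["X", "X"],
                "allele_count": [1, 1],
                "allele_number": [1000, 999],
            }
        )
        with pytest.raises(ValueError, match="differing allele_number"):
            aggregate_population_counts(df)


class TestCarrierFrequency:
    def test_reference_cohort_is_one_in_66(self, cngp_cohort):
        assert carrier_frequency(cngp_cohort).ratio_n == 66
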