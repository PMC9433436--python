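import numpy as np
import pandas as pd
import pytest
from scipy import stats

from htskin import krel, simulate
from htskin.krel import (
    RelRateTable,
    fraction_unreacted,
    krel_from_counts,
    krel_single_pair,
    rate_distribution,
    top_fraction,
)
from htskin.seqio import N_VARIANTS, all_variants, variant_index


class TestFractionUnreacted:
    def test_homogeneous_depletion(self):
        c = np.full(10, 1000.0)
        F = fraction_unreacted(c, c, 0.3, pseudocount=0)
        assert np.allclose(F, 0.7)

    def test_two_variant_closed_form(self):
        # w = (0.5, 0.5), F_true = (0.64, 0.80) => f = 0.28 and residual
        # proportions proportional to w*F
        c0 = np.array([0.5, 0.5])
        cf = np.array([0.5 * 0.64, 0.5 * 0.80])
        F = fraction_unreacted(c0, cf, 0.28, pseudocount=0)
        assert F == pytest.approx([0.64, 0.80], rel=1e-12)

    def test_f_out_of_range(self):
        with pytest.raises(ValueError):
            fraction_unreacted(np.ones(4), np.ones(4), 1.0)

    def test_weighted_mean_identity(self, landscape_truth):
        state = simulate.solve_exposure(landscape_truth, 0.2)
        c0 = simulate.sample_reads(simulate.solve_exposure(landscape_truth, 0.0),
                                   landscape_truth, expected=True)
        cf = simulate.sample_reads(state, landscape_truth, expected=True)
        F = fraction_unreacted(c0, cf, 0.2, pseudocount=0)
        p0 = c0 / c0.sum()
        assert np.dot(p0, F) == pytest.approx(0.8, abs=1e-10)


class TestKrelSinglePair:
    def test_closed_form_ratio_of_two(self):
        # F = (0.64, 0.80): ln 0.64 / ln 0.80 = 2 exactly since 0.64 = 0.8^2
        c0 = np.array([0.5, 0.5])
        cf = np.array([0.32, 0.40])
        k = krel_single_pair(c0, cf, 0.28, pseudocount=0, ref_index=1)
        assert k[0] == pytest.approx(2.0, abs=1e-12)
        assert k[1] == 1.0

    def test_oracle_equivalence_on_expected_proportions(self, landscape_truth):
        """Noise-free simulator output returns the assigned truth exactly."""
        c0 = simulate.sample_reads(simulate.solve_exposure(landscape_truth, 0.0),
                                   landscape_truth, expected=True)
        state = simulate.solve_exposure(landscape_truth, 0.15)
        cf = simulate.sample_reads(state, landscape_truth, expected=True)
        k = krel_single_pair(c0, cf, 0.15, pseudocount=0)
        assert np.abs(k - landscape_truth.true_krel).max() < 1e-8

    def test_printed_ratio_form_equivalence(self, landscape_truth):
        """The pool-sum ratio form of the estimator equals ln F_i / ln F_ref.

        With R_i the variant/reference read ratio at f, R_i,0 the same ratio
        at the start, and the pool sum S = sum_j p_j(0) R_j/R_j,0 = (1-f)/F_ref,
        the ratio expression ln[(1-f)/((R_i,0/R_i) S)] / ln[(1-f)/S] reduces
        algebraically to ln F_i / ln F_ref; both are computed numerically here.
        """
        f = 0.25
        ref = variant_index("AAAAAG")
        c0 = simulate.sample_reads(simulate.solve_exposure(landscape_truth, 0.0),
                                   landscape_truth, expected=True)
        cf = simulate.sample_reads(simulate.solve_exposure(landscape_truth, f),
                                   landscape_truth, expected=True)
        R = cf / cf[ref]
        R0 = c0 / c0[ref]
        p0 = c0 / c0.sum()
        S = np.dot(p0, R / R0)
        printed = np.log((1 - f) / ((R0 / R) * S)) / np.log((1 - f) / S)
        direct = krel_single_pair(c0, cf, f, pseudocount=0)
        assert np.allclose(printed, direct, atol=1e-10)


class TestKrelFromCounts:
    def _uniform_table(self, depth_per_variant=50):
        counts = pd.DataFrame(
            {"rep1_f0": depth_per_variant, "rep1_f0.3": depth_per_variant},
            index=all_variants(),
        )
        meta = pd.DataFrame([
            {"sample": "rep1_f0", "replicate": "rep1", "f": 0.0},
            {"sample": "rep1_f0.3", "replicate": "rep1", "f": 0.3},
        ])
        from htskin.seqio import PoolCountTable
        return PoolCountTable(counts=counts, samples=meta)

    def test_uniform_counts_give_unit_rates(self):
        rates = krel_from_counts(self._uniform_table())
        assert np.allclose(rates.k_rel, 1.0, atol=1e-12)
        assert (rates.data["flag"] == krel.FLAG_OK).all()

    def test_reference_is_exactly_one(self, sampled_rates):
        _, rates = sampled_rates
        assert rates.k_rel["AAAAAG"] == 1.0
        assert rates.data.loc["AAAAAG", "se_ln"] == 0.0

    def test_recovery_rank_correlation(self, landscape_truth, sampled_rates):
        _, rates = sampled_rates
        rho = stats.spearmanr(rates.k_rel.to_numpy(), landscape_truth.true_krel).statistic
        assert rho > 0.97

    def test_slow_tail_errors_largest(self, landscape_truth, sampled_rates):
        """Log-scale recovery error concentrates in the slow-reacting tail."""
        _, rates = sampled_rates
        err = np.abs(np.log(rates.k_rel.to_numpy() / landscape_truth.true_krel))
        slow = landscape_truth.true_krel < np.quantile(landscape_truth.true_krel, 0.1)
        fast = landscape_truth.true_krel > np.quantile(landscape_truth.true_krel, 0.9)
        assert err[slow].mean() > 2 * err[fast].mean()

    def test_censored_variant_flagged_not_dropped(self):
        table = self._uniform_table()
        # a variant that apparently accumulates can carry no rate information
        table.counts.loc["ACGUAC", "rep1_f0.3"] = 200
        rates = krel_from_counts(table)
        assert rates.data.loc["ACGUAC", "flag"] == krel.FLAG_CENSORED
        assert "ACGUAC" in rates.data.index
        assert rates.data.loc["ACGUAC", "k_rel"] > 0

    def test_timepoint_estimates_agree_within_sampling_error(self, landscape_truth):
        """f = 0.05 and f = 0.30 estimates differ only by counting noise."""
        table = simulate.simulate_pool_counts(landscape_truth, f_targets=(0.05, 0.30),
                                              replicates=1, seed=101)
        rates = krel_from_counts(table)
        e1 = rates.per_timepoint["rep1_f0.05"].to_numpy()
        e2 = rates.per_timepoint["rep1_f0.3"].to_numpy()
        s1 = rates.per_timepoint_se["rep1_f0.05"].to_numpy()
        s2 = rates.per_timepoint_se["rep1_f0.3"].to_numpy()
        z = (e1 - e2) / np.sqrt(s1**2 + s2**2)
        z = z[np.isfinite(z)]
        assert len(z) > 3000
        assert abs(np.median(z)) < 0.3
        assert np.median(np.abs(z)) < 2.0

    def test_calibration_idempotent(self, sampled_rates):
        _, rates = sampled_rates
        again = rates.calibrate()
        assert np.allclose(again.k_rel, rates.k_rel, rtol=1e-14)

    def test_csv_round_trip(self, tmp_path, sampled_rates):
        _, rates = sampled_rates
        path = tmp_path / "krel.csv"
        rates.to_csv(path)
        back = RelRateTable.from_csv(path)
        assert np.allclose(back.k_rel, rates.k_rel)


class TestRateDistribution:
    def test_degenerate_distribution_single_bin(self):
        data = pd.DataFrame({"k_rel": np.ones(N_VARIANTS),
                             "se_ln": 0.0, "n_obs": 1, "flag": "ok"},
                            index=pd.Index(all_variants(), name="variant"))
        hist = rate_distribution(RelRateTable(data=data))
        assert (hist["count"] > 0).sum() == 1
        assert hist["count"].sum() == N_VARIANTS

    def test_subset_overlay_conserves_counts(self, sampled_rates):
        _, rates = sampled_rates
        au = krel.dinucleotide_subset("A", "U")
        hist = rate_distribution(rates, subsets={"AU": au})
        assert len(au) == 256
        assert hist["AU"].sum() == 256


class TestTopFraction:
    def test_one_percent_of_pool(self, sampled_rates):
        _, rates = sampled_rates
        assert len(top_fraction(rates, 0.01)) == 41

    def test_near_one_returns_everything(self, sampled_rates):
        _, rates = sampled_rates
        assert len(top_fraction(rates, 0.9999)) == N_VARIANTS

    def test_tie_break_deterministic(self):
        data = pd.DataFrame({"k_rel": np.ones(N_VARIANTS),
                             "se_ln": 0.0, "n_obs": 1, "flag": "ok"},
                            index=pd.Index(all_variants(), name="variant"))
        top = top_fraction(RelRateTable(data=data), 0.01)
        assert top == all_variants()[:41]

    def test_invalid_fraction(self, sampled_rates):
        _, rates = sampled_rates
        with pytest.raises(ValueError):
            top_fraction(rates, 0.0)
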