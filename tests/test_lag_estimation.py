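import numpy as np
import pytest
from scipy import stats

from cwsilag import (TimeSeries, gray_relational_grade, lag_cross_correlation,
                     lag_gray_relational, lag_mutual_information,
                     mutual_information, savgol_smooth, zscore)
from cwsilag.errors import (DegenerateSeriesError, InsufficientOverlapError,
                            InvalidConfigError)

from conftest import delayed_arrays, make_delayed_pair


def naive_pearson_profile(tc, ta, max_lag):
    """Independent oracle: per-shift scipy Pearson loop."""
    n = len(tc)
    m_max = int(max_lag // tc.step)
    return np.array([stats.pearsonr(tc.v[m:], ta.v[:n - m]).statistic
                     for m in range(m_max + 1)])


class TestCrossCorrelation:
    def test_identical_series(self):
        rng = np.random.default_rng(0)
        tc, _ = delayed_arrays(600, 0, rng)
        est = lag_cross_correlation(tc, tc, 120.0)
        assert est.tau == 0.0
        assert est.score == pytest.approx(1.0, abs=1e-9)

    def test_exact_delayed_copy(self):
        tc, ta = delayed_arrays(700, 22, np.random.default_rng(1))
        est = lag_cross_correlation(tc, ta, 180.0)
        assert est.tau == 44.0
        assert est.score == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_with_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        tc = TimeSeries(np.arange(400) * 2.0, rng.normal(size=400))
        ta = TimeSeries(np.arange(400) * 2.0, rng.normal(size=400))
        est = lag_cross_correlation(tc, ta, 100.0)
        np.testing.assert_allclose(est.profile.scores,
                                   naive_pearson_profile(tc, ta, 100.0),
                                   atol=1e-12)

    def test_noisy_delay_median_error(self):
        errs = []
        for seed in range(5):
            tc, ta = make_delayed_pair(44.0, seed=seed, noise_sd=0.3)
            tc_z = zscore(savgol_smooth(tc))
            ta_z = zscore(savgol_smooth(ta))
            errs.append(abs(lag_cross_correlation(tc_z, ta_z, 180.0).tau - 44.0))
        assert np.median(errs) <= 6.0

    def test_insufficient_overlap_rejected(self):
        tc, ta = delayed_arrays(100, 0, np.random.default_rng(2))
        with pytest.raises(InsufficientOverlapError):
            lag_cross_correlation(tc, ta, 150.0)

    def test_constant_series_rejected(self):
        t = np.arange(200) * 2.0
        flat = TimeSeries(t, np.full(200, 1.0))
        wavy = TimeSeries(t, np.sin(t / 50))
        with pytest.raises(DegenerateSeriesError):
            lag_cross_correlation(flat, wavy, 60.0)


class TestMutualInformation:
    def test_self_information_equals_binned_entropy(self):
        x = np.random.default_rng(3).normal(size=1000)
        bins = 12
        mi = mutual_information(x, x, bins)
        p, _ = np.histogram(x, bins=bins)
        p = p[p > 0] / p.sum()
        assert mi == pytest.approx(-np.sum(p * np.log(p)), abs=1e-12)

    def test_independent_series_below_permutation_null(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(size=2000)
        y = rng.uniform(size=2000)
        mi = mutual_information(x, y, 12)
        null = [mutual_information(x, rng.permutation(y), 12)
                for _ in range(200)]
        assert mi < np.quantile(null, 0.95)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 500))
        assert mutual_information(x, y, 10) == pytest.approx(
            mutual_information(x, 2.0 * y, 10), abs=1e-12)

    def test_estimator_bias_shrinks_with_n(self):
        rng = np.random.default_rng(11)
        vals = {}
        for n in (200, 2000):
            mis = [mutual_information(rng.normal(size=n), rng.normal(size=n), 8)
                   for _ in range(20)]
            vals[n] = np.mean(mis)
        assert vals[2000] < vals[200]

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidConfigError):
            mutual_information(np.zeros(100), np.zeros(99), 5)


class TestLagMutualInformation:
    def test_exact_delayed_copy(self):
        tc, ta = delayed_arrays(700, 22, np.random.default_rng(5))
        assert lag_mutual_information(tc, ta, 180.0).tau == 44.0

    def test_identical_series(self):
        tc, _ = delayed_arrays(600, 0, np.random.default_rng(6))
        assert lag_mutual_information(tc, tc, 120.0).tau == 0.0

    def test_invariant_to_monotone_distortion(self):
        tc, ta = delayed_arrays(700, 22, np.random.default_rng(8))
        tc_cubed = tc.with_values(np.sign(tc.v) * np.abs(tc.v) ** 3)
        assert lag_mutual_information(tc_cubed, ta, 180.0).tau == 44.0


class TestGrayRelational:
    def test_hand_example(self):
        # hand evaluation: deltas (0,0,1), zeta (1, 1, 1/3), grade 7/9
        grade, zeta = gray_relational_grade(
            np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 3.0]), rho=0.5)
        np.testing.assert_allclose(zeta, [1.0, 1.0, 1.0 / 3.0])
        assert grade == pytest.approx(7.0 / 9.0)

    def test_degenerate_identical_sequences(self):
        x = np.arange(10.0)
        grade, zeta = gray_relational_grade(x, x)
        assert grade == 1.0 and np.all(zeta == 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coefficients_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        _, zeta = gray_relational_grade(rng.normal(size=50), rng.normal(size=50))
        assert np.all(zeta > 0) and np.all(zeta <= 1)

    def test_exact_delayed_copy_grade_one(self):
        tc, ta = delayed_arrays(700, 30, np.random.default_rng(9))
        est = lag_gray_relational(tc, ta, 180.0)
        assert est.tau == 60.0
        assert est.score == pytest.approx(1.0)

    def test_identical_series(self):
        tc, _ = delayed_arrays(600, 0, np.random.default_rng(10))
        assert lag_gray_relational(tc, tc, 120.0).tau == 0.0

    def test_noisy_delay_median_error(self):
        errs = []
        for seed in range(5):
            tc, ta = make_delayed_pair(60.0, seed=seed, noise_sd=0.3)
            tc_z = zscore(savgol_smooth(tc))
            ta_z = zscore(savgol_smooth(ta))
            errs.append(abs(lag_gray_relational(tc_z, ta_z, 180.0).tau - 60.0))
        assert np.median(errs) <= 10.0


class TestProfileContracts:
    def test_all_methods_on_sampling_grid(self):
        tc, ta = make_delayed_pair(44.0, seed=2, noise_sd=0.2)
        tc_z = zscore(savgol_smooth(tc))
        ta_z = zscore(savgol_smooth(ta))
        for fn in (lag_cross_correlation, lag_mutual_information,
                   lag_gray_relational):
            est = fn(tc_z, ta_z, 180.0)
            assert est.tau % tc.step == 0.0
            assert est.tau in est.profile.lags
            assert est.score == pytest.approx(np.max(est.profile.scores))

    def test_noise_free_recovery_all_methods(self):
        # on a clean pure delay every estimator returns the truth exactly
        tc, ta = make_delayed_pair(44.0, seed=3, noise_sd=0.0)
        for fn in (lag_cross_correlation, lag_mutual_information,
                   lag_gray_relational):
            assert fn(tc, ta, 180.0).tau == 44.0

    def test_boundary_argmax_flagged(self):
        tc, ta = delayed_arrays(700, 40, np.random.default_rng(12))
        est = lag_cross_correlation(tc, ta, 60.0)  # truth (80) beyond the grid
        assert est.profile.at_boundary
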