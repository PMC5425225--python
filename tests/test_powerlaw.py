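"""Truncated discrete power-law MLE, window selection, surrogates, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crackling import (
    PowerLawFit,
    bootstrap_exponent_sd,
    fit_truncated_power_law,
    goodness_of_fit_test,
    mle_exponent,
    sample_power_law,
)
from crackling.powerlaw import EXPONENT_BOUNDS, ks_distance, truncated_cdf, truncated_pmf
from crackling.exceptions import (
    DegenerateSupportError,
    InsufficientDataError,
    ParameterError,
)


def grid_search_mle(samples, s_min, s_max, step=1e-4):
    """Independent oracle: dense scan of the truncated log-likelihood."""
    x = np.asarray(samples)
    x = x[(x >= s_min) & (x <= s_max)]
    grid = np.arange(EXPONENT_BOUNDS[0], EXPONENT_BOUNDS[1] + step, step)
    support = np.arange(s_min, s_max + 1, dtype=float)
    loglik = np.array(
        [-a * np.log(x).sum() - x.size * np.log((support ** -a).sum()) for a in grid]
    )
    return grid[np.argmax(loglik)]


class TestPmf:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        exponent=st.floats(1.02, 5.0),
        s_min=st.integers(1, 5),
        width=st.integers(1, 400),
    )
    def test_pmf_sums_to_one(self, exponent, s_min, width):
        pmf = truncated_pmf(exponent, s_min, s_min + width)
        assert abs(pmf.sum() - 1.0) < 1e-12

    def test_ks_zero_when_empirical_equals_model(self):
        # exponent 2 on {1, 2}: pmf = (0.8, 0.2); 8 ones and 2 twos match it
        samples = np.array([1] * 8 + [2] * 2)
        assert ks_distance(samples, 2.0, 1, 2) == pytest.approx(0.0, abs=1e-15)


class TestMleExponent:
    @pytest.mark.parametrize("seed,tau,s_max", [(0, 1.4, 15), (1, 2.0, 20), (2, 3.0, 12)])
    def test_matches_dense_grid_search_on_small_fixtures(self, seed, tau, s_max):
        x = sample_power_law(tau, 1, s_max, 50, seed=seed)
        exponent, _ = mle_exponent(x, 1, s_max)
        assert abs(exponent - grid_search_mle(x, 1, s_max)) <= 2e-4

    def test_three_sample_toy_matches_brute_force_scan(self):
        samples = [1, 1, 2]
        exponent, _ = mle_exponent(samples, 1, 2, min_count=3)
        assert abs(exponent - grid_search_mle(samples, 1, 2)) <= 2e-4

    def test_large_sample_recovers_exponent(self):
        x = sample_power_law(1.5, 1, 1000, 100_000, seed=5)
        exponent, _ = mle_exponent(x, 1, 1000)
        assert exponent == pytest.approx(1.5, abs=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            mle_exponent([1, 2, 3], 1, 10)

    def test_degenerate_support_rejected(self):
        with pytest.raises(DegenerateSupportError):
            mle_exponent([2] * 20, 2, 2)


class TestFitLoop:
    def test_candidate_minimum_sizes_are_one_to_three(self):
        from crackling.powerlaw import S_MIN_CANDIDATES

        assert tuple(S_MIN_CANDIDATES) == (1, 2, 3)

    def test_self_sampling_recovery(self):
        x = sample_power_law(1.8, 1, 500, 5000, seed=3)
        fit = fit_truncated_power_law(x)
        assert fit.converged
        assert fit.s_max >= 0.95 * x.max()
        assert abs(fit.exponent - 1.8) < 0.1
        assert fit.n_av == ((x >= fit.s_min) & (x <= fit.s_max)).sum()

    def test_contaminating_outliers_are_handled_by_truncation(self):
        # power-law body plus a sparse clump of outliers at 10x the cutoff
        rng = np.random.default_rng(4)
        body = sample_power_law(1.8, 1, 100, 3000, seed=rng)
        outliers = rng.integers(1000, 1011, 10)
        x = np.concatenate([body, outliers])
        # under the strict printed criterion the loop prunes the whole
        # contaminated tail below the smallest outlier
        strict = fit_truncated_power_law(x, criterion="1/n")
        assert strict.s_max < outliers.min()
        assert np.isin(outliers, strict.excluded_tail).all()
        # under the default criterion ten stragglers in 3000 samples are
        # within sampling tolerance: the fit converges and the exponent
        # estimate stays accurate
        default = fit_truncated_power_law(x)
        assert default.converged
        assert abs(default.exponent - 1.8) < 0.1

    def test_decrementing_s_max_never_increases_n_av(self):
        x = sample_power_law(1.6, 1, 200, 2000, seed=6)
        n_av = [((x >= 1) & (x <= m)).sum() for m in range(200, 150, -1)]
        assert (np.diff(n_av) <= 0).all()

    def test_non_power_law_data_is_flagged_not_raised(self):
        rng = np.random.default_rng(7)
        x = rng.geometric(0.08, 2000)
        fit = fit_truncated_power_law(x)
        assert isinstance(fit, PowerLawFit)
        assert not fit.converged

    def test_fewer_than_30_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_truncated_power_law([2, 3, 4] * 9)


class TestSampler:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        exponent=st.floats(1.1, 4.0),
        s_min=st.integers(1, 5),
        width=st.integers(2, 100),
        seed=st.integers(0, 10_000),
    )
    def test_samples_stay_inside_truncation_window(self, exponent, s_min, width, seed):
        x = sample_power_law(exponent, s_min, s_min + width, 200, seed=seed)
        assert x.min() >= s_min and x.max() <= s_min + width

    def test_chi_square_against_analytic_pmf(self):
        s_min, s_max, tau, n = 2, 500, 2.0, 100_000
        x = sample_power_law(tau, s_min, s_max, n, seed=8)
        expected = n * truncated_pmf(tau, s_min, s_max)
        observed = np.bincount(x - s_min, minlength=s_max - s_min + 1).astype(float)
        # merge the sparse tail so every expected count is >= 5
        cut = np.searchsorted(expected < 5, True)
        obs = np.append(observed[:cut], observed[cut:].sum())
        exp = np.append(expected[:cut], expected[cut:].sum())
        _, p = stats.chisquare(obs, exp)
        assert p > 0.01

    def test_continuous_inverse_method_is_supported(self):
        x = sample_power_law(1.8, 2, 300, 5000, seed=9, method="continuous")
        assert x.min() >= 2 and x.max() <= 300
        y = sample_power_law(1.8, 1, 300, 5000, seed=9, method="continuous")
        assert y.min() >= 1 and y.max() <= 300  # acceptance-rejection branch

    def test_reproducible_under_seed(self):
        a = sample_power_law(1.6, 1, 100, 1000, seed=10)
        b = sample_power_law(1.6, 1, 100, 1000, seed=10)
        assert np.array_equal(a, b)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ParameterError):
            sample_power_law(1.0, 1, 100, 10, seed=0)


class TestGoodnessOfFit:
    def test_null_p_values_are_roughly_uniform(self):
        # data drawn from the tested model itself (no refitting): p uniform
        rng = np.random.default_rng(11)
        fit = PowerLawFit(exponent=1.8, s_min=1, s_max=500, ks_value=np.nan,
                          n_av=1000, converged=True)
        ps = []
        for _ in range(100):
            x = sample_power_law(1.8, 1, 500, 1000, seed=rng)
            ps.append(goodness_of_fit_test(x, fit, n_surrogates=300, seed=rng))
        assert 0.3 <= np.median(ps) <= 0.7

    def test_geometric_data_is_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.geometric(0.08, 2000)
        fit = fit_truncated_power_law(x)
        p = goodness_of_fit_test(x, fit, n_surrogates=500, seed=1)
        assert p < 0.05

    def test_surrogate_count_precondition(self):
        fit = PowerLawFit(1.8, 1, 100, 0.01, 500, True)
        with pytest.raises(ParameterError):
            goodness_of_fit_test([1, 2, 3], fit, n_surrogates=50, seed=0)


class TestBootstrap:
    def test_sd_scales_as_inverse_sqrt_n(self):
        # the bootstrap SD of one sample depends on the realized truncation
        # window, so the 1/sqrt(n) law is tested on draw-averaged SDs
        sd = {}
        for n, base in ((1000, 0), (4000, 100)):
            draws = []
            for k in range(6):
                x = sample_power_law(1.6, 1, 100, n, seed=base + k)
                draws.append(bootstrap_exponent_sd(x, n_boot=200, seed=base + k + 7).exponent_sd)
            sd[n] = np.mean(draws)
        ratio = sd[1000] / sd[4000]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_failed_refits_are_counted_not_raised(self):
        x = sample_power_law(1.6, 1, 50, 60, seed=14)
        result = bootstrap_exponent_sd(x, n_boot=50, seed=15)
        assert result.n_failed >= 0
        assert result.exponents.size + result.n_failed == 50
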