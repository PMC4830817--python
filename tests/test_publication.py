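import numpy as np
import pytest
from scipy import stats

from flawsim import (
    RandomStream,
    apply_publication_filter,
    biased_p_curve,
    funnel_data,
    generate_study_pool,
    noncentral_t_power,
    p_curve,
)


class TestGenerateStudyPool:
    def test_design_and_effect_uncorrelated(self):
        pool = generate_study_pool(10_000, stream=RandomStream(0))
        r = np.corrcoef(pool.table["n_per_group"], pool.table["true_d"])[0, 1]
        assert abs(r) < 0.03

    def test_ranges_respected(self):
        pool = generate_study_pool(2000, (5, 100), (0.0, 2.0), stream=RandomStream(1))
        t = pool.table
        assert t["n_per_group"].between(5, 100).all()
        assert t["true_d"].between(0, 2).all()
        assert ((t["p_value"] > 0) & (t["p_value"] <= 1)).all()

    def test_null_pool_significant_at_alpha_rate(self):
        pool = generate_study_pool(10_000, d_range=(0.0, 0.0), stream=RandomStream(2))
        rate = (pool.table["p_value"] < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 10_000)

    def test_observed_d_unbiased_at_large_n(self):
        pool = generate_study_pool(
            2000, n_range=(100, 100), d_range=(1.0, 1.0), stream=RandomStream(3)
        )
        obs = pool.table["observed_d"]
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        # small-sample inflation of d at n=100 is ~d*3/(4*198-1) < 0.005
        assert abs(obs.mean() - 1.0) < 3 * se + 0.005


class TestPublicationFilter:
    def test_alpha_one_publishes_everything(self):
        pool = generate_study_pool(500, stream=RandomStream(4))
        assert apply_publication_filter(pool, alpha=1.01).table["published"].all()

    def test_published_iff_significant(self):
        pool = apply_publication_filter(
            generate_study_pool(500, stream=RandomStream(5)), alpha=0.05
        )
        t = pool.table
        assert (t["published"] == (t["p_value"] < 0.05)).all()

    def test_null_stratum_published_effects_inflated(self):
        pool = apply_publication_filter(
            generate_study_pool(
                8000, n_range=(20, 20), d_range=(0.0, 0.0), stream=RandomStream(6)
            )
        )
        pub = pool.table[pool.table["published"]]
        abs_d = pub["observed_d"].abs()
        se = abs_d.std(ddof=1) / np.sqrt(len(abs_d))
        # selected |d| exceeds the significance boundary t_crit*sqrt(2/n) = 0.66
        assert abs(abs_d.mean() - 0.75) < 3 * se + 0.02

    def test_publication_rate_matches_power_per_stratum(self):
        size = 4000
        pool = apply_publication_filter(
            generate_study_pool(
                size, n_range=(20, 20), d_range=(0.5, 0.5), stream=RandomStream(7)
            )
        )
        rate = pool.table["published"].mean()
        expected = noncentral_t_power(0.5, 20, 20)
        assert abs(rate - expected) < 3 * np.sqrt(expected * (1 - expected) / size)

    def test_selection_inflates_mean_observed_effect(self):
        pool = apply_publication_filter(
            generate_study_pool(
                5000, n_range=(10, 10), d_range=(0.3, 0.3), stream=RandomStream(8)
            )
        )
        t = pool.table
        assert t.loc[t["published"], "observed_d"].mean() > t["observed_d"].mean()


class TestFunnelData:
    def test_dispersion_decreases_with_n(self):
        pool = generate_study_pool(20_000, d_range=(1.0, 1.0), stream=RandomStream(9))
        strata = funnel_data(pool, n_bins=5)["strata"]
        sds = strata.sort_values("n_mid")["sd"].to_numpy()
        assert np.all(np.diff(sds) < 0)

    def test_fixed_effect_pool_centered_at_true_d(self):
        pool = generate_study_pool(20_000, d_range=(1.0, 1.0), stream=RandomStream(10))
        strata = funnel_data(pool, n_bins=5)["strata"]
        assert np.all(np.abs(strata["mean"] - 1.0) < 0.05)

    def test_published_null_pool_is_asymmetric(self):
        pool = apply_publication_filter(
            generate_study_pool(
                20_000, n_range=(5, 100), d_range=(0.0, 0.0), stream=RandomStream(11)
            )
        )
        points = funnel_data(pool, published_only=True)["points"]
        small = points[points["n_per_group"] <= 10]
        # every published small-n null study shows a large spurious effect
        assert (small["observed_d"].abs() > 0.8).all()

    def test_empty_selection_rejected(self):
        pool = generate_study_pool(50, d_range=(0.0, 0.0), stream=RandomStream(12))
        pool.table["published"] = False
        with pytest.raises(ValueError):
            funnel_data(pool, published_only=True)


class TestPCurve:
    def test_null_curve_uniform(self):
        curve = p_curve(10_000, 20, 0.0, bin_width=0.05, stream=RandomStream(13))
        counts = curve.densities * curve.reps
        chi2 = ((counts - 500.0) ** 2 / 500.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, len(counts) - 1)

    def test_densities_sum_to_one(self):
        curve = p_curve(500, 20, 0.5, stream=RandomStream(14))
        assert curve.densities.sum() == pytest.approx(1.0)

    def test_significant_fraction_matches_power(self):
        reps = 10_000
        curve = p_curve(reps, 20, 0.5, sd=20.0, stream=RandomStream(15))
        expected = noncentral_t_power(0.5, 20, 20)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(curve.significant_fraction() - expected) < 3 * se

    def test_true_effect_piles_mass_at_small_p(self):
        curve = p_curve(10_000, 20, 0.5, bin_width=0.05, stream=RandomStream(16))
        d = curve.densities
        assert d[0] == d.max()
        assert np.all(np.diff(d[:6]) < 0)  # decreasing through p = .30


class TestBiasedPCurve:
    def test_zero_shift_identical_to_unbiased(self):
        plain = p_curve(2000, 20, 0.5, stream=RandomStream(17))
        biased = biased_p_curve(2000, 20, 0.5, shift_fraction=0.0, stream=RandomStream(17))
        np.testing.assert_array_equal(plain.densities, biased.densities)

    def test_full_shift_moves_exact_window_mass(self):
        plain = p_curve(5000, 20, 0.5, bin_width=0.01, stream=RandomStream(18))
        biased = biased_p_curve(
            5000, 20, 0.5, bin_width=0.01, shift_fraction=1.0,
            shift_window=(0.05, 0.10), stream=RandomStream(18),
        )
        edges = plain.bin_edges
        window = (edges[:-1] >= 0.05) & (edges[1:] <= 0.10)
        target = (edges[:-1] >= 0.04) & (edges[1:] <= 0.05)
        assert biased.densities[window].sum() == pytest.approx(0.0)
        assert biased.densities[target].sum() == pytest.approx(
            plain.densities[target].sum() + plain.densities[window].sum()
        )

    def test_mass_conserved_and_bump_below_05(self):
        curve = biased_p_curve(
            10_000, 20, 0.5, bin_width=0.01, shift_fraction=0.5, stream=RandomStream(19)
        )
        assert curve.densities.sum() == pytest.approx(1.0)
        i = 4  # bin [0.04, 0.05)
        assert curve.densities[i] > curve.densities[i - 1]
        assert curve.densities[i] > curve.densities[i + 1]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            biased_p_curve(100, 20, 0.5, shift_window=(0.10, 0.20), stream=RandomStream(20))
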