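import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flawsim import (
    MultiplicityScenario,
    RandomStream,
    bh_adjust,
    bonferroni_alpha,
    confusion_counts,
    familywise_error,
    fdr_prevalence_curve,
)
from flawsim.core import batch_two_sample_t


class TestFamilywiseError:
    def test_single_comparison_is_alpha(self):
        assert familywise_error(MultiplicityScenario(1, 0.05)) == pytest.approx(0.05)

    @pytest.mark.parametrize(
        "k,alpha,expected",
        [
            (10, 0.05, 0.4013),
            (15, 0.05, 0.5367),
            (20, 0.05, 0.6415),
            (10, 0.01, 0.0956),
            (15, 0.01, 0.1399),
            (20, 0.01, 0.1821),
        ],
    )
    def test_reference_values(self, k, alpha, expected):
        assert familywise_error(MultiplicityScenario(k, alpha)) == pytest.approx(
            expected, abs=5e-5
        )

    def test_matches_monte_carlo_of_null_t_tests(self):
        k, reps, n = 5, 4000, 10
        rng = RandomStream(0).rng
        any_rejection = np.zeros(reps, dtype=bool)
        for _ in range(k):
            a = rng.normal(100, 15, size=(reps, n))
            b = rng.normal(100, 15, size=(reps, n))
            _, p, _ = batch_two_sample_t(a, b)
            any_rejection |= p < 0.05
        expected = familywise_error(MultiplicityScenario(k, 0.05))
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(any_rejection.mean() - expected) < 3 * se

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            MultiplicityScenario(0, 0.05)
        with pytest.raises(ValueError):
            MultiplicityScenario(5, 1.5)


class TestBonferroni:
    @pytest.mark.parametrize(
        "k,expected", [(1, 0.05), (10, 0.005), (15, 0.05 / 15), (20, 0.0025)]
    )
    def test_thresholds(self, k, expected):
        assert bonferroni_alpha(0.05, k) == pytest.approx(expected)

    def test_k15_rounds_to_printed_003(self):
        assert round(bonferroni_alpha(0.05, 15), 3) == 0.003

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestConfusionCounts:
    def test_worked_example_exact(self):
        cc = confusion_counts(10_000, 0.10, 0.80, 0.05)
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (800, 200, 450, 8550)
        assert cc.fdr == pytest.approx(0.36)
        assert cc.ppv == pytest.approx(0.64)

    def test_full_prevalence_no_false_positives(self):
        cc = confusion_counts(100, 1.0, 0.8, 0.05)
        assert cc.fp == 0
        assert cc.fdr == 0

    def test_perfect_classification(self):
        cc = confusion_counts(100, 0.5, 1.0, 0.0)
        assert cc.fn == 0 and cc.fp == 0
        assert cc.ppv == 1

    def test_no_positives_signalled(self):
        with pytest.raises(ZeroDivisionError):
            confusion_counts(100, 0.0, 0.8, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=10**6),
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_margin_identities(self, n, prevalence, power, alpha):
        cc = confusion_counts(n, prevalence, power, alpha)
        assert cc.tp + cc.fn == pytest.approx(n * prevalence)
        assert cc.fp + cc.tn == pytest.approx(n * (1 - prevalence))
        assert cc.tp + cc.fn + cc.fp + cc.tn == pytest.approx(n)
        assert cc.fdr + cc.ppv == pytest.approx(1.0)

    def test_stochastic_mode_cells_sum_to_n(self):
        cc = confusion_counts(10_000, 0.10, 0.80, 0.05, stream=RandomStream(1))
        assert cc.tp + cc.fn + cc.fp + cc.tn == 10_000
        for cell in (cc.tp, cc.fn, cc.fp, cc.tn):
            assert float(cell).is_integer()


class TestFdrPrevalenceCurve:
    def test_median_decreases_with_prevalence(self):
        df = fdr_prevalence_curve(
            [0.05, 0.1, 0.3, 0.5, 0.9], reps=2000, stream=RandomStream(2)
        )
        assert np.all(np.diff(df["fdr_median"]) < 0)

    def test_reference_power_line_reproduces_worked_example(self):
        df = fdr_prevalence_curve([0.10], reps=10, stream=RandomStream(3))
        assert df["fdr_at_reference_power"].iloc[0] == pytest.approx(0.36)

    def test_fdr_vanishes_at_high_prevalence(self):
        df = fdr_prevalence_curve([0.999], reps=500, stream=RandomStream(4))
        assert df["fdr_q75"].iloc[0] < 0.01

    def test_fdr_decreasing_in_power_at_fixed_prevalence(self):
        pi, alpha = 0.1, 0.05
        fdr_of = lambda pw: (1 - pi) * alpha / ((1 - pi) * alpha + pi * pw)
        assert fdr_of(0.9) < fdr_of(0.5)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            fdr_prevalence_curve([0.0, 0.5])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        # q_(i) = min_{j >= i} m p_(j) / j: all equal .05 here
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_ordering_properties(self, pvals):
        p = np.asarray(pvals)
        q = bh_adjust(p)
        m = len(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= np.minimum(m * p, 1.0) + 1e-12)
        # monotone: sorting by p sorts by q
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
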