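"""Unit and property tests for the small-sample correlation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transomics import (
    CollinearControlError,
    DegenerateDataError,
    InsufficientOverlapError,
    PerfectCorrelationError,
    critical_thresholds,
    dixon_q,
    partial_r,
    pearson_r,
    t_from_r,
)

# Table 1 post-mortem intervals (hours), in subject order S01..S03, C01..C03
PMI_HOURS = [15.0, 16.5, 17.0, 8.0, 4.0, 42.0]


class TestPearsonR:
    @pytest.mark.parametrize(
        "y, expected",
        [
            ([1, 2, 3, 4, 5, 6], 1.0),
            ([5, 3, 1, -1, -3, -5], -1.0),           # y = -2x + 7
            ([2, 1, 4, 3, 6, 5], 14.5 / 17.5),       # hand-summed S_xy/S_xx
        ],
    )
    def test_known_values(self, y, expected):
        res = pearson_r([1, 2, 3, 4, 5, 6], y)
        assert res.r == pytest.approx(expected, abs=1e-12)
        assert res.n == 6 and res.df == 4

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, np.nan]
        y = [1.0, 2.0, 3.0, 4.0, np.nan, 6.0]
        res = pearson_r(x, y)
        assert res.n == 3  # positions 0, 1, 3 survive
        assert res.r == pytest.approx(1.0)

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientOverlapError):
            pearson_r([1, 2, np.nan, np.nan], [np.nan, 2, 3, 4])

    def test_degenerate_factor(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])

    def test_alpha_fills_threshold_fields(self):
        res = pearson_r([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5], alpha=0.01)
        assert res.r_crit == pytest.approx(0.91719, abs=1e-4)
        assert res.significant is False
        assert pearson_r([1, 2, 3, 4], [4, 2, 1, 0]).significant is None

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-100, max_value=100),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        r0 = pearson_r(x, y).r
        assert pearson_r(a * x + b, y).r == pytest.approx(r0, abs=1e-9)
        assert pearson_r(-a * x + b, y).r == pytest.approx(-r0, abs=1e-9)


class TestTFromR:
    def test_threshold_t_at_six_samples(self):
        assert t_from_r(0.91719, 6) == pytest.approx(4.604, abs=1e-3)

    def test_zero_and_direct_evaluation(self):
        assert t_from_r(0.0, 10) == 0.0
        assert t_from_r(0.5, 6) == pytest.approx(1 / math.sqrt(0.75), abs=1e-12)

    def test_perfect_correlation_is_signaled(self):
        with pytest.raises(PerfectCorrelationError):
            t_from_r(1.0, 6)
        with pytest.raises(ValueError):
            t_from_r(1.5, 6)

    def test_monotone_in_abs_r(self):
        rs = np.linspace(0, 0.999, 50)
        ts = [t_from_r(r, 6) for r in rs]
        assert all(t2 > t1 for t1, t2 in zip(ts, ts[1:]))


class TestCriticalThresholds:
    def test_six_sample_threshold(self):
        t_crit, r_crit = critical_thresholds(0.01, 4)
        assert t_crit == pytest.approx(4.604, abs=1e-3)
        assert r_crit == pytest.approx(0.91719, abs=1e-4)

    def test_reduced_overlap_threshold(self):
        _, r_crit = critical_thresholds(0.01, 2)
        assert r_crit == pytest.approx(0.99005, abs=1e-4)
        assert r_crit >= 0.99

    def test_looser_alpha(self):
        _, r_crit = critical_thresholds(0.05, 4)
        assert r_crit == pytest.approx(0.8114, abs=1e-4)

    def test_monotonicity(self):
        rc = [critical_thresholds(0.01, df)[1] for df in range(1, 20)]
        assert all(b < a for a, b in zip(rc, rc[1:]))
        assert (critical_thresholds(0.001, 4)[1]
                > critical_thresholds(0.01, 4)[1]
                > critical_thresholds(0.05, 4)[1])

    @pytest.mark.parametrize("alpha,df", [(0, 4), (1, 4), (0.01, 0), (0.01, 1.5)])
    def test_invalid_inputs(self, alpha, df):
        with pytest.raises(ValueError):
            critical_thresholds(alpha, df)

    @pytest.mark.parametrize("alpha", [0.1, 0.05, 0.01])
    def test_round_trip_with_t(self, alpha):
        """Inverting r_crit back through the t transform recovers t_crit."""
        for df in range(1, 31):
            t_crit, r_crit = critical_thresholds(alpha, df)
            assert t_from_r(r_crit, df + 2) == pytest.approx(t_crit, abs=1e-6)


def residual_correlation(x, y, z):
    """Independent oracle: correlate the least-squares residuals of x on z
    and y on z."""
    design = np.column_stack([np.ones_like(z), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


class TestPartialR:
    def test_uncorrelated_control_is_identity(self):
        assert partial_r(0.5, 0.0, 0.0) == 0.5

    def test_full_mediation_collapses_to_zero(self):
        assert partial_r(0.72, 0.9, 0.8) == pytest.approx(0.0, abs=1e-12)

    def test_rounded_headline_marginals(self):
        # the strongly negative mediator pair leaves only a weak direct link
        assert partial_r(0.96, -0.98, -0.97) == pytest.approx(0.1943, abs=1e-4)

    def test_symmetry_in_x_and_y(self):
        assert partial_r(0.6, 0.3, -0.5) == partial_r(0.6, -0.5, 0.3)

    def test_collinear_control(self):
        with pytest.raises(CollinearControlError):
            partial_r(0.5, 1.0, 0.2)
        with pytest.raises(ValueError):
            partial_r(1.2, 0.1, 0.2)

    @given(n=st.integers(4, 50), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_residual_regression_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.standard_normal((3, n))
        c = np.corrcoef(np.vstack([x, y, z]))
        formula = partial_r(c[0, 1], c[0, 2], c[1, 2])
        assert formula == pytest.approx(residual_correlation(x, y, z), abs=1e-9)


class TestDixonQ:
    def test_pmi_column_is_not_an_outlier(self):
        """The 42-hour post-mortem interval is extreme but below Q99%."""
        res = dixon_q(PMI_HOURS, ["S01", "S02", "S03", "C01", "C02", "C03"],
                      confidence=0.99)
        assert res.q_high == pytest.approx(25 / 38, abs=1e-9)
        assert res.q_crit == 0.740
        assert not res.is_outlier and res.outlier_sample == ""

    def test_gross_outlier_is_flagged(self):
        res = dixon_q([1, 2, 3, 4, 100], confidence=0.99)
        assert res.q_high == pytest.approx(96 / 99, abs=1e-9)
        assert res.q_crit == 0.821
        assert res.is_outlier and res.outlier_sample == "4"

    def test_low_side_outlier(self):
        res = dixon_q([-100, 1, 2, 3, 4], ["a", "b", "c", "d", "e"],
                      confidence=0.99)
        assert res.is_outlier and res.outlier_sample == "a"
        assert res.q_low > res.q_high

    def test_degenerate_values(self):
        with pytest.raises(DegenerateDataError):
            dixon_q([3.0, 3.0, 3.0, 3.0])

    def test_n_out_of_range(self):
        with pytest.raises(InsufficientOverlapError):
            dixon_q([1.0, 2.0])
        with pytest.raises(InsufficientOverlapError):
            dixon_q(list(range(31)))

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-50, max_value=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        base = np.array(PMI_HOURS)
        r0 = dixon_q(base, confidence=0.99)
        r1 = dixon_q(a * base + b, confidence=0.99)
        assert r1.q_high == pytest.approx(r0.q_high, abs=1e-9)
        assert r1.q_low == pytest.approx(r0.q_low, abs=1e-9)

    def test_missing_values_dropped_first(self):
        res = dixon_q([1.0, 2.0, np.nan, 3.0, 100.0], confidence=0.99)
        assert res.n == 4 and res.is_outlier
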