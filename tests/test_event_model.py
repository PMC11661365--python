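"""Weibull calibration, accrual, and censoring-model tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

from rmstswitch import (
    ArmEventModel,
    CensoringModel,
    InfeasibleError,
    TrialDesign,
    censoring_probability,
    sample_censoring_times,
    sample_entry_times,
    solve_dropout_bound,
    solve_weibull_params,
    weibull_moments,
)

LOG2 = math.log(2.0)


class TestWeibullCalibration:
    def test_shape_given_exponential_scale(self):
        shape, scale = solve_weibull_params(6.0, shape=1.0)
        assert shape == 1.0
        assert scale == pytest.approx(6.0 / LOG2, rel=1e-12)

    @given(
        median=st.floats(0.1, 50.0),
        true_shape=st.floats(0.4, 4.0),
        frac=st.floats(0.1, 3.0),
    )
    def test_survival_point_round_trip(self, median, true_shape, frac):
        """Recovered (shape, scale) satisfy both defining equations."""
        truth = ArmEventModel.from_median(median, true_shape)
        ref_time = frac * median
        ref_survival = float(truth.survival(ref_time))
        if not 1e-6 < ref_survival < 1 - 1e-6 or abs(frac - 1.0) < 1e-3:
            return
        shape, scale = solve_weibull_params(median, ref_time, ref_survival)
        assert scale * LOG2 ** (1 / shape) == pytest.approx(median, rel=1e-8)
        assert math.exp(-((ref_time / scale) ** shape)) == pytest.approx(
            ref_survival, rel=1e-8
        )
        assert shape == pytest.approx(true_shape, rel=1e-6)

    @pytest.mark.parametrize(
        "median, ref_time, ref_survival",
        [
            (10.0, 10.0, 0.5),  # under-determined: any shape fits
            (10.0, 2.0, 0.5),  # S=0.5 away from the median
            (10.0, 10.0, 0.9),  # S != 0.5 at the median
            (10.0, 2.0, 0.3),  # would need a negative shape
        ],
    )
    def test_degenerate_or_infeasible_points_rejected(
        self, median, ref_time, ref_survival
    ):
        with pytest.raises(InfeasibleError):
            solve_weibull_params(median, ref_time, ref_survival)

    def test_inconsistent_model_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ArmEventModel(median=6.0, shape=1.0, scale=6.0)


class TestWeibullMoments:
    def test_exponential_closed_form(self):
        m = weibull_moments(ArmEventModel(median=5 * LOG2, shape=1.0, scale=5.0))
        assert m.mean == pytest.approx(5.0, rel=1e-12)
        assert m.variance == pytest.approx(25.0, rel=1e-12)
        assert m.second_moment == pytest.approx(50.0, rel=1e-12)

    def test_shape_two_closed_form(self):
        model = ArmEventModel(median=LOG2**0.5, shape=2.0, scale=1.0)
        assert weibull_moments(model).mean == pytest.approx(
            math.sqrt(math.pi) / 2, rel=1e-12
        )

    def test_heavy_tail_against_monte_carlo(self, rng):
        model = ArmEventModel.from_median(LOG2 ** (1 / 0.75), 0.75)  # scale 1
        m = weibull_moments(model)
        draws = model.sample(10**6, rng)
        se_mean = draws.std() / 1000.0
        assert abs(draws.mean() - m.mean) < 3 * se_mean
        se_second = (draws**2).std() / 1000.0
        assert abs((draws**2).mean() - m.second_moment) < 3 * se_second


class TestAccrual:
    def test_instant_accrual_gives_zero_entries(self, rng):
        design = TrialDesign(Ta=0.0, Te=26.0, tau=12.0, n=10)
        assert np.all(sample_entry_times(design, 5, rng) == 0.0)

    def test_entries_uniform_over_accrual_window(self, rng):
        design = TrialDesign(Ta=3.5, Te=12.0, tau=5.75, n=10)
        entries = sample_entry_times(design, 4000, rng)
        assert entries.max() < 3.5 and entries.min() >= 0.0
        assert stats.kstest(entries, stats.uniform(0, 3.5).cdf).pvalue > 0.01


class TestTrialDesign:
    @pytest.mark.parametrize("r, n, expected", [(1.0, 232, 232), (1.5, 3, 5), (2.0, 101, 202)])
    def test_experimental_arm_rounding(self, r, n, expected):
        assert TrialDesign(Ta=0, Te=26, tau=12, n=n, r=r).n_experimental == expected

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"Ta": -1.0},
            {"Te": 2.0},  # < Ta
            {"tau": 30.0},  # > Te
            {"n": 1},
            {"r": 0.0},
            {"alpha": 1.5},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        base = dict(Ta=3.0, Te=26.0, tau=12.0, n=100, r=1.0, alpha=0.025)
        with pytest.raises(ValueError):
            TrialDesign(**{**base, **kwargs})


class TestCensoring:
    def test_admin_only_censoring_time_is_remaining_followup(self, rng):
        design = TrialDesign(Ta=0.0, Te=26.0, tau=12.0, n=10)
        cens = CensoringModel.administrative_only()
        c = sample_censoring_times(cens, np.zeros(4), design, rng)
        assert np.all(c == 26.0)

    def test_dropout_bound_matches_pure_dropout_closed_form(self):
        """With no administrative pressure, P(censored) = (1 - e^{-lam h})/(lam h)."""
        model = ArmEventModel.from_median(6.0, 1.0)  # exponential
        lam = LOG2 / 6.0
        design = TrialDesign(Ta=0.0, Te=10000.0, tau=10.0, n=10)
        h = solve_dropout_bound(0.3, model, design)
        h_closed = optimize.brentq(
            lambda x: (1 - math.exp(-lam * x)) / (lam * x) - 0.3, 1e-6, 1e6
        )
        assert h == pytest.approx(h_closed, rel=1e-5)

    def test_rate_below_administrative_floor_rejected(self):
        model = ArmEventModel.from_median(6.0, 1.0)
        design = TrialDesign(Ta=0.0, Te=10.0, tau=5.0, n=10)
        floor = censoring_probability(model, design)  # = e^{-lam Te}
        assert floor == pytest.approx(math.exp(-LOG2 / 6 * 10), rel=1e-8)
        with pytest.raises(InfeasibleError, match="administrative"):
            solve_dropout_bound(0.9 * floor, model, design)

    def test_small_bound_keeps_censoring_below_it(self, rng):
        design = TrialDesign(Ta=0.0, Te=26.0, tau=12.0, n=10)
        cens = CensoringModel(mode="total-rate", h=2.0, target_rate=0.5)
        c = sample_censoring_times(cens, np.zeros(2000), design, rng)
        assert c.max() < 2.0
        assert stats.kstest(c, stats.uniform(0, 2.0).cdf).pvalue > 0.01

    def test_calibrated_rate_reproduced_in_simulation(self, rng):
        """Simulated no-switching control censoring matches the target rate."""
        model = ArmEventModel.from_median(1.0, 1.0)
        design = TrialDesign(Ta=3.0, Te=5.0, tau=5.0, n=10)
        cens = CensoringModel.calibrated(0.2, model, design)
        n = 10**5
        v = sample_entry_times(design, n, rng)
        t = model.sample(n, rng)
        c = sample_censoring_times(cens, v, design, rng)
        observed = float(np.mean(c < t))
        assert abs(observed - 0.2) < 3 * math.sqrt(0.2 * 0.8 / n)
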