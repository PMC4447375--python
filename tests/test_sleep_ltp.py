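"""LTP gains and the Gaussian bonus schedule.

Hand-derived expected values: trigger at REM onset + 30 s, synchrony ratios
counted on small constructed rasters, arctangent arithmetic for the
transition angle, and a closed-form OLS oracle for window slopes.
"""

import math

import numpy as np
import pytest

from sleepsyn.types import Hypnogram, InvalidParameterError, SpikeRaster
from sleepsyn.binarynet import WeightTrajectory
from sleepsyn.sleep_ltp import (
    LTPSchedule,
    beta_angle,
    build_schedule,
    cieg_ltp1,
    cieg_ltp2,
    fit_window_slope,
    gaussian_bonus,
    select_trigger,
)


@pytest.fixture
def hyp():
    return Hypnogram([
        ("WK", 0, 100), ("SWS", 100, 400), ("REM", 400, 500),
        ("WK", 500, 600), ("SWS", 600, 10470 - 60), ("REM", 10470 - 60, 10470 - 60 + 40),
        ("WK", 10470 - 20, 10470), ("SWS", 10470, 10470 + 200),
    ])


class TestSelectTrigger:
    def test_trigger_30s_after_selected_rem_onset(self):
        h = Hypnogram([("WK", 0, 100), ("SWS", 100, 10470 - 200),
                       ("REM", 10470 - 200, 10470 - 200 + 300),
                       ("WK", 10470 + 100, 10670), ("SWS", 10670, 10770),
                       ("REM", 10770, 10870)])
        # first REM onset at 10270: the SECOND starts at 10770
        t_t, win = select_trigger(h, rem_index=2)
        assert t_t == 10800.0
        assert win.pre_window == (10740.0, 10770.0)
        assert win.post_window == (10770.0, 10800.0)

    def test_rem_onset_10470_gives_10500(self):
        h = Hypnogram([("WK", 0, 70), ("SWS", 70, 10470), ("REM", 10470, 10570)])
        t_t, _ = select_trigger(h, rem_index=1)
        assert t_t == 10500.0

    def test_missing_rem_episode_rejected(self, hyp):
        with pytest.raises(InvalidParameterError):
            select_trigger(hyp, rem_index=5)

    def test_short_rem_rejected(self):
        h = Hypnogram([("WK", 0, 50), ("SWS", 50, 150), ("REM", 150, 170)])
        with pytest.raises(InvalidParameterError):
            select_trigger(h, rem_index=1)

    def test_short_sws_truncates_pre_window_with_warning(self):
        h = Hypnogram([("WK", 0, 50), ("SWS", 50, 70), ("REM", 70, 120)])
        with pytest.warns(UserWarning, match="truncated"):
            _, win = select_trigger(h, rem_index=1)
        assert win.pre_window == (50.0, 70.0)


class TestCiegLTP1:
    def make_raster(self, pre_bins, shared_bins, n_bins=100):
        """Unit 1 (pre) fires in pre_bins; unit 0 (post) in shared_bins."""
        dt = 0.004
        pre = np.array(sorted(pre_bins)) * dt
        post = np.array(sorted(shared_bins)) * dt
        return SpikeRaster(2, n_bins * dt, [post, pre])

    def test_ratio_definition(self):
        r = self.make_raster(pre_bins=range(10), shared_bins=range(4))
        c = cieg_ltp1(r, (0.0, 0.4))
        assert np.isclose(c[0, 1], 0.4)

    def test_silent_presynaptic_unit_gets_zero(self):
        r = self.make_raster(pre_bins=[], shared_bins=[0, 1])
        c = cieg_ltp1(r, (0.0, 0.4))
        assert c[0, 1] == 0.0

    def test_identical_trains_give_one(self):
        r = self.make_raster(pre_bins=[1, 5, 9], shared_bins=[1, 5, 9])
        c = cieg_ltp1(r, (0.0, 0.4))
        assert np.isclose(c[0, 1], 1.0) and np.isclose(c[1, 0], 1.0)

    def test_empty_epoch_rejected(self):
        r = self.make_raster([0], [0])
        with pytest.raises(InvalidParameterError):
            cieg_ltp1(r, (0.2, 0.2))


class TestWindowSlope:
    def test_exact_linear_series(self):
        times = np.arange(0.0, 30.0)
        w = np.stack([0.2 + 0.001 * t * np.ones((3, 3)) for t in times])
        traj = WeightTrajectory(times, w)
        slopes = fit_window_slope(traj, (0.0, 29.0))
        assert np.allclose(slopes, 0.001, atol=1e-12)

    def test_constant_series_gives_zero(self):
        times = np.arange(10.0)
        traj = WeightTrajectory(times, np.ones((10, 2, 2)))
        assert np.allclose(fit_window_slope(traj, (0.0, 9.0)), 0.0)

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(0)
        times = np.arange(0.0, 31.0)
        w = 0.3 + 0.002 * times[:, None, None] + 0.01 * rng.standard_normal((31, 4, 4))
        traj = WeightTrajectory(times, w)
        slopes = fit_window_slope(traj, (0.0, 30.0))
        # closed form: beta = cov(t, w) / var(t)
        tc = times - times.mean()
        expected = np.einsum("t,tij->ij", tc, w - w.mean(axis=0)) / (tc ** 2).sum()
        assert np.allclose(slopes, expected, atol=1e-12)

    def test_too_few_snapshots_rejected(self):
        traj = WeightTrajectory(np.array([0.0, 50.0]), np.zeros((2, 2, 2)))
        with pytest.raises(InvalidParameterError):
            fit_window_slope(traj, (0.0, 50.0))


class TestBetaAngle:
    def test_collinear_gives_straight_angle(self):
        assert np.isclose(beta_angle(0.5, 0.5), math.pi)

    def test_symmetric_turn_gives_right_angle(self):
        assert np.isclose(beta_angle(-1.0, 1.0), math.pi / 2)

    def test_positive_rem_slope_bounded_below_three_half_pi(self):
        m_sws = np.linspace(-50, 50, 101)
        m_rem = np.logspace(-6, 3, 41)
        grid = beta_angle(m_sws[:, None], m_rem[None, :])
        assert np.all(grid < 1.5 * math.pi)

    def test_upward_turn_below_pi(self):
        assert beta_angle(0.001, 0.002) < math.pi
        assert beta_angle(0.002, 0.001) > math.pi


class TestCiegLTP2:
    def test_nonpositive_rem_slope_excluded(self):
        c = cieg_ltp2(np.array([-1.0, 0.0]), np.array([-0.5, 0.0]), "ltp2_permissive")
        assert np.all(c == 0.0)

    def test_cutoff_boundary_and_maximal_gain(self):
        # beta -> 0 requires arctan difference -> pi: extreme slopes
        c = cieg_ltp2(np.array([-1e12]), np.array([1e12]), "ltp2_permissive")
        assert c[0] > 0.99 * (1 - math.pi / (1.5 * math.pi)) + 0.3  # ~ -> 1 as beta -> 0
        # collinear upward (beta = pi) is the restrictive cutoff
        c = cieg_ltp2(np.array([0.5]), np.array([0.5]), "ltp2_restrictive")
        assert np.isclose(c[0], 0.0)

    def test_restrictive_leq_permissive_elementwise(self):
        rng = np.random.default_rng(1)
        m_s = rng.normal(0, 0.01, 200)
        m_r = rng.normal(0, 0.01, 200)
        cp = cieg_ltp2(m_s, m_r, "ltp2_permissive")
        cr = cieg_ltp2(m_s, m_r, "ltp2_restrictive")
        assert np.all(cr <= cp + 1e-12)
        assert np.all((cp >= 0) & (cp <= 1) & (cr >= 0) & (cr <= 1))

    def test_unknown_variant_rejected(self):
        with pytest.raises(InvalidParameterError):
            cieg_ltp2(np.zeros(2), np.zeros(2), "ltp3")


class TestGaussianBonus:
    def sched(self, cieg, sigma=600.0):
        return LTPSchedule(variant="ltp1_full_sws", t_trigger=1000.0,
                           cieg=np.asarray(cieg, dtype=float), mu=1800.0, sigma=sigma)

    def test_zero_gain_gives_zero_increment(self):
        s = self.sched(np.zeros((3, 3)))
        assert np.all(gaussian_bonus(2800.0, s, 0.004) == 0.0)

    def test_zero_before_trigger(self):
        s = self.sched(np.ones((2, 2)))
        assert np.all(gaussian_bonus(999.9, s, 0.004) == 0.0)

    def test_peak_increment_value(self):
        s = self.sched(np.ones((2, 2)))  # diagonal is zeroed; check a synapse
        inc = gaussian_bonus(1000.0 + 1800.0, s, 0.004)
        assert np.isclose(inc[0, 1], 0.004 / (600.0 * math.sqrt(2 * math.pi)), rtol=1e-12)
        assert np.isclose(inc[0, 1], 2.6596e-6, rtol=1e-3)
        assert inc[0, 0] == 0.0

    def test_total_bonus_integrates_to_cieg(self):
        s = LTPSchedule(variant="ltp1_full_sws", t_trigger=100.0,
                        cieg=np.array([[0.0, 0.7], [1.0, 0.0]]), mu=900.0, sigma=150.0)
        dt = 0.004
        ts = np.arange(100.0, 100.0 + 2 * 900.0, dt)
        total = sum(s.envelope(t, dt) for t in ts)
        assert abs(total - 1.0) < 0.01  # unit-mass Gaussian Riemann sum

    def test_invalid_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            self.sched(np.ones((2, 2)), sigma=0.0)

    def test_cieg_out_of_bounds_rejected(self):
        with pytest.raises(InvalidParameterError):
            self.sched(np.full((2, 2), 1.5))


class TestBuildSchedule:
    def test_ltp1_requires_spikes_and_ltp2_requires_trajectory(self, hyp):
        with pytest.raises(InvalidParameterError):
            build_schedule("ltp1_full_sws", hyp, 1)
        with pytest.raises(InvalidParameterError):
            build_schedule("ltp2_permissive", hyp, 1)
        with pytest.raises(InvalidParameterError):
            build_schedule("ltp9", hyp, 1)
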