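"""LIF network operations: hand-evaluated STDP increments, exact
normalization, the embossing plan, the LTP Gaussian mass, and integration
properties of the full simulation."""

import math

import numpy as np
import pytest

from sleepsyn.types import InvalidParameterError
from sleepsyn.lifnet import (
    EmbossingPlan,
    LIFConfig,
    STDPConfig,
    SleepSchedule,
    build_embossing_plan,
    lif_step,
    ltp_bonus_m2,
    normalize_weights,
    run_model2,
    sleep_modulated_constants,
    stdp_update,
)

SCALED = dict(t_sleep=60.0, t_wake=120.0, t_ltp_peak=80.0, t_ltp_std=10.0)


class TestLifStep:
    def test_zero_input_decays_to_rest_without_spikes(self):
        cfg = LIFConfig()
        v = np.full(3, -60.0)
        g_e = np.zeros(3)
        g_i = np.zeros(3)
        ref = np.zeros(3, dtype=int)
        for _ in range(2000):
            v, g_e, g_i, ref, spiked = lif_step(v, g_e, g_i, ref, cfg)
            assert not spiked.any()
        assert np.allclose(v, cfg.v_rest, atol=1e-6)

    def test_constant_suprathreshold_drive_fires_periodically(self):
        cfg = LIFConfig()
        # hold a constant excitatory conductance by re-injecting the decay
        g_const = 8.0  # nS, strongly suprathreshold
        v = np.array([cfg.v_rest])
        g_e = np.array([0.0])
        g_i = np.array([0.0])
        ref = np.zeros(1, dtype=int)
        spikes = []
        for k in range(3000):
            g_e[:] = g_const
            v, g_e, g_i, ref, spiked = lif_step(v, g_e, g_i, ref, cfg)
            if spiked[0]:
                spikes.append(k * cfg.dt)
        isi = np.diff(spikes)
        assert isi.size > 5
        assert isi.std() <= cfg.dt  # periodic up to step quantization
        # closed-form LIF interspike interval + refractory period
        tau_eff = cfg.tau_m / (1.0 + 1000.0 * g_const * cfg.tau_m / cfg.c_m)
        v_inf = (cfg.v_rest / cfg.tau_m + 1000.0 * g_const * cfg.e_exc / cfg.c_m) * tau_eff
        t_isi = cfg.refractory_s + tau_eff * math.log(
            (v_inf - cfg.v_reset) / (v_inf - cfg.v_threshold))
        assert abs(isi.mean() - t_isi) < 2 * cfg.dt

    def test_inhibitory_conductance_pulls_below_rest(self):
        cfg = LIFConfig()
        v = np.array([-60.0])
        out, *_ = lif_step(v, np.zeros(1), np.zeros(1), np.zeros(1, dtype=int),
                           cfg, inh_increment=50.0)
        v_no_inh, *_ = lif_step(v, np.zeros(1), np.zeros(1), np.zeros(1, dtype=int), cfg)
        assert out[0] < v_no_inh[0]


class TestStdpUpdate:
    def setup_method(self):
        self.cfg = STDPConfig()

    def test_potentiation_amplitude_at_small_delay(self):
        dw = stdp_update("post", 1e-9, np.array([0.5]), self.cfg, v=0.0)
        assert np.isclose(dw[0], 3.2, atol=1e-6)

    def test_potentiation_at_tau(self):
        dw = stdp_update("post", 0.020, np.array([0.5]), self.cfg, v=0.0)
        assert np.isclose(dw[0], 3.2 * math.exp(-1.0), atol=1e-9)
        assert np.isclose(dw[0], 1.1772, atol=1e-3)

    def test_depression_at_minus_tau(self):
        dw = stdp_update("pre", -0.020, np.array([1.0]), self.cfg, v=0.0)
        assert np.isclose(dw[0], -0.03 * math.exp(-1.0), atol=1e-9)
        assert np.isclose(dw[0], -0.011036, atol=1e-5)

    def test_wrong_sign_delays_contribute_nothing(self):
        assert stdp_update("post", -0.01, np.array([1.0]), self.cfg)[0] == 0.0
        assert stdp_update("post", 0.0, np.array([1.0]), self.cfg)[0] == 0.0
        assert stdp_update("pre", 0.01, np.array([1.0]), self.cfg)[0] == 0.0

    def test_depression_scales_with_weight(self):
        d1 = stdp_update("pre", -0.005, np.array([1.0]), self.cfg, v=0.0)
        d2 = stdp_update("pre", -0.005, np.array([2.0]), self.cfg, v=0.0)
        assert np.isclose(d2[0], 2 * d1[0])


class TestSleepModulation:
    def test_identity_at_gamma_one(self):
        sched = SleepSchedule(**SCALED)
        assert sleep_modulated_constants(STDPConfig(), 1.0, 90.0, sched) == (3.2, 0.03)

    def test_division_multiplication_during_sleep(self):
        sched = SleepSchedule(**SCALED)
        cp, cd = sleep_modulated_constants(STDPConfig(), 2.0, 90.0, sched)
        assert np.isclose(cp, 1.6) and np.isclose(cd, 0.06)

    def test_unmodulated_outside_sleep(self):
        sched = SleepSchedule(**SCALED)
        assert sleep_modulated_constants(STDPConfig(), 5.0, 10.0, sched) == (3.2, 0.03)
        assert sleep_modulated_constants(STDPConfig(), 5.0, 150.0, sched) == (3.2, 0.03)

    def test_literal_reading_multiplies_both(self):
        sched = SleepSchedule(gamma_literal=True, **SCALED)
        cp, cd = sleep_modulated_constants(STDPConfig(), 2.0, 90.0, sched)
        assert np.isclose(cp, 6.4) and np.isclose(cd, 0.06)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(InvalidParameterError):
            sleep_modulated_constants(STDPConfig(), 0.0, 90.0, SleepSchedule(**SCALED))


class TestEmbossing:
    def test_uniform_reference_row_gives_unit_gain(self):
        w = np.full((5, 8), 0.3)
        plan = build_embossing_plan(w, seed=0)
        assert np.allclose(plan.theta, 1.0)

    def test_gain_is_normalized_reference_weight(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.1, 1.0, (6, 10))
        plan = build_embossing_plan(w, seed=2)
        for i, k in enumerate(plan.k_ref):
            assert np.allclose(plan.theta[i], w[k] / w[k].mean())

    def test_reference_is_a_derangement(self):
        w = np.random.default_rng(3).uniform(0.1, 1.0, (45, 20))
        plan = build_embossing_plan(w, seed=4)
        assert not np.any(plan.k_ref == np.arange(45))
        assert sorted(plan.k_ref) == list(range(45))

    def test_zero_reference_row_rejected(self):
        w = np.zeros((4, 6))
        with pytest.raises(InvalidParameterError):
            build_embossing_plan(w, seed=5)

    def test_fixed_point_reference_rejected_in_plan(self):
        with pytest.raises(InvalidParameterError):
            EmbossingPlan(k_ref=np.array([0, 2, 1]), theta=np.ones((3, 4)))


class TestLtpBonus:
    def test_zero_kappa_gives_zero(self):
        plan = EmbossingPlan(k_ref=np.array([1, 0]), theta=np.ones((2, 3)))
        sched = SleepSchedule(**SCALED)
        assert np.all(ltp_bonus_m2(80.0, plan, 0.0, sched, 0.001) == 0.0)

    def test_heaviside_gate_before_sleep(self):
        plan = EmbossingPlan(k_ref=np.array([1, 0]), theta=np.ones((2, 3)))
        sched = SleepSchedule(**SCALED)
        assert np.all(ltp_bonus_m2(10.0, plan, 2.0, sched, 0.001) == 0.0)

    def test_unmodulated_gaussian_mass_is_0p05_ns(self):
        sched = SleepSchedule()
        # analytic normalization
        assert np.isclose(sched.ltp_amplitude * sched.t_ltp_std * math.sqrt(2 * math.pi),
                          0.05, rtol=1e-12)
        # Riemann sum of the applied increments (kappa = theta = 1); the peak
        # is placed deep inside sleep so the onset gate truncates nothing
        sched = SleepSchedule(t_sleep=100.0, t_wake=800.0, t_ltp_peak=450.0, t_ltp_std=45.0)
        plan = EmbossingPlan(k_ref=np.array([1, 0]), theta=np.ones((2, 2)))
        dt = 0.01
        ts = np.arange(sched.t_sleep, sched.t_ltp_peak + 20 * sched.t_ltp_std, dt)
        total = sum(ltp_bonus_m2(t, plan, 1.0, sched, dt)[0, 0] for t in ts)
        assert abs(total - 0.05) < 0.0005

    def test_peak_rate_value(self):
        sched = SleepSchedule()
        assert np.isclose(sched.ltp_amplitude, 0.05 / (45 * math.sqrt(2 * math.pi)),
                          rtol=1e-12)
        assert np.isclose(sched.ltp_amplitude, 4.432e-4, rtol=1e-3)


class TestNormalizeWeights:
    def test_per_neuron_mean_exactly_omega(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0, 1, (45, 200))
        dw = rng.normal(0, 0.1, (45, 200))
        out = normalize_weights(w, dw, omega=0.25)
        assert np.allclose(out.mean(axis=1), 0.25, atol=1e-12)
        assert np.all(out >= 0)

    def test_identity_when_already_normalized_and_no_update(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(0.1, 1, (5, 10))
        w = w * (0.25 / w.mean(axis=1))[:, None]
        out = normalize_weights(w, np.zeros_like(w), omega=0.25)
        assert np.allclose(out, w, atol=1e-14)

    def test_row_scale_invariance(self):
        rng = np.random.default_rng(8)
        w = rng.uniform(0.1, 1, (4, 6))
        out1 = normalize_weights(w, np.zeros_like(w))
        out2 = normalize_weights(2 * w, np.zeros_like(w))
        assert np.allclose(out1, out2)

    def test_nonpositive_row_rejected(self):
        w = np.zeros((2, 4))
        with pytest.raises(InvalidParameterError):
            normalize_weights(w, np.zeros_like(w))


@pytest.fixture(scope="module")
def short_run():
    sched = SleepSchedule(kappa_sleep=1.0, gamma_sleep=2.0, **SCALED)
    return run_model2(schedule=sched, seed=0, total_duration=135.0,
                      snapshot_every_s=5.0, n_surrogates=50)


class TestRunModel2:

    def test_duration_must_exceed_wake(self):
        with pytest.raises(InvalidParameterError):
            run_model2(schedule=SleepSchedule(**SCALED), seed=0, total_duration=100.0)

    def test_normalization_conserved_throughout(self, short_run):
        assert np.allclose(short_run.w_final.mean(axis=1), 0.25, atol=1e-9)
        assert np.allclose(short_run.w_presleep.mean(axis=1), 0.25, atol=1e-9)
        # float32 snapshots carry the invariant at single precision
        assert np.allclose(short_run.snapshots.mean(axis=2), 0.25, atol=1e-5)

    def test_weights_nonnegative(self, short_run):
        assert short_run.w_final.min() >= 0
        assert short_run.snapshots.min() >= 0

    def test_selectivity_record_shapes_and_values(self, short_run):
        rec = short_run.record
        assert rec.sel.shape[1] == 45
        assert set(np.unique(rec.sel)) <= {-1, 0, 1}
        assert 0.0 <= rec.t_s <= 1.0 and 0.0 <= rec.t_h <= 1.0
        assert "t_s" in rec.surrogate and "t_h" in rec.surrogate

    def test_embossing_gain_from_presleep_snapshot(self, short_run):
        plan = short_run.plan
        w = short_run.w_presleep
        for i, k in list(enumerate(plan.k_ref))[:5]:
            assert np.allclose(plan.theta[i], w[k] / w[k].mean(), atol=1e-9)

    def test_seeded_determinism(self):
        sched = SleepSchedule(**SCALED)
        a = run_model2(schedule=sched, seed=3, total_duration=130.0,
                       record_spikes=True, n_surrogates=10)
        b = run_model2(schedule=sched, seed=3, total_duration=130.0,
                       record_spikes=True, n_surrogates=10)
        assert np.array_equal(a.w_final, b.w_final)
        assert np.array_equal(a.spike_counts, b.spike_counts)
        assert a.record.t_s == b.record.t_s
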