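"""Hippocampo-cortical network of leaky integrate-and-fire neurons (Model 2).

45 principal LIF neurons, not connected to each other, each receiving 200
plastic excitatory input synapses (conductances W in nS) driven by the
two-memory alternating Poisson input. Every principal spike recruits, after
a short delay, an inhibitory conductance onto the whole principal layer
(network feedback inhibition), enforcing competition.

Plasticity combines three mechanisms:

* STDP on the last pre/post spike pair (δt = t_post − t_pre):
  potentiation  WP = (C_p + v·W)·exp(−δt/τ) at a postsynaptic spike (δt > 0),
  depression    WD = (−C_d + v)·W·exp(δt/τ) at a presynaptic spike (δt < 0),
  with v a zero-mean Gaussian factor (σ = 0.015) drawn fresh per event;
* a Gaussian embossing LTP bonus during sleep whose per-synapse gain θ copies
  the normalized pre-sleep weight profile of a randomly chosen *other* neuron
  (a derangement k(i) ≠ i), scaled by the magnitude κ_sleep; the unmodulated
  Gaussian integrates to 0.05 nS;
* multiplicative weight normalization after every update, keeping each
  neuron's mean input weight exactly at ω = 0.25 nS.

Sleep (t ∈ [t_sleep, t_wake)) halves the input rates and rescales the STDP
constants by γ_sleep — potentiation weakened (C_p/γ), depression strengthened
(C_d·γ). The literal both-multiplied variant is available via
``gamma_literal=True`` on the schedule.

The inner simulation loop is compiled with numba; the module-level operation
functions are the reference definitions used by the unit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from sleepsyn.types import InvalidParameterError, SpikeRaster, TwoMemoryInputConfig
from sleepsyn.weight_metrics import UndefinedResultError
from sleepsyn.memory_metrics import (
    SelectivityRecord,
    proportion_hits,
    proportion_switches,
    selectivity_over_time,
    surrogate_test,
)

__all__ = [
    "LIFConfig",
    "STDPConfig",
    "SleepSchedule",
    "EmbossingPlan",
    "Model2Result",
    "lif_step",
    "stdp_update",
    "sleep_modulated_constants",
    "build_embossing_plan",
    "ltp_bonus_m2",
    "normalize_weights",
    "run_model2",
]


@dataclass
class LIFConfig:
    """Membrane and circuit parameters (potentials in mV, conductances in nS,
    capacitance in pF, times in s). Canonical leaky integrate-and-fire values;
    the published circuit fixes only the architecture (45 neurons × 200
    inputs, feedback inhibition), so membrane constants are conventions and
    are all configurable."""

    n_neurons: int = 45
    m_inputs: int = 200
    tau_m: float = 0.020
    v_rest: float = -70.0
    v_threshold: float = -54.0
    v_reset: float = -60.0
    refractory_s: float = 0.003
    tau_syn_e: float = 0.005
    tau_syn_i: float = 0.060
    c_m: float = 250.0
    e_exc: float = 0.0
    e_inh: float = -72.0
    inhibition_strength: float = 12.0
    inhibition_delay_s: float = 0.001
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.v_threshold <= self.v_reset:
            raise InvalidParameterError("threshold must exceed reset")
        for name in ("tau_m", "tau_syn_e", "tau_syn_i", "c_m", "dt"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass
class STDPConfig:
    tau_stdp: float = 0.020
    c_p: float = 3.2       # nS, potentiation amplitude
    c_d: float = 0.03      # unitless multiplicative depression
    sigma_v: float = 0.015

    def __post_init__(self) -> None:
        if self.tau_stdp <= 0:
            raise InvalidParameterError("tau_stdp must be positive")
        if self.c_p < 0 or self.c_d < 0:
            raise InvalidParameterError("c_p and c_d must be >= 0")


@dataclass
class SleepSchedule:
    """Sleep interval, STDP modulation γ, embossing gain κ and LTP Gaussian."""

    t_sleep: float = 315.0
    t_wake: float = 585.0
    gamma_sleep: float = 1.0
    kappa_sleep: float = 0.0
    t_ltp_peak: float = 405.0
    t_ltp_std: float = 45.0
    ltp_integral_ns: float = 0.05
    gamma_literal: bool = False
    omega: float = 0.25    # nS, per-neuron mean weight target

    def __post_init__(self) -> None:
        if not (self.t_sleep < self.t_ltp_peak < self.t_wake):
            raise InvalidParameterError("need t_sleep < t_ltp_peak < t_wake")
        if self.gamma_sleep <= 0:
            raise InvalidParameterError("gamma_sleep must be > 0")
        if self.kappa_sleep < 0:
            raise InvalidParameterError("kappa_sleep must be >= 0")
        if self.t_ltp_std <= 0:
            raise InvalidParameterError("t_ltp_std must be positive")

    @property
    def ltp_amplitude(self) -> float:
        """A such that the unmodulated Gaussian integrates to the stated mass."""
        return self.ltp_integral_ns / (self.t_ltp_std * math.sqrt(2.0 * math.pi))


@dataclass
class EmbossingPlan:
    """Reference derangement k(i) ≠ i and the gain matrix θ_ij."""

    k_ref: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.k_ref)
        if np.any(k == np.arange(k.size)):
            raise InvalidParameterError("reference map must satisfy k(i) != i")


@dataclass
class Model2Result:
    times: np.ndarray                # snapshot times (s)
    snapshots: np.ndarray            # (T, n, m) float32 weight snapshots
    w_presleep: np.ndarray           # W at the last step before sleep onset
    w_final: np.ndarray
    plan: EmbossingPlan
    spikes: SpikeRaster | None
    spike_counts: np.ndarray
    record: SelectivityRecord
    schedule: SleepSchedule
    seed: object = None


# ---------------------------------------------------------------------------
# Reference operations (unit-test surface; the numba kernel mirrors these)
# ---------------------------------------------------------------------------


def lif_step(v, g_e, g_i, ref_steps_left, cfg: LIFConfig,
             exc_increment=0.0, inh_increment=0.0):
    """One Euler step of the LIF layer.

    Incoming synaptic increments (nS) are applied instantaneously, the
    membrane integrates, threshold crossings emit spikes and reset, and the
    conductances decay. Returns (v, g_e, g_i, ref_steps_left, spiked).
    """
    v = np.array(v, dtype=float)
    g_e = np.array(g_e, dtype=float) + exc_increment
    g_i = np.array(g_i, dtype=float) + inh_increment
    ref = np.array(ref_steps_left, dtype=np.int64)
    dt = cfg.dt
    active = ref <= 0
    dv = (cfg.v_rest - v) / cfg.tau_m \
        + 1000.0 * (g_e * (cfg.e_exc - v) + g_i * (cfg.e_inh - v)) / cfg.c_m
    v = np.where(active, v + dt * dv, cfg.v_reset)
    ref = np.maximum(ref - 1, 0)
    spiked = active & (v >= cfg.v_threshold)
    v = np.where(spiked, cfg.v_reset, v)
    ref[spiked] = int(round(cfg.refractory_s / dt))
    g_e *= math.exp(-dt / cfg.tau_syn_e)
    g_i *= math.exp(-dt / cfg.tau_syn_i)
    return v, g_e, g_i, ref, spiked


def sleep_modulated_constants(stdp: STDPConfig, gamma: float, t: float,
                              schedule: SleepSchedule) -> tuple[float, float]:
    """Effective (C_p, C_d) at time t: inside the sleep interval potentiation
    is divided and depression multiplied by γ (or both multiplied, for the
    literal reading)."""
    if gamma <= 0:
        raise InvalidParameterError("gamma must be > 0")
    if schedule.t_sleep <= t < schedule.t_wake:
        if schedule.gamma_literal:
            return stdp.c_p * gamma, stdp.c_d * gamma
        return stdp.c_p / gamma, stdp.c_d * gamma
    return stdp.c_p, stdp.c_d


def stdp_update(event: str, delta_t: float, w, stdp: STDPConfig,
                c_p_eff: float | None = None, c_d_eff: float | None = None,
                v: float = 0.0):
    """ΔW for a single plasticity event on synapse weight(s) ``w``.

    ``event='post'`` (postsynaptic spike, δt = t_post − t_pre > 0) applies
    potentiation; ``event='pre'`` (presynaptic spike, δt < 0) applies
    depression; events at δt of the wrong sign (including exactly 0)
    contribute nothing.
    """
    w = np.asarray(w, dtype=float)
    c_p = stdp.c_p if c_p_eff is None else c_p_eff
    c_d = stdp.c_d if c_d_eff is None else c_d_eff
    if event == "post":
        if delta_t <= 0:
            return np.zeros_like(w)
        return (c_p + v * w) * math.exp(-delta_t / stdp.tau_stdp)
    if event == "pre":
        if delta_t >= 0:
            return np.zeros_like(w)
        return (-c_d + v) * w * math.exp(delta_t / stdp.tau_stdp)
    raise InvalidParameterError(f"unknown event type {event!r}")


def build_embossing_plan(w_presleep: np.ndarray, seed) -> EmbossingPlan:
    """Gain matrix from a pre-sleep weight snapshot: θ_ij = W_kj / mean_x W_kx
    with k = k(i), a random derangement of the neurons (so every neuron is
    embossed with another neuron's pattern)."""
    w = np.asarray(w_presleep, dtype=float)
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    while True:
        k_ref = rng.permutation(n)
        if not np.any(k_ref == np.arange(n)):
            break
    row_means = w[k_ref].mean(axis=1)
    if np.any(row_means <= 0):
        raise InvalidParameterError("all-zero reference row: embossing gain undefined")
    theta = w[k_ref] / row_means[:, None]
    return EmbossingPlan(k_ref=k_ref, theta=theta)


def ltp_bonus_m2(t: float, plan: EmbossingPlan, kappa: float,
                 schedule: SleepSchedule, dt: float) -> np.ndarray:
    """Per-synapse LTP increment at time t: κ·θ·A·exp(−(t−t_peak)²/(2σ²))·dt,
    gated by the Heaviside of (t − t_sleep)."""
    if t < schedule.t_sleep:
        return np.zeros_like(plan.theta)
    g = schedule.ltp_amplitude * math.exp(
        -((t - schedule.t_ltp_peak) ** 2) / (2.0 * schedule.t_ltp_std ** 2))
    return kappa * plan.theta * g * dt


def normalize_weights(w: np.ndarray, dw: np.ndarray, omega: float = 0.25) -> np.ndarray:
    """Multiplicative normalization: W' = clip(W+ΔW, 0, ∞)·ω / rowmean, so each
    neuron's mean input weight is exactly ω and within-row proportions are
    preserved."""
    total = np.clip(np.asarray(w, dtype=float) + np.asarray(dw, dtype=float), 0.0, None)
    row_means = total.mean(axis=1)
    if np.any(row_means <= 0):
        raise InvalidParameterError("non-positive row mean: normalization undefined")
    return total * (omega / row_means)[:, None]


# ---------------------------------------------------------------------------
# Compiled simulation loop
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_kernel(seed, n_steps, dt, n, m, half,
                tau_m, v_rest, v_th, v_reset, ref_steps, tau_e, tau_i, c_m,
                e_exc, e_inh, j_inh, delay_steps,
                window_steps, f_active, f_inactive,
                sleep_step, wake_step, sleep_factor,
                c_p, c_d, tau_stdp, sigma_v, gamma, gamma_literal,
                kappa, ltp_peak, ltp_std, ltp_amp, ltp_every,
                omega, k_ref,
                u, theta, w_presleep,
                snap_stride, snaps,
                spike_counts, spike_buf_t, spike_buf_u):
    np.random.seed(seed)
    s = np.empty(n)
    rows = np.empty(n)
    for i in range(n):
        acc = 0.0
        for j in range(m):
            acc += u[i, j]
        rows[i] = acc
        s[i] = omega * m / acc

    v = np.full(n, v_rest)
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)
    t_pre = np.full(m, -1.0e9)
    t_post = np.full(n, -1.0e9)
    ring = np.zeros(delay_steps + 1, dtype=np.int64)
    de = math.exp(-dt / tau_e)
    di = math.exp(-dt / tau_i)
    active_a = True
    n_rec = 0
    cap = spike_buf_t.shape[0]
    ltp_window = 6.0 * ltp_std

    for step in range(n_steps):
        t = step * dt
        if step % window_steps == 0:
            active_a = np.random.random() < 0.5
        sleeping = sleep_step <= step < wake_step
        if sleeping:
            fa = f_active * sleep_factor
            fi = f_inactive * sleep_factor
            if gamma_literal:
                cp_eff = c_p * gamma
            else:
                cp_eff = c_p / gamma
            cd_eff = c_d * gamma
        else:
            fa = f_active
            fi = f_inactive
            cp_eff = c_p
            cd_eff = c_d

        if step == sleep_step:
            for i in range(n):
                for j in range(m):
                    w_presleep[i, j] = s[i] * u[i, j]
            for i in range(n):
                k = k_ref[i]
                for j in range(m):
                    theta[i, j] = w_presleep[k, j] / omega

        # --- input spikes: excitation + depression events ---------------
        for j in range(m):
            if (j < half) == active_a:
                rate = fa
            else:
                rate = fi
            if np.random.random() < rate * dt:
                t_pre[j] = t
                for i in range(n):
                    w_ij = s[i] * u[i, j]
                    g_e[i] += w_ij
                    dtij = t_post[i] - t
                    if dtij < 0.0:
                        vn = np.random.normal(0.0, sigma_v)
                        d = (-cd_eff + vn) * w_ij * math.exp(dtij / tau_stdp)
                        new = u[i, j] + d / s[i]
                        if new < 0.0:
                            new = 0.0
                        rows[i] += new - u[i, j]
                        u[i, j] = new

        # --- delayed feedback inhibition ---------------------------------
        arriving = ring[step % (delay_steps + 1)]
        if arriving > 0:
            amt = j_inh * arriving
            for i in range(n):
                g_i[i] += amt
        ring[step % (delay_steps + 1)] = 0

        # --- membrane update, spikes, potentiation -----------------------
        n_spikes_now = 0
        for i in range(n):
            if ref[i] > 0:
                ref[i] -= 1
                v[i] = v_reset
            else:
                dv = (v_rest - v[i]) / tau_m \
                    + 1000.0 * (g_e[i] * (e_exc - v[i]) + g_i[i] * (e_inh - v[i])) / c_m
                v[i] += dt * dv
                if v[i] >= v_th:
                    v[i] = v_reset
                    ref[i] = ref_steps
                    t_post[i] = t
                    spike_counts[i] += 1
                    n_spikes_now += 1
                    if n_rec < cap:
                        spike_buf_t[n_rec] = t
                        spike_buf_u[n_rec] = i
                        n_rec += 1
                    for j in range(m):
                        dtij = t - t_pre[j]
                        if dtij > 0.0:
                            e = math.exp(-dtij / tau_stdp)
                            if e > 1.0e-12:
                                vn = np.random.normal(0.0, sigma_v)
                                d = (cp_eff + vn * s[i] * u[i, j]) * e
                                new = u[i, j] + d / s[i]
                                if new < 0.0:
                                    new = 0.0
                                rows[i] += new - u[i, j]
                                u[i, j] = new
        if n_spikes_now > 0:
            ring[(step + delay_steps) % (delay_steps + 1)] += n_spikes_now

        # --- embossing LTP (integrated over ltp_every-step substeps) -----
        if kappa > 0.0 and step >= sleep_step and step % ltp_every == 0:
            tmid = t + 0.5 * (ltp_every - 1) * dt
            if abs(tmid - ltp_peak) < ltp_window:
                b = kappa * ltp_amp * math.exp(
                    -((tmid - ltp_peak) ** 2) / (2.0 * ltp_std * ltp_std)) \
                    * dt * ltp_every
                for i in range(n):
                    binc = b / s[i]
                    acc = 0.0
                    for j in range(m):
                        inc = binc * theta[i, j]
                        u[i, j] += inc
                        acc += inc
                    rows[i] += acc

        # --- conductance decay, normalization, housekeeping --------------
        for i in range(n):
            g_e[i] *= de
            g_i[i] *= di
            s[i] = omega * m / rows[i]

        if step % 64 == 63:
            for i in range(n):
                acc = 0.0
                for j in range(m):
                    u[i, j] *= s[i]
                    acc += u[i, j]
                rows[i] = acc
                s[i] = omega * m / acc

        if (step + 1) % snap_stride == 0:
            k = (step + 1) // snap_stride - 1
            if k < snaps.shape[0]:
                for i in range(n):
                    for j in range(m):
                        snaps[k, i, j] = np.float32(s[i] * u[i, j])

    # fold the scale back so u holds the final weights
    for i in range(n):
        for j in range(m):
            u[i, j] *= s[i]
    return n_rec


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        k = rng.permutation(n)
        if not np.any(k == np.arange(n)):
            return k


def run_model2(lif_cfg: LIFConfig | None = None, stdp_cfg: STDPConfig | None = None,
               schedule: SleepSchedule | None = None,
               kappa: float | None = None, gamma: float | None = None,
               seed=0, total_duration: float = 900.0,
               input_cfg: TwoMemoryInputConfig | None = None,
               snapshot_every_s: float = 5.0, ltp_every_steps: int = 10,
               record_spikes: bool = True, n_surrogates: int = 200) -> Model2Result:
    """Full wake → sleep → wake simulation with selectivity tracking.

    ``kappa``/``gamma`` override the schedule's κ_sleep/γ_sleep. The run is
    reproducible under ``seed``; the final selectivity is evaluated at the
    last snapshot. Surrogate significance of T_S and T_H is computed from
    ``n_surrogates`` shuffles of the post-sleep selectivity pattern.
    """
    lif = lif_cfg or LIFConfig()
    stdp = stdp_cfg or STDPConfig()
    sched = schedule or SleepSchedule()
    if kappa is not None or gamma is not None:
        sched = SleepSchedule(
            t_sleep=sched.t_sleep, t_wake=sched.t_wake,
            gamma_sleep=sched.gamma_sleep if gamma is None else gamma,
            kappa_sleep=sched.kappa_sleep if kappa is None else kappa,
            t_ltp_peak=sched.t_ltp_peak, t_ltp_std=sched.t_ltp_std,
            ltp_integral_ns=sched.ltp_integral_ns,
            gamma_literal=sched.gamma_literal, omega=sched.omega)
    inp = input_cfg or TwoMemoryInputConfig()
    if inp.m != lif.m_inputs:
        raise InvalidParameterError("input config and LIF config disagree on m")
    if total_duration <= sched.t_wake:
        raise InvalidParameterError("total_duration must exceed t_wake")

    dt = lif.dt
    n, m = lif.n_neurons, lif.m_inputs
    n_steps = int(round(total_duration / dt))
    snap_stride = max(1, int(round(snapshot_every_s / dt)))
    n_snaps = n_steps // snap_stride

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(3)
    rng = np.random.default_rng(child[0])
    kernel_seed = int(np.random.default_rng(child[1]).integers(0, 2**31 - 1))
    k_ref = _derangement(n, rng)

    u = rng.uniform(0.05, 1.0, size=(n, m))
    w0 = u * (sched.omega / u.mean(axis=1))[:, None]

    theta = np.zeros((n, m))
    w_presleep = np.zeros((n, m))
    snaps = np.zeros((n_snaps, n, m), dtype=np.float32)
    spike_counts = np.zeros(n, dtype=np.int64)
    cap = int(n * total_duration * 60) + 1000 if record_spikes else 1
    spike_buf_t = np.zeros(cap)
    spike_buf_u = np.zeros(cap, dtype=np.int32)

    n_rec = _run_kernel(
        kernel_seed, n_steps, dt, n, m, m // 2,
        lif.tau_m, lif.v_rest, lif.v_threshold, lif.v_reset,
        int(round(lif.refractory_s / dt)), lif.tau_syn_e, lif.tau_syn_i, lif.c_m,
        lif.e_exc, lif.e_inh, lif.inhibition_strength,
        max(1, int(round(lif.inhibition_delay_s / dt))),
        max(1, int(round(inp.window_s / dt))), inp.f_active_hz, inp.f_inactive_hz,
        int(round(sched.t_sleep / dt)), int(round(sched.t_wake / dt)),
        inp.sleep_rate_factor,
        stdp.c_p, stdp.c_d, stdp.tau_stdp, stdp.sigma_v,
        sched.gamma_sleep, sched.gamma_literal,
        sched.kappa_sleep, sched.t_ltp_peak, sched.t_ltp_std,
        sched.ltp_amplitude, int(ltp_every_steps),
        sched.omega, k_ref,
        u, theta, w_presleep,
        snap_stride, snaps, spike_counts, spike_buf_t, spike_buf_u)

    w_final = u
    times = np.concatenate([[0.0], (np.arange(1, n_snaps + 1) * snap_stride) * dt])
    snapshots = np.concatenate([w0[None].astype(np.float32), snaps])

    plan = EmbossingPlan(k_ref=k_ref, theta=theta)
    mem_a, mem_b = inp.memory_a, inp.memory_b
    sel = selectivity_over_time(snapshots, mem_a, mem_b)
    sel_sleep = selectivity_over_time(w_presleep[None], mem_a, mem_b)[0]
    sel_theta = selectivity_over_time(theta[None], mem_a, mem_b)[0]
    sel_final = selectivity_over_time(w_final[None], mem_a, mem_b)[0]
    t_s = proportion_switches(sel_sleep, sel_final)
    t_h = proportion_hits(sel_theta, sel_final)
    surr_seed = np.random.default_rng(child[2])
    surrogate = {}
    for name, obs, ref in (("t_s", t_s, sel_sleep), ("t_h", t_h, sel_theta)):
        try:
            surrogate[name] = surrogate_test(
                obs, sel_final, ref, name, n_surrogates=n_surrogates,
                seed=int(surr_seed.integers(0, 2**31 - 1)))
        except UndefinedResultError:
            # constant reference pattern: the statistic is shuffle-invariant
            surrogate[name] = {"observed": obs, "p": float("nan"),
                               "significant": False, "degenerate": True}
    record = SelectivityRecord(times=times, sel=sel, sel_theta=sel_theta,
                               t_s=t_s, t_h=t_h, surrogate=surrogate)

    spikes = None
    if record_spikes:
        tt = spike_buf_t[:n_rec]
        uu = spike_buf_u[:n_rec]
        per_unit = [np.sort(tt[uu == i]) for i in range(n)]
        # bin-start times can repeat only across units, never within one
        spikes = SpikeRaster(n, total_duration, per_unit, bin_width_s=dt)

    return Model2Result(times=times, snapshots=snapshots, w_presleep=w_presleep,
                        w_final=w_final, plan=plan, spikes=spikes,
                        spike_counts=spike_counts, record=record,
                        schedule=sched, seed=seed)
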