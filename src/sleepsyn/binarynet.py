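"""Fully connected excitatory network of stochastic binary units (Model 1).

Each of the N neurons is a binary unit updated stochastically every
Δt = 4 ms from its total synaptic current

    I_i(t) = w_ie · e_i(t) + (1/(N−1)) · Σ_j w_ij · v_j(t)

through the adjusted sigmoid  P(v_i = 1) = 1 / (1 + exp(K_t − K_s · I_i)).
Recurrent weights are plastic under a stable, weight-dependent Hebbian rule
evaluated on 4 ms co-firing:

* both pre and post fire in the bin:  Δw = C_p · J(w) · Δt with
  J(w) = exp(−w) − exp(−1) (potentiation is larger for weak synapses and
  vanishes at w = 1);
* pre fires, post silent:  Δw = C_d · (0 − θ) · Δt (fixed depression);
* pre silent: no change.

An optional LTP schedule (see :mod:`sleepsyn.sleep_ltp`) adds a per-synapse
Gaussian weight bonus on top of the instantaneous rule.

Update order within a step (fixed convention, stated because it is part of
the model definition): currents are computed from the previous-bin states,
new states are drawn, and plasticity is applied on the new-bin states.
External inputs drive their neuron through w_ie only; they do not enter the
plasticity rule as presynaptic partners.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from sleepsyn.types import InvalidParameterError, SpikeRaster

__all__ = [
    "Model1Config",
    "WeightTrajectory",
    "Model1Simulator",
    "total_current",
    "fire_probability",
    "hebbian_step",
    "simulate_model1",
]


@dataclass
class Model1Config:
    """Parameters of the binary-network model; defaults are the model's
    published operating point (50 neurons is the scaled desk size)."""

    n_neurons: int = 50
    k_t: float = 6.0
    k_s: float = 11.0
    w_ie: float = 0.5
    dt: float = 0.004
    c_p: float = 6.25
    c_d: float = 0.021
    theta: float = 1.0
    w_min: float = 0.0
    w_max: float = 1.5

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise InvalidParameterError("need at least 2 neurons")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.c_p < 0 or self.c_d < 0:
            raise InvalidParameterError("plasticity rates must be >= 0")
        if self.w_max <= self.w_min:
            raise InvalidParameterError("w_max must exceed w_min")


@dataclass
class WeightTrajectory:
    """Time-stamped snapshots of the N×N weight matrix plus run metadata."""

    times: np.ndarray
    weights: np.ndarray  # (n_snapshots, N, N)
    config: Model1Config | None = None
    seed: object = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("snapshot times must be strictly increasing")
        if self.weights.shape[0] != self.times.size:
            raise InvalidParameterError("times/weights length mismatch")

    def at(self, t: float) -> np.ndarray:
        """Snapshot at the latest time ≤ t (within a small tolerance)."""
        idx = int(np.searchsorted(self.times, t + 1e-9, side="right")) - 1
        if idx < 0:
            raise InvalidParameterError(f"no snapshot at or before t={t}")
        return self.weights[idx]

    def window(self, t_start: float, t_end: float) -> "WeightTrajectory":
        sel = (self.times >= t_start - 1e-9) & (self.times <= t_end + 1e-9)
        return WeightTrajectory(self.times[sel], self.weights[sel], self.config, self.seed)


def total_current(v: np.ndarray, w: np.ndarray, e: np.ndarray, cfg: Model1Config) -> np.ndarray:
    """Total synaptic current I_i = w_ie·e_i + (1/(N−1))·Σ_j w_ij·v_j."""
    n = cfg.n_neurons
    v = np.asarray(v, dtype=float)
    e = np.asarray(e, dtype=float)
    if w.shape != (n, n) or v.shape != (n,) or e.shape != (n,):
        raise InvalidParameterError("dimension mismatch between v, w, e and config")
    return cfg.w_ie * e + (w @ v) / (n - 1)


def fire_probability(current: np.ndarray, cfg: Model1Config) -> np.ndarray:
    """Adjusted sigmoid P = 1/(1 + exp(K_t − K_s·I)); values in (0, 1),
    monotone increasing in the current."""
    return 1.0 / (1.0 + np.exp(cfg.k_t - cfg.k_s * np.asarray(current, dtype=float)))


def hebbian_step(v: np.ndarray, w: np.ndarray, cfg: Model1Config) -> np.ndarray:
    """One application of the instantaneous plasticity rule on bin states ``v``.

    Returns a new weight matrix; the diagonal stays zero and values are
    clipped to the configured bounds.
    """
    v = np.asarray(v, dtype=bool)
    w = np.array(w, dtype=float)
    pre = np.flatnonzero(v)
    if pre.size:
        block = w[:, pre]
        dw = np.where(v[:, None],
                      cfg.c_p * (np.exp(-block) - math.exp(-1.0)) * cfg.dt,
                      cfg.c_d * (0.0 - cfg.theta) * cfg.dt)
        w[:, pre] = np.clip(block + dw, cfg.w_min, cfg.w_max)
        np.fill_diagonal(w, 0.0)
    return w


class Model1Simulator:
    """Stateful stepping engine; supports snapshotting, LTP bonuses, online
    convergence detection, and exact state cloning for branch comparisons."""

    def __init__(self, cfg: Model1Config, seed=0, w0: np.ndarray | None = None):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        n = cfg.n_neurons
        if w0 is None:
            w0 = self.rng.uniform(0.0, 1.0, size=(n, n))
        else:
            w0 = np.array(w0, dtype=float)
            if w0.shape != (n, n):
                raise InvalidParameterError("w0 shape mismatch")
        np.fill_diagonal(w0, 0.0)
        self.w = w0
        self.v = np.zeros(n, dtype=bool)
        self.step_index = 0
        self.spike_steps: list[np.ndarray] = []   # per-step firing-unit indices
        self.spike_units: list[np.ndarray] = []
        self._exp_m1 = math.exp(-1.0)
        # firing probabilities for the quiescent network (v = 0), with and
        # without an external spike; same expression as the general path so
        # the fast path is bitwise identical
        self._p0 = float(1.0 / (1.0 + np.exp(cfg.k_t - cfg.k_s * np.float64(0.0))))
        self._pe = float(1.0 / (1.0 + np.exp(cfg.k_t - cfg.k_s * np.float64(cfg.w_ie))))

    @property
    def t(self) -> float:
        return self.step_index * self.cfg.dt

    def clone(self) -> "Model1Simulator":
        """Deep copy (weights, states, RNG stream) for bit-identical branching."""
        return copy.deepcopy(self)

    def step(self, e_t: np.ndarray, ltp_increment: np.ndarray | None = None) -> np.ndarray:
        """Advance one 4 ms bin given the external binary input ``e_t``."""
        cfg = self.cfg
        n = cfg.n_neurons
        if self.v.any():
            current = (self.w @ self.v.astype(float)) / (n - 1)
            if e_t.any():
                current = current + cfg.w_ie * np.asarray(e_t, dtype=float)
            p = 1.0 / (1.0 + np.exp(cfg.k_t - cfg.k_s * current))
        else:
            p = np.where(e_t, self._pe, self._p0)
        v_new = self.rng.random(n) < p
        pre = np.flatnonzero(v_new)
        if pre.size:
            block = self.w[:, pre]
            dw = np.where(v_new[:, None],
                          cfg.c_p * (np.exp(-block) - self._exp_m1) * cfg.dt,
                          -cfg.c_d * cfg.theta * cfg.dt)
            self.w[:, pre] = block + dw
        if ltp_increment is not None:
            self.w += ltp_increment
        if pre.size or ltp_increment is not None:
            np.clip(self.w, cfg.w_min, cfg.w_max, out=self.w)
            np.fill_diagonal(self.w, 0.0)
        self.v = v_new
        self.step_index += 1
        if pre.size:
            self.spike_steps.append(np.full(pre.size, self.step_index - 1, dtype=np.int64))
            self.spike_units.append(pre)
        return v_new

    def network_raster(self) -> SpikeRaster:
        """Network spikes so far as a raster (bin-start times)."""
        n = self.cfg.n_neurons
        if self.spike_steps:
            steps = np.concatenate(self.spike_steps)
            units = np.concatenate(self.spike_units)
        else:
            steps = np.empty(0, dtype=np.int64)
            units = np.empty(0, dtype=np.int64)
        spikes = []
        for u in range(n):
            s = np.sort(steps[units == u]).astype(float) * self.cfg.dt
            spikes.append(s)
        duration = max(self.t, self.cfg.dt)
        return SpikeRaster(n, duration, spikes)

    def run(self, raster: SpikeRaster, t_end: float | None = None,
            ltp=None, snapshot_stride: int = 250,
            stop_on_convergence: bool = False, epsilon: float = 0.00025,
            conv_window_s: float = 100.0, conv_check_every_s: float = 25.0,
            chunk_steps: int = 25_000) -> WeightTrajectory:
        """Drive the network with ``raster`` until ``t_end`` (default: raster end).

        ``ltp`` is an optional :class:`sleepsyn.sleep_ltp.LTPSchedule`; its
        per-step Gaussian increment is added after the Hebbian update. With
        ``stop_on_convergence`` the run halts once every synapse's OLS slope
        over the trailing ``conv_window_s`` (1 s snapshot grid) has magnitude
        ≤ ``epsilon``.
        """
        cfg = self.cfg
        if raster.n_units != cfg.n_neurons:
            raise InvalidParameterError(
                f"raster has {raster.n_units} units, network has {cfg.n_neurons}")
        if t_end is None:
            t_end = raster.duration_s
        if t_end - 1e-9 > raster.duration_s:
            raise InvalidParameterError("raster shorter than requested simulation")
        start_step = self.step_index
        n_steps = int(round(t_end / cfg.dt)) - start_step
        if n_steps < 0:
            raise InvalidParameterError("t_end earlier than current simulator time")

        snap_times = [self.t]
        snaps = [self.w.copy()]
        conv_stride = max(1, int(round(1.0 / cfg.dt)))  # 1 s grid
        win_len = int(round(conv_window_s)) + 1
        ring: list[np.ndarray] = [self.w.copy()]
        check_every = max(1, int(round(conv_check_every_s)))
        since_check = 0

        done = 0
        while done < n_steps:
            m = min(chunk_steps, n_steps - done)
            t0 = self.t
            e_chunk = raster.to_binary(t_start=t0, t_end=t0 + m * cfg.dt, bin_width_s=cfg.dt)
            for k in range(m):
                inc = None if ltp is None else ltp.increment(self.t, cfg.dt)
                self.step(e_chunk[k], inc)
                if self.step_index % snapshot_stride == 0:
                    snap_times.append(self.t)
                    snaps.append(self.w.copy())
                if stop_on_convergence and self.step_index % conv_stride == 0:
                    ring.append(self.w.copy())
                    if len(ring) > win_len:
                        ring.pop(0)
                    since_check += 1
                    if len(ring) == win_len and since_check >= check_every:
                        since_check = 0
                        if self._converged(ring, epsilon):
                            return self._finish(snap_times, snaps)
            done += m
        return self._finish(snap_times, snaps)

    def _converged(self, ring: list[np.ndarray], epsilon: float) -> bool:
        stack = np.stack(ring)  # (T, N, N) on the 1 s grid
        t = np.arange(stack.shape[0], dtype=float)
        t -= t.mean()
        denom = (t ** 2).sum()
        slopes = np.tensordot(t, stack - stack.mean(axis=0), axes=(0, 0)) / denom
        off = ~np.eye(self.cfg.n_neurons, dtype=bool)
        return bool(np.all(np.abs(slopes[off]) <= epsilon))

    def _finish(self, snap_times, snaps) -> WeightTrajectory:
        if not np.isclose(snap_times[-1], self.t):
            snap_times.append(self.t)
            snaps.append(self.w.copy())
        return WeightTrajectory(np.asarray(snap_times), np.stack(snaps),
                                config=self.cfg, seed=self.seed)


def simulate_model1(cfg: Model1Config, external: SpikeRaster, ltp=None,
                    snapshot_stride: int = 250, seed=0, t_end: float | None = None,
                    **run_kwargs) -> tuple[WeightTrajectory, SpikeRaster]:
    """Convenience wrapper: fresh simulator, one run; returns the weight
    trajectory and the network spike raster."""
    sim = Model1Simulator(cfg, seed=seed)
    traj = sim.run(external, t_end=t_end, ltp=ltp, snapshot_stride=snapshot_stride,
                   **run_kwargs)
    return traj, sim.network_raster()
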