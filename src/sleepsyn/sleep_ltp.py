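"""Sleep-dependent LTP for the binary network: per-synapse gains and the
Gaussian long-term bonus.

A single REM episode is selected on a hypnogram; the bonus Gaussian is
triggered at t_T = REM onset + 30 s, peaks μ = 30 min later, and its
amplitude is scaled per synapse by a gain matrix Cieg (modeling
immediate-early-gene modulation). Five gain variants:

* LTP1 (synchrony-based): Cieg_ij is the fraction of presynaptic spikes that
  co-occurred (same 4 ms bin) with a postsynaptic spike, computed over
  (a) the entire SWS episode preceding the selected REM (``ltp1_full_sws``),
  (b) the last 30 s of that SWS episode (``ltp1_30s_sws_end``), or
  (c) those 30 s plus the first 30 s of REM (``ltp1_60s_transition``).
* LTP2 (trajectory-based): the weight trajectory of each synapse is fit by
  OLS over the last 30 s of SWS and the first 30 s of REM; the angle
  β = π − (arctan(m_REM) − arctan(m_SWS)) formed at the transition maps
  linearly onto the gain, Cieg = max(0, 1 − β/β_max), restricted to synapses
  with a positive REM slope. β_max = 3π/2 (``ltp2_permissive``: any positive
  REM slope qualifies) or π (``ltp2_restrictive``: only trajectories that
  turn upward, m_REM > m_SWS).

The per-step bonus is the Gaussian density scaled by Δt, so the
time-integrated bonus per synapse equals Cieg_ij (an order-one total on
weights in [0, 1]); the unscaled per-step density is available via
``scale_by_dt=False``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from sleepsyn.types import Hypnogram, InvalidParameterError, SpikeRaster

__all__ = [
    "VARIANTS",
    "LTPSchedule",
    "TransitionWindows",
    "select_trigger",
    "cieg_ltp1",
    "fit_window_slope",
    "beta_angle",
    "cieg_ltp2",
    "gaussian_bonus",
    "build_schedule",
]

VARIANTS = (
    "ltp1_full_sws",
    "ltp1_30s_sws_end",
    "ltp1_60s_transition",
    "ltp2_permissive",
    "ltp2_restrictive",
)


@dataclass
class TransitionWindows:
    """SWS episode bounds and the two 30 s windows abutting the SWS/REM boundary."""

    sws_start: float
    sws_end: float            # == REM onset
    rem_end: float
    pre_window: tuple[float, float]   # last 30 s of SWS (possibly truncated)
    post_window: tuple[float, float]  # first 30 s of REM


@dataclass
class LTPSchedule:
    """Trigger time, Gaussian parameters and the per-synapse gain matrix."""

    variant: str
    t_trigger: float
    cieg: np.ndarray
    mu: float = 1800.0
    sigma: float = 600.0
    scale_by_dt: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive")
        c = np.asarray(self.cieg, dtype=float)
        if np.any(c < -1e-12) or np.any(c > 1 + 1e-12):
            raise InvalidParameterError("Cieg must lie in [0, 1]")
        if c.ndim == 2 and c.shape[0] == c.shape[1]:
            np.fill_diagonal(c, 0.0)
        self.cieg = c

    @property
    def t_peak(self) -> float:
        return self.t_trigger + self.mu

    def envelope(self, t: float, dt: float) -> float:
        """Scalar Gaussian factor at time ``t`` (0 before the trigger)."""
        if t < self.t_trigger:
            return 0.0
        g = math.exp(-((t - self.t_peak) ** 2) / (2.0 * self.sigma ** 2)) \
            / (self.sigma * math.sqrt(2.0 * math.pi))
        return g * dt if self.scale_by_dt else g

    def increment(self, t: float, dt: float) -> np.ndarray | None:
        """Per-synapse additive weight increment at time ``t`` (None if zero)."""
        g = self.envelope(t, dt)
        if g == 0.0:
            return None
        return self.cieg * g


def gaussian_bonus(t: float, sched: LTPSchedule, dt: float) -> np.ndarray:
    """Per-synapse additive increment matrix at time ``t`` (zeros if inactive)."""
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    inc = sched.increment(t, dt)
    return np.zeros_like(sched.cieg) if inc is None else inc


def select_trigger(hyp: Hypnogram, rem_index: int = 4,
                   window_s: float = 30.0) -> tuple[float, TransitionWindows]:
    """Trigger time and transition windows for the ``rem_index``-th REM episode
    (1-based). t_T = REM onset + 30 s; the pre-window is the last 30 s of the
    preceding SWS episode (truncated with a warning if the episode is
    shorter), the post-window the first 30 s of REM."""
    rems = [(a, b) for s, a, b in hyp.episodes if s == "REM"]
    if rem_index < 1 or rem_index > len(rems):
        raise InvalidParameterError(
            f"hypnogram has {len(rems)} REM episodes, requested #{rem_index}")
    rem_start, rem_end = rems[rem_index - 1]
    if rem_end - rem_start < window_s:
        raise InvalidParameterError(
            f"REM episode #{rem_index} shorter than {window_s} s; cannot evaluate post-window")
    sws = [(a, b) for s, a, b in hyp.episodes if s == "SWS" and np.isclose(b, rem_start)]
    sws_start, sws_end = sws[0]
    pre_lo = sws_end - window_s
    if pre_lo < sws_start:
        warnings.warn(
            f"SWS episode preceding REM #{rem_index} shorter than {window_s} s; "
            "pre-window truncated", stacklevel=2)
        pre_lo = sws_start
    t_trigger = rem_start + window_s
    windows = TransitionWindows(
        sws_start=sws_start, sws_end=sws_end, rem_end=rem_end,
        pre_window=(pre_lo, sws_end), post_window=(rem_start, rem_start + window_s))
    return t_trigger, windows


def cieg_ltp1(network_spikes: SpikeRaster, epoch: tuple[float, float],
              bin_width_s: float = 0.004) -> np.ndarray:
    """Synchrony-based gain: Cieg_ij = (# bins where both i and j fire) /
    (# bins where presynaptic j fires), over ``epoch``; 0 where j is silent."""
    t0, t1 = epoch
    if t1 <= t0:
        raise InvalidParameterError("empty epoch")
    if t0 < 0 or t1 > network_spikes.duration_s + bin_width_s:
        raise InvalidParameterError("epoch outside raster duration")
    b = network_spikes.to_binary(t_start=t0, t_end=t1, bin_width_s=bin_width_s).astype(float)
    both = b.T @ b                      # [i, j] = # bins i and j co-fire
    pre_counts = b.sum(axis=0)          # per presynaptic unit
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(pre_counts > 0, both / pre_counts[None, :], 0.0)
    np.fill_diagonal(c, 0.0)
    return c


def fit_window_slope(traj, window: tuple[float, float]) -> np.ndarray:
    """Per-synapse OLS slope (s⁻¹) of w_ij(t) over snapshots inside ``window``."""
    sub = traj.window(*window)
    if sub.times.size < 3:
        raise InvalidParameterError(
            f"need >= 3 snapshots in window {window}, found {sub.times.size}")
    t = sub.times - sub.times.mean()
    denom = (t ** 2).sum()
    return np.tensordot(t, sub.weights - sub.weights.mean(axis=0), axes=(0, 0)) / denom


def beta_angle(m_sws, m_rem) -> np.ndarray:
    """Angle β (radians) formed by the weight trajectory at the SWS/REM
    transition: β = π − (arctan(m_REM) − arctan(m_SWS)).

    Collinear segments give β = π; an upward turn (m_REM > m_SWS) gives
    β < π; any positive REM slope gives β < 3π/2.
    """
    return np.pi - (np.arctan(np.asarray(m_rem, dtype=float))
                    - np.arctan(np.asarray(m_sws, dtype=float)))


def cieg_ltp2(m_sws: np.ndarray, m_rem: np.ndarray, variant: str) -> np.ndarray:
    """Trajectory-based gain: zero unless the REM slope is positive, otherwise
    linear in the transition angle, Cieg = max(0, 1 − β/β_max)."""
    if variant == "ltp2_permissive":
        beta_max = 1.5 * np.pi
    elif variant == "ltp2_restrictive":
        beta_max = np.pi
    else:
        raise InvalidParameterError(f"unknown LTP2 variant {variant!r}")
    beta = beta_angle(m_sws, m_rem)
    c = np.maximum(0.0, 1.0 - beta / beta_max)
    c = np.where(np.asarray(m_rem) > 0, c, 0.0)
    if c.ndim == 2 and c.shape[0] == c.shape[1]:
        np.fill_diagonal(c, 0.0)
    return c


def build_schedule(variant: str, hyp: Hypnogram, rem_index: int,
                   traj=None, network_spikes: SpikeRaster | None = None,
                   mu: float = 1800.0, sigma: float = 600.0,
                   scale_by_dt: bool = True, window_s: float = 30.0) -> LTPSchedule:
    """Assemble an :class:`LTPSchedule` for one of the five variants.

    LTP1 variants need the network spike raster up to the trigger; LTP2
    variants need a weight trajectory with ≥ 3 snapshots in each 30 s
    transition window.
    """
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    t_trigger, win = select_trigger(hyp, rem_index, window_s=window_s)
    if variant.startswith("ltp1"):
        if network_spikes is None:
            raise InvalidParameterError("LTP1 variants require the network spike raster")
        if variant == "ltp1_full_sws":
            epoch = (win.sws_start, win.sws_end)
        elif variant == "ltp1_30s_sws_end":
            epoch = win.pre_window
        else:  # ltp1_60s_transition
            epoch = (win.pre_window[0], win.post_window[1])
        cieg = cieg_ltp1(network_spikes, epoch)
    else:
        if traj is None:
            raise InvalidParameterError("LTP2 variants require a weight trajectory")
        m_sws = fit_window_slope(traj, win.pre_window)
        m_rem = fit_window_slope(traj, win.post_window)
        cieg = cieg_ltp2(m_sws, m_rem, variant)
    return LTPSchedule(variant=variant, t_trigger=t_trigger, cieg=cieg,
                       mu=mu, sigma=sigma, scale_by_dt=scale_by_dt)
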