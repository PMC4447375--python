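"""Synthetic spike rasters, hypnograms and two-memory input drives.

The generators reproduce the statistical structure the simulators assume:

* homogeneous Poisson rasters at arbitrary rates (the non-correlated input
  regime used for the rate sweeps);
* correlated rasters built from a shared mother train, hitting a target mean
  pairwise binned Pearson correlation while preserving the per-unit rate;
* hypnograms of alternating WK → SWS → REM cycles with log-normal episode
  durations calibrated so the mean SWS episode lasts ≈ 87 s and ≈ 91.6 % of
  REM-onset-to-REM-onset intervals are shorter than 30 min;
* state-conditioned rasters following a hypnogram, with per-state rates
  ordered WK > REM > SWS and synchrony ordered WK > SWS > REM;
* the two-memory alternating Poisson drive of the hippocampo-cortical model.

All generators are deterministic under their ``seed`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from sleepsyn.types import (
    Hypnogram,
    InvalidParameterError,
    SpikeRaster,
    StateStats,
    TwoMemoryInputConfig,
    STATES,
)

__all__ = [
    "gen_poisson_raster",
    "gen_correlated_raster",
    "gen_hypnogram",
    "gen_state_raster",
    "gen_two_memory_input",
    "HypnogramParams",
    "read_raster",
    "write_raster",
    "read_hypnogram",
    "write_hypnogram",
]


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration): count then order statistics."""
    if rate == 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    # strict monotonicity: perturb exact duplicates (measure-zero but finite floats)
    dup = np.flatnonzero(np.diff(t) == 0)
    while dup.size:
        t[dup + 1] = np.nextafter(t[dup + 1], np.inf)
        t = np.sort(t)
        dup = np.flatnonzero(np.diff(t) == 0)
    return t[t < duration]


def gen_poisson_raster(n: int, rate: float, duration: float, seed) -> SpikeRaster:
    """Independent homogeneous Poisson spike trains.

    Parameters
    ----------
    n: number of units.
    rate: mean rate in Hz (≥ 0; 0 yields an empty raster).
    duration: raster duration in seconds (> 0).
    seed: anything accepted by :func:`numpy.random.default_rng`.
    """
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    spikes = [_poisson_times(rng, rate, duration) for _ in range(n)]
    return SpikeRaster(n, duration, spikes)


def gen_correlated_raster(n: int, rate: float, corr_target: float,
                          duration: float, seed,
                          heterogeneity: float = 0.0) -> SpikeRaster:
    """Poisson trains with a target mean pairwise binned Pearson correlation.

    Mechanism: a mother Poisson train at the unit rate is thinned into every
    unit with a per-unit copy probability q_u centred on ``sqrt(corr_target)``;
    the remaining rate is filled with independent Poisson spikes so each
    unit's mean rate is preserved. For sparse 4 ms bins the binned Pearson
    correlation of units u and v is ≈ q_u·q_v, so the mean pairwise
    correlation matches the target.

    ``heterogeneity`` in [0, 1] spreads the copy probabilities uniformly over
    sqrt(corr_target)·[1−h, 1+h] (mean preserved), mimicking the structured
    pairwise-synchrony matrices of real population recordings; 0 gives a
    homogeneous correlation matrix.
    """
    if not (0 <= corr_target < 1):
        raise InvalidParameterError("corr_target must be in [0, 1)")
    if not (0 <= heterogeneity <= 1):
        raise InvalidParameterError("heterogeneity must be in [0, 1]")
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    if corr_target == 0 or rate == 0:
        spikes = [_poisson_times(rng, rate, duration) for _ in range(n)]
        return SpikeRaster(n, duration, spikes)
    q0 = math.sqrt(corr_target)
    q = np.clip(q0 * (1.0 + heterogeneity * (2.0 * rng.random(n) - 1.0)), 0.0, 1.0)
    mother = _poisson_times(rng, rate, duration)
    spikes = []
    for u in range(n):
        keep = mother[rng.random(mother.size) < q[u]]
        own = _poisson_times(rng, rate * (1.0 - q[u]), duration)
        t = np.unique(np.concatenate([keep, own]))
        spikes.append(t)
    return SpikeRaster(n, duration, spikes)


@dataclass
class HypnogramParams:
    """Log-normal episode-duration parameters (natural-log mean and sd).

    Defaults are calibrated to two printed statistics of rat sleep
    architecture: mean SWS episode duration ≈ 87 s, and ≈ 91.6 % of
    REM-onset-to-REM-onset intervals below 30 min. The WK tail (σ ≈ 1.3)
    carries the > 30 min intervals: long waking bouts, not long sleep
    episodes, separate distant REM episodes.
    """

    wk_mu_log: float = 5.60
    wk_sigma_log: float = 1.30
    sws_mu_log: float = 4.338
    sws_sigma_log: float = 0.506
    rem_mu_log: float = 4.60
    rem_sigma_log: float = 0.44
    min_episode_s: float = 10.0

    def __post_init__(self) -> None:
        for name in ("wk_sigma_log", "sws_sigma_log", "rem_sigma_log", "min_episode_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


def gen_hypnogram(n_cycles: int, params: HypnogramParams | None = None, seed=0) -> Hypnogram:
    """Alternating WK → SWS → REM cycles with log-normal episode durations.

    Every REM episode is preceded by SWS by construction; episode durations
    are floored at ``params.min_episode_s`` so that transition windows around
    SWS/REM boundaries remain evaluable.
    """
    if n_cycles < 1:
        raise InvalidParameterError("n_cycles must be >= 1")
    p = params or HypnogramParams()
    rng = np.random.default_rng(seed)
    episodes = []
    t = 0.0
    for _ in range(n_cycles):
        for state, mu, sig in (("WK", p.wk_mu_log, p.wk_sigma_log),
                               ("SWS", p.sws_mu_log, p.sws_sigma_log),
                               ("REM", p.rem_mu_log, p.rem_sigma_log)):
            d = max(float(rng.lognormal(mu, sig)), p.min_episode_s)
            episodes.append((state, t, t + d))
            t += d
    return Hypnogram(episodes)


def gen_state_raster(hyp: Hypnogram, stats: StateStats | None, n: int, seed=0,
                     heterogeneity: float = 1.0) -> SpikeRaster:
    """State-conditioned raster: within each episode units follow the
    correlated-Poisson generator with that state's rate and synchrony.

    Pairwise synchrony is heterogeneous across unit pairs by default (as in
    real population recordings, where the correlation matrix is structured);
    the per-episode mean pairwise correlation still matches the state target.
    """
    stats = stats or StateStats()
    rng = np.random.default_rng(seed)
    spikes = [[] for _ in range(n)]
    for state, a, b in hyp.episodes:
        dur = b - a
        if dur <= 0:
            continue
        sub = gen_correlated_raster(n, stats.rates_hz[state], stats.corrs[state],
                                    dur, rng.integers(0, 2**31 - 1),
                                    heterogeneity=heterogeneity)
        for u in range(n):
            spikes[u].append(sub.spikes[u] + a)
    merged = [np.concatenate(s) if s else np.empty(0) for s in spikes]
    return SpikeRaster(n, hyp.duration_s, merged)


def gen_two_memory_input(cfg: TwoMemoryInputConfig, duration: float, seed=0
                         ) -> tuple[SpikeRaster, np.ndarray]:
    """Two-memory alternating Poisson drive plus per-window labels.

    In each 125 ms window one memory, drawn uniformly, is active: its units
    fire at ``f_active_hz``, the others at ``f_inactive_hz``; both rates are
    multiplied by ``sleep_rate_factor`` for windows inside
    ``[t_sleep, t_wake)``. Returns the raster and an array of labels
    (``'A'``/``'B'``), one per complete window (a final partial window is
    truncated).
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n_windows = int(duration / cfg.window_s + 1e-9)
    labels = np.where(rng.random(n_windows) < 0.5, "A", "B")
    a_ids, b_ids = set(cfg.memory_a.tolist()), set(cfg.memory_b.tolist())
    if a_ids & b_ids:
        raise InvalidParameterError("memory id sets overlap")
    spikes = [[] for _ in range(cfg.m)]
    half = cfg.m // 2
    for w, lab in enumerate(labels):
        t0 = w * cfg.window_s
        factor = 1.0
        if cfg.t_sleep is not None and cfg.t_wake is not None and cfg.t_sleep <= t0 < cfg.t_wake:
            factor = cfg.sleep_rate_factor
        f_act = cfg.f_active_hz * factor
        f_ina = cfg.f_inactive_hz * factor
        for u in range(cfg.m):
            in_a = u < half
            rate = f_act if (lab == "A") == in_a else f_ina
            t = _poisson_times(rng, rate, cfg.window_s)
            if t.size:
                spikes[u].append(t + t0)
    merged = [np.concatenate(s) if s else np.empty(0) for s in spikes]
    return SpikeRaster(cfg.m, n_windows * cfg.window_s, merged), labels


# ---------------------------------------------------------------------------
# CSV I/O
#
# Spike raster dialect: first line `# n_units=<int> duration_s=<float>`,
# then header `unit_id,time_s`, one row per spike.
# Hypnogram dialect: header `state,start_s,end_s`, states exactly WK|SWS|REM.
# ---------------------------------------------------------------------------


class RasterParseError(ValueError):
    pass


def write_raster(raster: SpikeRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_units={raster.n_units} duration_s={float(raster.duration_s)!r}\n")
        fh.write("unit_id,time_s\n")
        for u, t in enumerate(raster.spikes):
            for x in t:
                fh.write(f"{u},{float(x)!r}\n")


def read_raster(path, bin_width_s: float = 0.004) -> SpikeRaster:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise RasterParseError("line 1: missing '# n_units=... duration_s=...' header")
    meta = dict(tok.split("=") for tok in lines[0][1:].split())
    try:
        n_units = int(meta["n_units"])
        duration = float(meta["duration_s"])
    except (KeyError, ValueError) as exc:
        raise RasterParseError(f"line 1: bad metadata header ({exc})") from exc
    if len(lines) < 2 or lines[1].strip() != "unit_id,time_s":
        raise RasterParseError("line 2: expected header 'unit_id,time_s'")
    spikes: list[list[float]] = [[] for _ in range(n_units)]
    for ln, row in enumerate(lines[2:], start=3):
        if not row.strip():
            continue
        parts = row.split(",")
        try:
            u = int(parts[0])
            t = float(parts[1])
        except (IndexError, ValueError) as exc:
            raise RasterParseError(f"line {ln}: malformed row {row!r}") from exc
        if not 0 <= u < n_units:
            raise RasterParseError(f"line {ln}: unit_id {u} out of range")
        if spikes[u] and t <= spikes[u][-1]:
            raise RasterParseError(f"line {ln}: spike times not strictly increasing for unit {u}")
        spikes[u].append(t)
    return SpikeRaster(n_units, duration, [np.asarray(s) for s in spikes], bin_width_s)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("state,start_s,end_s\n")
        for state, a, b in hyp.episodes:
            fh.write(f"{state},{float(a)!r},{float(b)!r}\n")


def read_hypnogram(path) -> Hypnogram:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "state,start_s,end_s":
        raise RasterParseError("line 1: expected header 'state,start_s,end_s'")
    episodes = []
    for ln, row in enumerate(lines[1:], start=2):
        if not row.strip():
            continue
        parts = row.split(",")
        if len(parts) != 3:
            raise RasterParseError(f"line {ln}: malformed row {row!r}")
        state = parts[0].strip()
        if state not in STATES:
            raise RasterParseError(f"line {ln}: unknown state label {state!r}")
        try:
            a, b = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise RasterParseError(f"line {ln}: malformed row {row!r}") from exc
        episodes.append((state, a, b))
    if not episodes:
        raise RasterParseError("hypnogram file contains no episodes")
    return Hypnogram(episodes)
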