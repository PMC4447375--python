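"""Core domain containers: spike rasters, hypnograms, state statistics.

These are deliberately thin dataclasses with eager validation; all heavy
lifting (generation, simulation, metrics) lives in the dedicated modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

STATES = ("WK", "SWS", "REM")


class InvalidParameterError(ValueError):
    """Raised when an operation receives out-of-domain parameters."""


@dataclass
class SpikeRaster:
    """Per-unit spike times in seconds over a fixed recording duration.

    Parameters
    ----------
    n_units:
        Number of units (spike trains).
    duration_s:
        Total duration; all spike times must lie in ``[0, duration_s)``.
    spikes:
        One sorted ``float`` array of spike times per unit.
    bin_width_s:
        Width used by :meth:`to_binary`; 4 ms by default, the synchrony
        window of the binary network model.
    """

    n_units: int
    duration_s: float
    spikes: list[np.ndarray]
    bin_width_s: float = 0.004

    def __post_init__(self) -> None:
        if self.n_units != len(self.spikes):
            raise InvalidParameterError(
                f"n_units={self.n_units} but {len(self.spikes)} spike trains given"
            )
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        clean = []
        for u, t in enumerate(self.spikes):
            t = np.asarray(t, dtype=float)
            if t.ndim != 1:
                raise InvalidParameterError(f"unit {u}: spike times must be 1-D")
            if t.size and (t[0] < 0 or t[-1] >= self.duration_s):
                raise InvalidParameterError(
                    f"unit {u}: spike times outside [0, {self.duration_s})"
                )
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise InvalidParameterError(f"unit {u}: spike times not strictly increasing")
            clean.append(t)
        self.spikes = clean

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.duration_s / self.bin_width_s - 1e-9))

    def counts(self) -> np.ndarray:
        """Spike count per unit."""
        return np.array([t.size for t in self.spikes])

    def rates(self) -> np.ndarray:
        """Mean firing rate per unit in Hz."""
        return self.counts() / self.duration_s

    def to_binary(self, t_start: float = 0.0, t_end: float | None = None,
                  bin_width_s: float | None = None) -> np.ndarray:
        """Binned binary matrix (n_bins × n_units); ≥2 spikes per bin collapse to 1.

        The binary collapse matches the two-state neuron model driven by the
        raster: a unit is either active or silent within a bin.
        """
        bw = self.bin_width_s if bin_width_s is None else bin_width_s
        if t_end is None:
            t_end = self.duration_s
        n_bins = int(round((t_end - t_start) / bw))
        out = np.zeros((n_bins, self.n_units), dtype=bool)
        for u, t in enumerate(self.spikes):
            tt = t[(t >= t_start) & (t < t_start + n_bins * bw)]
            idx = np.floor((tt - t_start) / bw).astype(np.int64)
            idx = idx[idx < n_bins]
            out[idx, u] = True
        return out

    def slice(self, t_start: float, t_end: float) -> "SpikeRaster":
        """Sub-raster on [t_start, t_end), times re-referenced to t_start."""
        spikes = [t[(t >= t_start) & (t < t_end)] - t_start for t in self.spikes]
        return SpikeRaster(self.n_units, t_end - t_start, spikes, self.bin_width_s)


@dataclass
class Hypnogram:
    """Ordered, contiguous, non-overlapping state episodes over {WK, SWS, REM}.

    Invariants enforced at construction: episodes sorted and contiguous, each
    with positive duration, no two consecutive episodes share a state, and
    every REM episode is immediately preceded by SWS (REM onset from waking
    is not physiological in the rat sleep architecture modeled here).
    """

    episodes: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        eps = [(str(s), float(a), float(b)) for s, a, b in self.episodes]
        prev_end = None
        prev_state = None
        for i, (state, a, b) in enumerate(eps):
            if state not in STATES:
                raise InvalidParameterError(f"episode {i}: unknown state {state!r}")
            if b <= a:
                raise InvalidParameterError(f"episode {i}: end {b} <= start {a}")
            if prev_end is not None and not np.isclose(a, prev_end):
                raise InvalidParameterError(f"episode {i}: gap/overlap at {a} (prev end {prev_end})")
            if state == prev_state:
                raise InvalidParameterError(f"episode {i}: repeats state {state}")
            if state == "REM" and prev_state != "SWS":
                raise InvalidParameterError(f"episode {i}: REM not preceded by SWS")
            prev_end, prev_state = b, state
        self.episodes = eps

    @property
    def duration_s(self) -> float:
        return self.episodes[-1][2]

    def state_at(self, t: float) -> str:
        for state, a, b in self.episodes:
            if a <= t < b:
                return state
        raise InvalidParameterError(f"time {t} outside hypnogram")

    def episodes_of(self, state: str) -> list[tuple[float, float]]:
        return [(a, b) for s, a, b in self.episodes if s == state]

    def rem_onsets(self) -> np.ndarray:
        return np.array([a for s, a, _ in self.episodes if s == "REM"])

    def rem_to_rem_intervals(self) -> np.ndarray:
        """Intervals between consecutive REM episode onsets, in seconds."""
        onsets = self.rem_onsets()
        return np.diff(onsets)


@dataclass
class StateStats:
    """Per-state firing statistics used to emulate state-conditioned rasters.

    ``rates_hz`` and ``corrs`` map state → mean unit rate and target mean
    pairwise binned Pearson correlation. Defaults respect the orderings seen
    in rat CA1: rates WK > REM > SWS, synchrony WK > SWS > REM.
    """

    rates_hz: dict = field(default_factory=lambda: {"WK": 10.0, "REM": 7.5, "SWS": 5.0})
    corrs: dict = field(default_factory=lambda: {"WK": 0.06, "SWS": 0.03, "REM": 0.005})

    def __post_init__(self) -> None:
        for st in STATES:
            if st not in self.rates_hz or st not in self.corrs:
                raise InvalidParameterError(f"statistics missing for state {st}")
            if self.rates_hz[st] <= 0:
                raise InvalidParameterError(f"{st}: mean rate must be > 0")
            if not (0 <= self.corrs[st] < 1):
                raise InvalidParameterError(f"{st}: correlation target must be in [0, 1)")


@dataclass
class TwoMemoryInputConfig:
    """Two-memory alternating Poisson input drive for the LIF network.

    200 input units split into memory A (ids 0..99) and memory B
    (ids 100..199); in every 125 ms window exactly one memory is active
    (f_active = 20 Hz) and the other inactive (f_inactive = 10 Hz); both
    rates are halved inside the sleep interval.
    """

    m: int = 200
    f_active_hz: float = 20.0
    f_inactive_hz: float = 10.0
    window_s: float = 0.125
    t_sleep: float | None = None
    t_wake: float | None = None
    sleep_rate_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.m % 2:
            raise InvalidParameterError("m must be even (two equal memories)")
        if not (self.f_active_hz > self.f_inactive_hz > 0):
            raise InvalidParameterError("need f_active > f_inactive > 0")
        if self.window_s <= 0:
            raise InvalidParameterError("window_s must be positive")

    @property
    def memory_a(self) -> np.ndarray:
        return np.arange(self.m // 2)

    @property
    def memory_b(self) -> np.ndarray:
        return np.arange(self.m // 2, self.m)
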