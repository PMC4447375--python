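"""Weight-pattern metrics for the binary network.

Rescaling vs restructuring of a synaptic weight pattern are distinguished by
two complementary metrics against a reference snapshot: the similarity index
(normalized inverse of the summed absolute differences — drops under any
change, including uniform rescaling) and the Spearman rank correlation of the
off-diagonal weights (drops only when the *ordering* of synaptic strengths is
reorganized). Net change is summarized by M_Δw, the mean element-wise
difference over the N(N−1) off-diagonal entries, and steady state is declared
when every synapse's weight drifts slower than ε = 2.5×10⁻⁴ s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from sleepsyn.types import InvalidParameterError

__all__ = [
    "UndefinedResultError",
    "MetricSeries",
    "net_weight_change",
    "similarity_index",
    "abs_difference_sum",
    "spearman_weights",
    "convergence_time",
    "distribution_stats",
    "metric_series",
]


class UndefinedResultError(ValueError):
    """Raised when a metric is mathematically undefined for the given input."""


@dataclass
class MetricSeries:
    """A named metric evaluated over trajectory snapshot times."""

    times: np.ndarray
    values: np.ndarray
    metric: str
    reference_time: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.times.shape != self.values.shape:
            raise InvalidParameterError("times/values shape mismatch")


def _off_diagonal(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidParameterError("weight matrix must be square")
    return w[~np.eye(w.shape[0], dtype=bool)]


def _check_same_shape(w1: np.ndarray, w2: np.ndarray) -> None:
    if np.shape(w1) != np.shape(w2):
        raise InvalidParameterError("weight matrices differ in size")


def net_weight_change(w1: np.ndarray, w2: np.ndarray) -> float:
    """M_Δw = Σ_{i≠j} (w2_ij − w1_ij) / (N(N−1)); negative = net downscaling."""
    _check_same_shape(w1, w2)
    return float(np.mean(_off_diagonal(np.asarray(w2) - np.asarray(w1))))


def abs_difference_sum(w: np.ndarray, ref: np.ndarray) -> float:
    """Raw sum of absolute off-diagonal differences to the reference pattern."""
    _check_same_shape(w, ref)
    return float(np.sum(np.abs(_off_diagonal(np.asarray(w) - np.asarray(ref)))))


def similarity_index(w: np.ndarray, ref: np.ndarray) -> float:
    """SI = 1 − mean |w − ref| over off-diagonal entries; 1 for identical
    patterns, 0 when every entry differs by a full weight unit."""
    n = np.shape(w)[0]
    return 1.0 - abs_difference_sum(w, ref) / (n * (n - 1))


def spearman_weights(w: np.ndarray, ref: np.ndarray) -> float:
    """Spearman rank correlation of the vectorized off-diagonal weights
    against the reference pattern (average ranks for ties)."""
    _check_same_shape(w, ref)
    a = _off_diagonal(w)
    b = _off_diagonal(ref)
    if a.size < 2:
        raise InvalidParameterError("need >= 2 off-diagonal entries")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedResultError("constant weight pattern: rank correlation undefined")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def convergence_time(traj, epsilon: float = 0.00025, window_s: float = 100.0) -> float | None:
    """First snapshot time at which every synapse's OLS slope over the
    trailing ``window_s`` has magnitude ≤ ε; ``None`` if never reached.

    The trailing window must contain ≥ 3 snapshots; a window longer than the
    trajectory raises.
    """
    times = traj.times
    if times[-1] - times[0] < window_s:
        raise InvalidParameterError("window longer than trajectory")
    n = traj.weights.shape[1]
    off = ~np.eye(n, dtype=bool)
    for k in range(times.size):
        t_hi = times[k]
        lo = np.searchsorted(times, t_hi - window_s - 1e-9)
        if k - lo + 1 < 3 or times[k] - times[lo] < window_s - 1e-6:
            continue
        t = times[lo:k + 1]
        wts = traj.weights[lo:k + 1]
        tc = t - t.mean()
        slopes = np.tensordot(tc, wts - wts.mean(axis=0), axes=(0, 0)) / (tc ** 2).sum()
        if np.all(np.abs(slopes[off]) <= epsilon):
            return float(t_hi)
    return None


def distribution_stats(w: np.ndarray, bins: int = 20,
                       hist_range: tuple[float, float] = (0.0, 1.5)) -> dict:
    """Mean, standard deviation and normalized histogram of off-diagonal weights."""
    vals = _off_diagonal(w)
    hist, edges = np.histogram(vals, bins=bins, range=hist_range)
    total = hist.sum()
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std()),
        "hist": hist / total if total else hist.astype(float),
        "bin_edges": edges,
    }


def metric_series(traj, metric: str, reference_time: float = 0.0) -> MetricSeries:
    """Evaluate ``similarity``, ``spearman`` or ``mean_weight`` at every
    snapshot of a trajectory against the snapshot at ``reference_time``."""
    ref = traj.at(reference_time)
    values = []
    for w in traj.weights:
        if metric == "similarity":
            values.append(similarity_index(w, ref))
        elif metric == "spearman":
            values.append(spearman_weights(w, ref))
        elif metric == "mean_weight":
            values.append(float(np.mean(_off_diagonal(w))))
        else:
            raise InvalidParameterError(f"unknown metric {metric!r}")
    return MetricSeries(traj.times, np.asarray(values), metric, reference_time)
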