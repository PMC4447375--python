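"""Memory selectivity, switch/hit proportions and surrogate significance for
the hippocampo-cortical model.

A principal neuron's memory selectivity at time t compares the summed input
weights from the two memories:

    Sel_i = +1 if Σ_{j∈A} W_ij > Σ_{j∈B} W_ij, −1 if <, 0 if equal.

Sleep-induced reorganization is summarized by two proportions over the 45
principal neurons:

* T_S — proportion of *switches*: neurons with Sel_i[t_sleep]·Sel_i[∞] = −1;
* T_H — proportion of *LTP hits*: neurons whose final selectivity matches the
  selectivity imposed by the embossing gain, Sel_θ_i[t_sleep]·Sel_i[∞] = +1.

Zero-selectivity neurons count as neither switch nor hit (the Heaviside of a
non-positive product is taken as 0). Significance is assessed against 200
surrogates obtained by shuffling the post-sleep selectivity labels across
neurons, recomputing the statistic per shuffle, and fitting a normal
distribution to the surrogate values (two-sided p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from sleepsyn.types import InvalidParameterError
from sleepsyn.weight_metrics import UndefinedResultError

__all__ = [
    "SelectivityRecord",
    "selectivity",
    "selectivity_over_time",
    "ltp_selectivity",
    "proportion_switches",
    "proportion_hits",
    "surrogate_test",
]


@dataclass
class SelectivityRecord:
    """Per-neuron selectivity over time plus the sleep-reorganization summary."""

    times: np.ndarray                 # snapshot times (s)
    sel: np.ndarray                   # (n_snapshots, n_neurons) in {1, -1, 0}
    sel_theta: np.ndarray | None      # per-neuron selectivity imposed by LTP
    t_s: float | None = None
    t_h: float | None = None
    surrogate: dict = field(default_factory=dict)   # statistic -> test summary


def _sign_compare(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.zeros(a.shape[:-1] if a.ndim > 1 else (), dtype=np.int8)
    out = np.where(a > b, 1, np.where(a < b, -1, 0)).astype(np.int8)
    return out


def selectivity(w_row: np.ndarray, memory_a: np.ndarray, memory_b: np.ndarray) -> int:
    """Selectivity of one neuron from its input-weight row: sign of
    Σ_A W − Σ_B W (strict comparison; exact ties give 0)."""
    w_row = np.asarray(w_row, dtype=float)
    a_ids = np.asarray(memory_a)
    b_ids = np.asarray(memory_b)
    if np.intersect1d(a_ids, b_ids).size:
        raise InvalidParameterError("memory id sets overlap")
    sa = w_row[a_ids].sum()
    sb = w_row[b_ids].sum()
    return int(np.sign(sa - sb))


def selectivity_over_time(snapshots: np.ndarray, memory_a: np.ndarray,
                          memory_b: np.ndarray) -> np.ndarray:
    """Vectorized selectivity for a (T, n, m) stack of weight snapshots."""
    snaps = np.asarray(snapshots, dtype=float)
    sa = snaps[..., np.asarray(memory_a)].sum(axis=-1)
    sb = snaps[..., np.asarray(memory_b)].sum(axis=-1)
    return _sign_compare(sa, sb)


def ltp_selectivity(theta_row: np.ndarray, memory_a: np.ndarray,
                    memory_b: np.ndarray) -> int:
    """Selectivity imposed by the embossing gain row θ_i (same sign rule)."""
    return selectivity(theta_row, memory_a, memory_b)


def proportion_switches(sel_sleep: np.ndarray, sel_final: np.ndarray) -> float:
    """T_S: fraction of neurons whose selectivity product is −1 across sleep."""
    sel_sleep = np.asarray(sel_sleep)
    sel_final = np.asarray(sel_final)
    if sel_sleep.shape != sel_final.shape:
        raise InvalidParameterError("selectivity vectors differ in length")
    return float(np.mean(sel_sleep * sel_final == -1))


def proportion_hits(sel_theta: np.ndarray, sel_final: np.ndarray) -> float:
    """T_H: fraction of neurons whose final selectivity matches the
    LTP-imposed selectivity (product +1)."""
    sel_theta = np.asarray(sel_theta)
    sel_final = np.asarray(sel_final)
    if sel_theta.shape != sel_final.shape:
        raise InvalidParameterError("selectivity vectors differ in length")
    return float(np.mean(sel_theta * sel_final == 1))


def surrogate_test(observed: float, sel_final: np.ndarray, reference: np.ndarray,
                   statistic: str, n_surrogates: int = 200, seed=0) -> dict:
    """Shuffle-based significance of an observed T_S or T_H value.

    The post-sleep selectivity vector is permuted across neurons
    ``n_surrogates`` times; the statistic is recomputed per shuffle against
    the fixed ``reference`` vector (pre-sleep selectivity for ``"t_s"``,
    LTP-imposed selectivity for ``"t_h"``); a normal fit to the surrogate
    values yields a two-sided p and the central p > 0.05 non-significance
    interval.
    """
    if n_surrogates < 2:
        raise InvalidParameterError("need at least 2 surrogates")
    if statistic == "t_s":
        stat = proportion_switches
    elif statistic == "t_h":
        stat = proportion_hits
    else:
        raise InvalidParameterError(f"unknown statistic {statistic!r}")
    sel_final = np.asarray(sel_final)
    reference = np.asarray(reference)
    rng = np.random.default_rng(seed)
    surr = np.empty(n_surrogates)
    for k in range(n_surrogates):
        surr[k] = stat(reference, rng.permutation(sel_final))
    mu = float(surr.mean())
    sd = float(surr.std(ddof=1))
    if sd == 0:
        raise UndefinedResultError("degenerate (constant) surrogate distribution")
    z = (observed - mu) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    half = float(stats.norm.ppf(0.975) * sd)
    return {
        "observed": float(observed),
        "surrogate_mean": mu,
        "surrogate_sd": sd,
        "z": float(z),
        "p": p,
        "nonsignificance_interval": (mu - half, mu + half),
        "significant": p < 0.05,
    }
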