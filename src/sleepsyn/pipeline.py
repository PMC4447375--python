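"""Experiment orchestration: rate sweeps, LTP-variant comparisons and the
sleep-modulation (γ × κ) grid.

Every experiment is reproducible from its serialized configuration: all
seeds are recorded in the output tables, and per-seed child seeds are derived
with :class:`numpy.random.SeedSequence` so runs are independent of execution
order.

Desk-scale defaults (50 binary neurons, 5–10 seeds, shortened sleep
schedules) keep each experiment in the minutes range; full-scale settings
are reached by passing larger configs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sleepsyn.types import Hypnogram, InvalidParameterError, StateStats
from sleepsyn import synthgen
from sleepsyn.binarynet import Model1Config, Model1Simulator
from sleepsyn.sleep_ltp import VARIANTS, build_schedule, select_trigger
from sleepsyn import weight_metrics
from sleepsyn.lifnet import LIFConfig, STDPConfig, SleepSchedule, run_model2

__all__ = [
    "ExperimentConfig",
    "run_to_convergence",
    "sweep_rates",
    "compare_ltp_variants",
    "sweep_sleep_grid",
    "report",
]


@dataclass
class ExperimentConfig:
    """Provenance record serialized next to every experiment's outputs."""

    experiment_id: str
    params: dict = field(default_factory=dict)
    seeds: list = field(default_factory=list)
    output_dir: str | None = None
    snapshot_stride: int = 250

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def save(self, directory) -> Path:
        path = Path(directory) / "config.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json())
        return path


def _child_seed(root_seed, *key: int) -> int:
    """Deterministic per-task seed below 2**31."""
    ss = np.random.SeedSequence([int(root_seed)] + [int(k) for k in key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def run_to_convergence(rate_hz: float, cfg: Model1Config | None = None, seed=0,
                       max_duration: float = 6000.0, epsilon: float = 0.00025,
                       conv_window_s: float = 100.0) -> dict:
    """One binary-network run on independent Poisson inputs, halted at the
    steady-state criterion (|dw/dt| ≤ ε for every synapse over the trailing
    window) or at ``max_duration``.

    Returns the converged mean/sd of the off-diagonal weights, the net weight
    change M_Δw from the initial matrix, and the stop time.
    """
    cfg = cfg or Model1Config()
    raster = synthgen.gen_poisson_raster(cfg.n_neurons, rate_hz, max_duration,
                                         seed=_child_seed(seed, 1))
    sim = Model1Simulator(cfg, seed=_child_seed(seed, 2))
    w0 = sim.w.copy()
    traj = sim.run(raster, snapshot_stride=int(round(25.0 / cfg.dt)),
                   stop_on_convergence=True, epsilon=epsilon,
                   conv_window_s=conv_window_s)
    off = ~np.eye(cfg.n_neurons, dtype=bool)
    stop_t = float(traj.times[-1])
    return {
        "rate_hz": rate_hz,
        "seed": seed,
        "mean_weight": float(sim.w[off].mean()),
        "sd_weight": float(sim.w[off].std()),
        "m_dw": weight_metrics.net_weight_change(w0, sim.w),
        "stop_time_s": stop_t,
        "converged": stop_t < max_duration - 1e-6,
        "n_neurons": cfg.n_neurons,
    }


def sweep_rates(rates, n_seeds: int = 5, cfg: Model1Config | None = None,
                max_duration: float = 6000.0, conv_window_s: float = 100.0,
                seed0: int = 0) -> pd.DataFrame:
    """Rate sweep of the binary network on Poisson inputs: one run per
    (rate, seed); low rates downscale the weights (M_Δw < 0), high rates
    upscale them, and the converged mean grows with the input rate."""
    if np.any(np.asarray(list(rates)) <= 0):
        raise InvalidParameterError("rates must be positive")
    rows = []
    for rate in rates:
        for s in range(n_seeds):
            rows.append(run_to_convergence(rate, cfg=cfg,
                                           seed=_child_seed(seed0, int(rate * 1000), s),
                                           max_duration=max_duration,
                                           conv_window_s=conv_window_s))
    return pd.DataFrame(rows)


def compare_ltp_variants(hyp: Hypnogram, variants=None, n_seeds: int = 10,
                         cfg: Model1Config | None = None,
                         stats: StateStats | None = None, rem_index: int = 2,
                         mu: float = 1800.0, sigma: float = 600.0,
                         include_no_ltp: bool = True, seed0: int = 0,
                         t_end: float | None = None) -> pd.DataFrame:
    """Per-variant restructuring comparison on a shared hypnogram.

    For each seed, one state-conditioned raster drives a common simulation up
    to the LTP trigger (all arms share this bit-identical prefix via state
    cloning); each arm then continues with its own per-synapse gain matrix
    until the end of the Gaussian application window. Reported per arm:
    Spearman rank correlation and similarity of the final weights against the
    initial pattern, and M_Δw over the LTP window.
    """
    variants = list(VARIANTS) if variants is None else list(variants)
    cfg = cfg or Model1Config()
    stats = stats or StateStats()
    t_trigger, _ = select_trigger(hyp, rem_index)
    end = t_trigger + mu + 3.0 * sigma if t_end is None else t_end
    if end > hyp.duration_s + 1e-6:
        raise InvalidParameterError(
            f"hypnogram ({hyp.duration_s:.0f} s) shorter than the LTP window end ({end:.0f} s)")
    arms = (["no_ltp"] if include_no_ltp else []) + variants
    rows = []
    for s in range(n_seeds):
        raster = synthgen.gen_state_raster(hyp, stats, cfg.n_neurons,
                                           seed=_child_seed(seed0, 11, s))
        base = Model1Simulator(cfg, seed=_child_seed(seed0, 13, s))
        w_init = base.w.copy()
        pre_traj = base.run(raster, t_end=t_trigger,
                            snapshot_stride=int(round(1.0 / cfg.dt)))
        net_spikes = base.network_raster()
        w_at_trigger = base.w.copy()
        for arm in arms:
            sim = base.clone()
            sched = None
            if arm != "no_ltp":
                sched = build_schedule(arm, hyp, rem_index, traj=pre_traj,
                                       network_spikes=net_spikes, mu=mu, sigma=sigma)
            sim.run(raster, t_end=end, ltp=sched,
                    snapshot_stride=int(round(25.0 / cfg.dt)))
            rows.append({
                "variant": arm,
                "seed": s,
                "spearman_vs_initial": weight_metrics.spearman_weights(sim.w, w_init),
                "similarity_vs_initial": weight_metrics.similarity_index(sim.w, w_init),
                "m_dw_ltp_window": weight_metrics.net_weight_change(w_at_trigger, sim.w),
                "mean_cieg": 0.0 if sched is None else float(np.mean(sched.cieg)),
                "frac_recruited": 0.0 if sched is None else float(np.mean(sched.cieg > 0)),
            })
    return pd.DataFrame(rows)


def sweep_sleep_grid(gammas, kappas, n_runs: int = 20,
                     lif_cfg: LIFConfig | None = None,
                     stdp_cfg: STDPConfig | None = None,
                     schedule: SleepSchedule | None = None,
                     total_duration: float | None = None,
                     seed0: int = 0, n_surrogates: int = 200) -> pd.DataFrame:
    """γ × κ grid of the hippocampo-cortical model: per cell, ``n_runs``
    independent simulations; reports per-run T_S, T_H and their surrogate
    p-values (one row per run)."""
    if n_runs < 1:
        raise InvalidParameterError("n_runs must be >= 1")
    sched = schedule or SleepSchedule()
    duration = total_duration if total_duration is not None else sched.t_wake + 315.0
    rows = []
    for gi, g in enumerate(gammas):
        for ki, k in enumerate(kappas):
            for r in range(n_runs):
                res = run_model2(lif_cfg=lif_cfg, stdp_cfg=stdp_cfg, schedule=sched,
                                 gamma=float(g), kappa=float(k),
                                 seed=_child_seed(seed0, gi, ki, r),
                                 total_duration=duration,
                                 snapshot_every_s=max(5.0, duration / 60.0),
                                 record_spikes=False, n_surrogates=n_surrogates)
                rec = res.record
                rows.append({
                    "gamma": float(g), "kappa": float(k), "run": r,
                    "t_s": rec.t_s, "t_h": rec.t_h,
                    "p_t_s": rec.surrogate["t_s"].get("p"),
                    "p_t_h": rec.surrogate["t_h"].get("p"),
                    "surr_mean_t_s": rec.surrogate["t_s"].get("surrogate_mean"),
                    "surr_mean_t_h": rec.surrogate["t_h"].get("surrogate_mean"),
                    "sig_t_s": bool(rec.surrogate["t_s"].get("significant")),
                    "sig_t_h": bool(rec.surrogate["t_h"].get("significant")),
                })
    return pd.DataFrame(rows)


def grid_summary(grid: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a sleep-grid table: per (γ, κ) cell, mean T_S / T_H and the
    fraction of runs whose statistic is surrogate-significant."""
    return (grid.groupby(["gamma", "kappa"])
                .agg(mean_t_s=("t_s", "mean"), mean_t_h=("t_h", "mean"),
                     sig_frac_t_s=("sig_t_s", "mean"), sig_frac_t_h=("sig_t_h", "mean"),
                     n=("run", "count"))
                .reset_index())


def report(run_dir) -> dict:
    """Collect an experiment directory into a machine-readable summary
    (written as ``summary.json``) plus a human-readable ``summary.md``.

    The directory must contain ``config.json`` and at least one metric table
    (``*.csv``); missing artifacts raise with the absent file names.
    """
    run_dir = Path(run_dir)
    missing = []
    cfg_path = run_dir / "config.json"
    if not cfg_path.exists():
        missing.append(str(cfg_path))
    tables = sorted(run_dir.glob("*.csv")) if run_dir.exists() else []
    if not tables:
        missing.append(str(run_dir / "*.csv"))
    if missing:
        raise FileNotFoundError("missing experiment artifacts: " + ", ".join(missing))
    config = json.loads(cfg_path.read_text())
    summary: dict = {"config": config, "tables": {}}
    lines = [f"# Experiment summary: {config.get('experiment_id', run_dir.name)}", ""]
    for tab in tables:
        df = pd.read_csv(tab)
        numeric = df.select_dtypes("number")
        summary["tables"][tab.name] = {
            "rows": int(len(df)),
            "columns": list(df.columns),
            "means": {c: float(numeric[c].mean()) for c in numeric.columns},
        }
        lines.append(f"## {tab.name} ({len(df)} rows)")
        lines.append(df.describe().to_string())
        lines.append("")
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (run_dir / "summary.md").write_text("\n".join(lines))
    return summary
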