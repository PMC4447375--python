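"""Shared fixtures.

The expensive simulation campaigns (rate sweep, LTP-variant comparison,
sleep-modulation grid) are session-scoped so several tests can interrogate
one set of runs. Desk-scale problem sizes (30-50 binary neurons, shortened
sleep schedules, 2-20 seeds) are chosen so the whole suite runs on one CPU
in well under half an hour; the scientific claims under test are scale-free
orderings and calibrations, not absolute magnitudes.
"""

from __future__ import annotations

import pytest

from sleepsyn.types import StateStats
from sleepsyn import synthgen, pipeline
from sleepsyn.binarynet import Model1Config
from sleepsyn.lifnet import SleepSchedule


@pytest.fixture(scope="session")
def rate_sweep():
    """Poisson rate sweep across the full rate grid, 2 seeds per rate.

    Runs are capped at 2500 s; at that point the weight distribution is
    within a few percent of its asymptote at every rate (relaxation is
    fastest at high rates).
    """
    rates = [3.0, 5.0, 7.0, 10.0, 12.0, 20.0, 40.0]
    return pipeline.sweep_rates(rates, n_seeds=2, cfg=Model1Config(n_neurons=50),
                                max_duration=2000.0, seed0=7)


@pytest.fixture(scope="session")
def desk_hypnogram():
    """Hypnogram with short waking bouts: several sleep cycles inside ~35 min
    of simulated time, enough for one LTP trigger plus its Gaussian window."""
    params = synthgen.HypnogramParams(wk_mu_log=4.0, wk_sigma_log=0.4)
    return synthgen.gen_hypnogram(10, params, seed=5)


@pytest.fixture(scope="session")
def ltp_comparison(desk_hypnogram):
    """Five LTP variants plus the no-LTP baseline on a shared hypnogram,
    10 seeds, with a time-compressed Gaussian (mu=240 s, sigma=80 s; the
    time-integrated bonus per synapse is unchanged by the compression)."""
    return pipeline.compare_ltp_variants(
        desk_hypnogram, n_seeds=10, cfg=Model1Config(n_neurons=30),
        stats=StateStats(), rem_index=2, mu=240.0, sigma=80.0, seed0=3)


SCALED_SLEEP = dict(t_sleep=90.0, t_wake=165.0, t_ltp_peak=115.0, t_ltp_std=12.5)


@pytest.fixture(scope="session")
def sleep_grid():
    """γ × κ grid of the LIF model on a compressed schedule (90 s wake,
    75 s sleep, 15 s recovery), 20 runs per cell."""
    sched = SleepSchedule(**SCALED_SLEEP)
    return pipeline.sweep_sleep_grid(
        gammas=[1.0, 2.0, 4.0], kappas=[0.0, 1.0, 2.0], n_runs=20,
        schedule=sched, total_duration=180.0, seed0=11, n_surrogates=200)
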