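# Methods

`sleepsyn` implements two network models of sleep-dependent synaptic
plasticity — a fully connected stochastic binary network with Hebbian
rescaling and transition-triggered LTP, and a hippocampo-cortical leaky
integrate-and-fire (LIF) circuit with sleep-modulated STDP and embossing
LTP — together with the synthetic spike/hypnogram generators that stand in
for rat CA1 recordings and the weight-pattern metrics used to quantify
rescaling vs restructuring.

## Synthetic data generators (`synthgen`)

**Poisson rasters.** Homogeneous Poisson processes per unit (counts drawn
from the Poisson law, times as sorted uniforms). Used for the rate sweeps
(3–40 Hz, binned at 4 ms).

**Correlated rasters.** A mother Poisson train at the unit rate is thinned
into each unit with a per-unit copy probability q_u centred on
√c (c = target mean pairwise binned Pearson correlation); the remaining rate
is filled with independent spikes, preserving each unit's mean rate. For
sparse bins the correlation of units u, v is ≈ q_u·q_v, so the mean pairwise
correlation is ≈ c. A `heterogeneity` parameter spreads q_u uniformly over
√c·[1−h, 1+h]: real population recordings show structured, heterogeneous
correlation matrices, and this heterogeneity is what makes the steady-state
weight distribution of the binary network wider under correlated inputs than
under rate-matched independent Poisson inputs. State-conditioned rasters
default to h = 1; the plain generator defaults to h = 0.

**State statistics.** Defaults: rates WK 10 / REM 7.5 / SWS 5 Hz (within
the 5–10 Hz range typical of CA1 population data) and correlations WK 0.06 /
SWS 0.03 / REM 0.005, respecting the orderings rate WK > REM > SWS and
synchrony WK > SWS > REM. The correlation magnitudes are conventions, not
published values; both dictionaries are configurable.

**Hypnograms.** Alternating WK → SWS → REM cycles with log-normal episode
durations, floored at 10 s. SWS: log-mean 4.338, log-sd 0.506 (mean ≈ 87 s);
REM: 4.60 / 0.44 (mean ≈ 110 s); WK: 5.60 / 1.30. The heavy-tailed WK
distribution carries the long REM-to-REM intervals: the WK log-mean was
calibrated once so that ≈ 91.6 % of REM-onset-to-REM-onset intervals are
below 30 min (the published cumulative statistic) while the SWS mean stays at
≈ 87 s. No distributional form is published; the log-normal is a standard
choice for bout durations.

**Two-memory drive.** 200 input units, memory A = units 1–100, memory B =
101–200. In each 125 ms window one memory is active (drawn uniformly); active
units fire Poisson at 20 Hz, inactive at 10 Hz; both rates are halved inside
the sleep interval.

What the generators do **not** emulate: LFP structure (spindles, delta,
theta), theta-modulated inhomogeneous rates, refractoriness, and the
intermediate-sleep state. Tests passing on these inputs show that the models
respond correctly to the *rate and synchrony statistics* of the sleep-wake
cycle, not that they reproduce any particular animal's recordings.

## Model 1: stochastic binary network (`binarynet`)

N binary neurons, fully connected (no self-connections), updated every
Δt = 4 ms. Total current I_i = w_ie·e_i + (1/(N−1))·Σ_j w_ij·v_j with
external binary input e_i; firing probability P = 1/(1 + exp(K_t − K_s·I)),
K_t = 6, K_s = 11 (spontaneous rate with w_ie = 0 ≈ 0.6 Hz, within the
published 0.5–1 Hz band). Weights are initialized uniform on [0, 1], zero
diagonal, and evolve by a stable Hebbian rule on 4 ms co-firing:

* co-firing: Δw = C_p·J(w)·Δt, J(w) = e^(−w) − e^(−1), C_p = 6.25 s⁻¹ —
  weight-dependent potentiation, zero at w = 1;
* presynaptic spike without postsynaptic spike: Δw = −C_d·θ·Δt,
  C_d = 0.021 s⁻¹, θ = 1;
* silent presynaptic partner: no change.

Fixed conventions (the update order is part of the model definition):
currents are computed from the previous bin's states, the new states are
drawn, plasticity is applied on the new-bin states. External inputs drive
their neuron through w_ie only and are not presynaptic partners in the
plasticity rule. Weights are clipped to [0, 1.5]: J self-limits potentiation
near w = 1 but depression has no floor, and the additive LTP bonus needs
headroom above 1; both bounds are configurable.

**Steady state.** Convergence is declared when every synapse's OLS slope
over a trailing window (default 100 s, snapshots on a 1 s grid) has magnitude
≤ ε = 2.5×10⁻⁴ s⁻¹. Two regimes follow from the model's own constants:
below ≈ 7 Hz input the maximal drift never exceeds ε, and at the 100 s window
the shot noise of discrete potentiation events keeps the per-synapse slope
estimates above ε essentially forever — so low-rate runs are halted at a
configurable cap (defaults 4000–6000 s, by which point the mean weight is
within a few percent of its asymptote). For convergence-*time* comparisons a
500 s window is used, where detection binds on the relaxation dynamics; the
published decrease of convergence time with input rate is reproduced on the
≥ 10 Hz branch, while below ≈ 7 Hz the criterion triggers at the first
evaluable window (the drift there is sub-threshold from the start), which
compresses all low-rate times to the window length. How the slope was
estimated in the original analysis is not documented; the trailing-window OLS
is this package's convention.

**Operating points** (mean converged off-diagonal weight, 50 neurons):
≈ 0.40 at 5 Hz, ≈ 0.49 at 7 Hz, ≈ 0.59 at 10 Hz — net downscaling below the
0.5 midpoint for ≤ 7 Hz inputs and net upscaling above it for ≥ 10 Hz, with
the mean growing monotonically in rate.

## Sleep-dependent LTP for Model 1 (`sleep_ltp`)

A single REM episode is selected on the hypnogram (default: the 4th);
t_T = REM onset + 30 s triggers a per-synapse Gaussian weight bonus with peak
delay μ = 30 min and width σ. σ is not published ("σ the variance"); the
default σ = 600 s puts ±3σ at the ≈ 3600 s application window seen in the
published trajectories. The per-step increment is the Gaussian *density*
scaled by Δt, so the time-integrated bonus per synapse equals its gain
Cieg ∈ [0, 1]; an unscaled per-step density would inject ≈ Cieg/Δt = 250
weight units and destroy the [0, 1] weight range, so the scaled form is the
default and the unscaled behavior is available behind `scale_by_dt=False`.

Gains: LTP1 computes Cieg_ij as the fraction of presynaptic spikes that
co-occur with postsynaptic spikes in 4 ms bins over (a) the full preceding
SWS episode, (b) its last 30 s, or (c) those 30 s plus the first 30 s of REM;
synapses whose presynaptic unit is silent in the epoch get 0. LTP2 fits each
synapse's weight trajectory by OLS over the last 30 s of SWS and first 30 s
of REM and forms the transition angle β = π − (arctan m_REM − arctan m_SWS):
collinear segments give β = π, upward turns β < π, and any positive REM slope
gives β < 3π/2. The gain is linear in the angle, Cieg = max(0, 1 − β/β_max),
restricted to positive REM slopes, with β_max = 3π/2 (permissive) or π
(restrictive). The angle formula and the linear anchors (β → 0 maps to gain
1, β_max to 0) are this package's construction; they reproduce both published
cutoff statements exactly. Because weight drifts over 30 s are ≪ 1, β
concentrates near π: the permissive rule then grants ≈ 1/3 gain to roughly
the half of synapses with positive REM slope (a strong, binary-like
embossing), while the restrictive rule grants only vanishing gains — hence
permissive LTP2 restructures most and restrictive LTP2 barely differs from
the no-LTP baseline, with the LTP1 variants in between.

## Weight-pattern metrics (`weight_metrics`)

M_Δw: mean element-wise difference over the N(N−1) off-diagonal entries
(negative = net downscaling). Similarity index: 1 − mean |w − ref| over
off-diagonal entries, normalized to [0, 1] and oriented so larger = more
similar (the raw absolute-difference sum is also exposed). Spearman rank
correlation over the vectorized off-diagonal entries (average ranks on ties;
a constant pattern raises an undefined-result signal). Rescaling = falling
similarity at preserved Spearman; restructuring = both falling.

## Model 2: hippocampo-cortical LIF circuit (`lifnet`)

45 LIF neurons, no recurrent excitation, each receiving the 200 two-memory
inputs through plastic conductances W (nS); every principal spike recruits,
after a 1 ms delay, an inhibitory conductance onto the whole layer. STDP on
nearest pre/post spike pairs: potentiation (C_p + v·W)·e^(−δt/τ) at a
postsynaptic spike (δt > 0), depression (−C_d + v)·W·e^(δt/τ) at a
presynaptic spike (δt < 0), with τ = 20 ms, C_p = 3.2 nS, C_d = 0.03, and v a
fresh zero-mean Gaussian (σ = 0.015) per event; δt = 0 events contribute
nothing, and weights are clipped at 0 before normalization (no truncation of
v). After every update each neuron's mean input weight is renormalized to
exactly ω = 0.25 nS (multiplicative, proportion-preserving). Sleep
(315–585 s of a 900 s run) halves the input rates, rescales the STDP
constants (C_p/γ, C_d·γ — the printed equation multiplies both, which
contradicts the accompanying text; the literal reading is available via
`gamma_literal=True`), and applies embossing LTP: a Gaussian bonus (peak
405 s, sd 45 s, unmodulated mass 0.05 nS) scaled per synapse by
θ_ij = W_k(i),j / mean(W_k(i),·) from the pre-sleep snapshot, where k is a
random derangement of the neurons, and by the magnitude κ_sleep.

**Membrane and circuit constants.** The published model fixes only the
architecture; membrane parameters are not available. Defaults: τ_m = 20 ms,
V_rest = −70 mV, V_th = −54 mV, V_reset = −60 mV, refractory 3 ms,
C_m = 250 pF, exponential conductances with τ_e = 5 ms and E_exc = 0 mV, and
*slow* feedback inhibition: τ_i = 60 ms, 12 nS per spike, E_inh = −72 mV,
delay 1 ms. The slow inhibition is a deliberate design choice: it spans the
125 ms input window, so each window's onset race selects a sparse set of
winners and the two memories end up represented by balanced teams (≈ 22/45).
With fast (≤ 10 ms) inhibition the layer either fires in lockstep (all
neurons converge on one memory) or selects winners by noise alone.

**Known limitation.** With the published STDP constants, a single
postsynaptic spike redistributes the bulk of a neuron's row weight onto
recently active inputs (C_p·Σ_j e^(−δt_j/τ) ≈ 150 nS against a fixed row
budget of m·ω = 50 nS), capping the steady-state composition near 63:37 and
the preferred/non-preferred drive ratio near 1.2. Memory selectivity is
therefore maintained *dynamically* and persists on the scale of minutes, not
indefinitely: across a sleep cycle a substantial baseline fraction of neurons
switch selectivity even without STDP modulation, and the network is nearly
silent during sleep at the default operating point (halved drive falls below
the inhibition-free threshold), which leaves the γ modulation little activity
to act on. Consequently the proportion of switches T_S responds only weakly
to γ at desk scale, while the proportion of LTP hits T_H responds robustly to
κ (the embossing bonus acts directly on the weights). The simulation step is
1 ms; the LTP bonus is integrated in 10-step substeps (it varies on a 45 s
scale); the inner loop is compiled with numba and is exactly reproducible
under the run seed.

## Memory metrics (`memory_metrics`)

Sel_i = sign(Σ_{j∈A} W_ij − Σ_{j∈B} W_ij) ∈ {1, −1, 0} (strict comparison;
ties are measure-zero with continuous weights). T_S = fraction of neurons
with Sel[t_sleep]·Sel[end] = −1; T_H = fraction with Sel_θ[t_sleep]·Sel[end]
= +1; zero-selectivity neurons count as neither (Heaviside at 0 taken as 0),
so T_S + (stable fraction) + (zero-involving fraction) = 1 exactly.
Significance: 200 shuffles of the post-sleep selectivity vector, the
statistic recomputed per shuffle against the fixed reference, a normal fit to
the surrogates, two-sided p (the published analysis states only p > 0.05;
two-sided is this package's choice), plus the central 95 % non-significance
interval used for grid shading.

## Experiment scale

Desk-scale defaults: 50 binary neurons (150 for the spontaneous-rate
calibration; the original Poisson runs used 150 throughout), 5–10 seeds per
condition (original: 25), rate-sweep runs capped at 4000–6000 s,
LTP comparisons on compressed Gaussians (μ = 300 s, σ = 100 s; the
time-integrated bonus is unchanged by compression), and LIF sleep schedules
compressed to 90 s wake / 75 s sleep / 15 s recovery with 20 runs per grid
cell (original: 50). All scales are parameters; full-scale settings are one
config away.

## Numerical conventions and degenerate inputs

Empty epochs, rasters shorter than the requested simulation, mismatched
sizes, non-positive distribution parameters, γ ≤ 0, σ ≤ 0 and overlapping
memory sets raise an invalid-parameter error; constant weight patterns
(Spearman) and constant surrogate distributions raise an undefined-result
signal rather than returning NaN. 0/0 synchrony ratios (silent presynaptic
unit) are defined as 0. Multiple spikes in one 4 ms bin collapse to a single
binary event. The binary-network state snapshot stride defaults to 1 s
(250 steps); convergence checks run every 25 s.
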