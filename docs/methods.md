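# Methods

## The circuit model

### Geometry and electrical coupling

Golgi cells (GoCs) are placed uniformly at random in a
500 × 500 × 100 µm slab of the granule cell layer (115 cells, matching
the measured anatomical density). Each unordered pair at 3-D intersomatic
distance `d` (µm) is electrically coupled with probability

    P(d) = H(0.01 · (−1745 + 1836 / (1 + exp((d − 267)/39)))),

where `H` clamps to [0, 1] (`P(0) ≈ 0.89`, `P ≈ 0` beyond ~270 µm), and a
connected pair receives the total junctional conductance

    g(d) = g0 · round(k · Y(d)/5),    Y(d) = −2.3 + 29.7 · exp(−d/70.4),

with `g0 = 0.9 nS` per junction and half-away-from-zero rounding (the
MATLAB convention). `k` scales coupling strength; `k = 1` is the
physiological level and `k = 0` removes all junctions. Under these rules
the mean per-cell summed conductance measures 16.3 ± 0.3 nS over
realizations; published estimates for this connectivity are somewhat
higher (~22 nS), a discrepancy we report rather than absorb by modifying
the printed rules (see `scripts/acceptance.py` output).

### The simplified neuron

The model neuron is a deliberate reduction: a two-compartment
(soma + lumped dendrite) leaky integrate-and-fire cell replaces
multi-compartment, channel-based GoC models. The soma (40 pF, 3 nS leak,
threshold −40 mV, reset −55 mV, 2 ms refractory) carries a constant
pacemaker bias current and a spike-triggered adaptation conductance
(reversal −90 mV, τ = 200 ms); the dendrite (10 pF, 1 nS leak, 25 nS
soma–dendrite coupling) carries the parallel-fiber synapses and the gap
junctions. Optional Ornstein–Uhlenbeck somatic current noise is available
(`noise_sigma`, default 0 pA — the deterministic pacemaker plus synaptic
input reproduces the network-level statistics without it).

Two parameters are calibrated per cell type by nested 1-D root-finding
(brentq): the adaptation increment sets the f–I slope to a target sampled
uniformly from the measured 14–25 Hz/nA range, and (inside that loop) the
pacemaker bias sets the spontaneous rate to a target from the measured
3–9 Hz range. Five calibrated parameter sets are drawn per network and
assigned to cells at random.

Because an integrate-and-fire soma has no action-potential waveform, the
junctional current carried by spikes is restored explicitly: each spike
deposits the charge `g_ij · spike_area` into every coupled dendrite
(`spike_area = 75 mV·ms`, the AP's time-integral above baseline). This
spikelet transmission is the mechanism by which coupled GoCs loosely
synchronize; the dendritic impedance and the spikelet area were set so the
coupled network sits in the loose-synchrony regime (strongly correlated
40 ms-binned rates without full locking) rather than calibrated to any
single-pair quantity — the lumped dendrite is too abstract for
per-junction coupling coefficients to be meaningful. The emergent pair
coupling decays with distance through `g(d)`; we report, rather than
enforce, its spatial scale.

### Inputs

Input spike trains are inhomogeneous Poisson processes (exact thinning
against the piecewise-constant rate) with

    r_k(t) = A · (w_k · b(t)) + c,   clamped at 2 Hz,

where `b(t)` is the min–max-normalized 6-channel behavioral vector
(state, locomotion, whisker setpoint, whisker motion index, whisking
amplitude, pupil) over a fixed 20 s segment. `Input-Beh` uses
`A = 50 Hz`, `c = 7 Hz` and sparse uniform [0, 1] weights (each zeroed
with probability 0.5); `Bimodal` adds a negatively modulated population
(`A = −25 Hz`, `c = 30 Hz`); `Uncorrelated` adds inputs reading
circularly shifted behavior segments; `Tuned` divides the volume into
four 125 µm sagittal modules, each dominated by one behavioral variable,
with mossy-fiber connectivity restricted to the module. A constant-rate
background (30 MFs at 5 Hz, 60 PFs at 2 Hz) is always present.
Mossy fibers contact somata (p = 0.2 within 300 µm, 3-D distance);
parallel fibers contact dendrites (p = 0.2 within 100 µm along the
mediolateral x axis, the parallel-fiber axis). Defaults are 24 MFs and
60 PFs, the middle of the ranges explored.

Synaptic conductances are peak-normalized rise/decay exponentials
(AMPA-type, reversal 0 mV): MF→GoC has τ_rise = 0.1 ms and two decay
components (0.7 nS/0.7 ms + 0.2 nS/3.5 ms; summed peak 0.89 nS);
PF→GoC has a single 0.67 nS/1.06 ms component.

### Integration

The kernel (numba-compiled) advances both compartments with
exponential-Euler updates — conductances frozen over the step, membrane
relaxed exactly toward its instantaneous equilibrium — which remains
stable under arbitrarily large adaptation or junctional loads where
explicit Euler diverges. Synaptic and adaptation states decay by exact
exponential factors. Junctional currents use the synchronous previous-step
dendritic voltages, so the summed gap-junction current over the network is
zero at every step by symmetry. Default timestep 0.1 ms (the test suite
checks that halving it changes mean rates by < 2% after discarding the
2 s onset transient); 0.025 ms is available where reference-grade
integration is wanted. Spike detection is threshold crossing at −40 mV
with a 2 ms lockout; only spike times are stored. Divergence (|V| >
200 mV) raises a time-stamped error.

## Analyses

All analyses operate on neurons × time matrices — 40 ms-binned spike
rates for the model, ΔF/F (10th-percentile baseline, 100 ms square
smoothing) for fluorescence-like data — centered per neuron.

- **Modes.** SVD `X = U S Vᵀ`; loading columns sign-flipped so their
  entry-sum is non-negative. Residual activity reconstitutes modes 2..N,
  leaving exactly zero projection onto PM1.
- **Bi-cross-validation.** 30 repeats; per repeat the time axis is split
  70/30 in random 500 ms blocks (contiguity respects autocorrelation),
  loadings come from training times, and on test times the K latent
  dynamics are estimated from 80% of neurons by least squares
  (`X̂2 = U2K · pinv(U1K) · X1`), scoring variance explained on the
  held-out 20%. The peak of the mean curve (smallest K within 1e−6 of
  the maximum) is the shared dimensionality.
- **Effective dimensionality.** Participation ratio `(Σλ)²/Σλ²` of the
  covariance eigenvalues; for model populations averaged over ten
  300 × 300 × 100 µm subsampled volumes (35–45 cells each).
- **Correlations.** Pearson r in 40 ms bins, total or residual; per-pair
  circular-shuffle nulls (500 repeats, independent shifts drawn from
  [1, T−1] bins; one shift set per repeat shared across pairs by
  default); distance dependence fit on 20 µm-binned means (first 20 µm
  excluded, bins weighted by pair count), linear for total and
  `A·exp(−d/λ)+b` for residual correlations.
- **Decoding.** Mode dynamics and behavior are restricted to active
  periods ± 500 ms and area-weighted-resampled to 20 Hz; ridge
  regression with the penalty chosen from a 10⁻⁴..10⁴ grid by 5-fold
  blocked inner CV; 100 random 80/20 block partitions. Rank-K decoding
  uses the first K mode dynamics from a single full-time SVD, with the
  optimal K the smallest reaching 90% of the maximal improvement over
  PM1. Within-period and across-period 500 ms block shuffles preserve
  the target's marginal distribution exactly.
- **Active periods.** Min–max-normalized WMI and locomotion averaged in
  100 ms bins; onset at the first upward crossing of either threshold
  (0.25 WMI / 0.4 Loco), offset when both fall below (0.2 / 0.1);
  periods < 1 s apart merged, < 1 s long discarded, padding 0.5 s. The
  min–max scale and the both-below offset rule are documented choices
  (ending on either trace alone would truncate sustained running).
- **Events.** Air-puff windows A1 [−400, −200), A2 [0, 800), R1
  [0, 300), R2 [300, 800) ms on 50 ms bins; class I if A2 > A1 and
  R1 − R2 > 0.05 Hz, class II if A2 > A1 otherwise, class III otherwise
  (so classes partition neurons); first-event latency searched in
  [0, 800] ms. Trial similarity S(t) is the mean pairwise dot product of
  raw population rate vectors per 100 ms bin (a unit-normalized variant
  is available); its decay timescale is the integral of the
  [0, 1]-normalized profile over [0, 800] ms. Step-cycle modulation flags
  a cell iff its lift-aligned event probability correlates with the mean
  paw trajectory (|r| > 0.5, p < 0.01, two-sided t approximation on the
  number of bins) while the within-instance event shuffle does not
  (p > 0.1).
- **ICA stability.** FastICA (logcosh, unit-variance whitening) on the
  two halves of ten random 500 ms-block partitions per candidate K;
  greedy alignment by maximal |loading dot product|; the chosen
  dimensionality is the largest K whose mean aligned correlation reaches
  0.9 (all larger K fall below). Non-convergence is retried with fresh
  seeds and otherwise scored as instability.

## The synthetic generator

`generate_behavior` emulates head-fixed mouse behavior: alternating
quiet/active bouts with log-normal durations (means 4 s), where active
bouts are whisking bouts and contain locomotion with probability 0.5 —
so the six channels are correlated but not redundant, as in real
sessions. Whisking oscillates at 8–15 Hz about a protracted setpoint;
pupil follows arousal slowly with a 0.5 s lag. All randomness flows
through named substreams of one master seed.

`generate_population_activity` plants a slow common mode (positive
loadings, ≥ 1 s autocorrelation, driven by smoothed behavioral
intensity), differential modes with orthonormal mixed-sign loadings and
geometrically decaying variances (ratio 0.7, so the planted spectrum is
identifiable), and independent noise, at exact prescribed variance
fractions (defaults 0.7/0.2/0.1); optional single-exponential indicator
convolution (τ = 0.7 s) mimics GCaMP6f kinetics. Ground-truth loadings
and dynamics are returned for recovery tests.

What the generator does **not** emulate: sensor noise structure of real
imaging (shot noise, neuropil contamination), spike-inference artifacts,
non-stationarity across a session, or genuinely nonlinear
behavior–activity coupling. Passing recovery tests therefore shows the
analyses are correct and well-calibrated on data satisfying their own
assumptions, not that those assumptions hold for any particular
recording.

## Known limitations

- The simplified neuron underestimates how strongly the printed synaptic
  conductances modulate firing: behavioral drive changes rates by well
  under 1 Hz per cell, so the **uncoupled** network behaves as nearly
  independent pacemakers and its effective dimensionality (~45–60 for
  115 cells over 20 s) exceeds the ~28 reported for the channel-based
  model. The coupled network's statistics (common-mode CVEV ~0.7,
  mean pairwise correlation ~0.6–0.75, effective dimensionality ~1.7–2.0)
  are insensitive to this because they are dominated by junctional
  synchronization.
- The synthetic behavioral segment modulates input rates strongly
  relative to Poisson shot noise, so the input population's own PM1 CVEV
  (~0.5) is far above the ~0.1 seen with recorded behavior; this is a
  property of the surrogate conditions, not of the analysis.
- Mean pairwise correlation is not perfectly monotone in the coupling
  scale at its low end: at k = 0.25 almost all pairs quantize to zero
  junctions and the few surviving 0.9 nS junctions shunt the dendrite
  and jitter input-locked spike phases, dipping the (near-zero) mean
  correlation by ~0.01 below the uncoupled value before coupling gains
  dominate from k = 0.5.
- Network construction under the printed wiring rules yields ~16 nS mean
  per-cell junctional conductance, not the published ~22 nS (see above).
- The 20 s simulation segment (as in the original protocol) limits the
  precision of all correlation and dimensionality estimates; acceptance
  quantities average 3 seeds and 10 subsampled volumes.
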