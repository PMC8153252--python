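# gocpop

Population dynamics of electrically coupled cerebellar Golgi cells:
a gap-junction-coupled spiking-network model and the population-level
analyses used to characterize multidimensional inhibitory activity.

Cerebellar Golgi cells (GoCs) — the inhibitory interneurons of the granule
cell layer — are densely coupled by connexin-36 gap junctions and show, in
awake mice, a dominant slow common population mode tracking the animal's
behavioral state plus a handful of faster *differential* modes distributed
across cells. This package is for computational neuroscientists who want to
(i) simulate a biologically constrained electrically coupled GoC circuit
driven by behavior-modulated excitatory inputs and (ii) quantify
multidimensional population activity the same way on model or surrogate
data: mode decomposition, shared and effective dimensionality, pairwise
correlation structure, behavioral decoding and event-aligned responses.

## What it computes

**Circuit model.** 115 model GoCs placed in a 500 × 500 × 100 µm volume are
connected with distance-dependent probability
`P(d) = H(0.01·(−1745 + 1836/(1 + exp((d−267)/39))))` and total
gap-junction conductance `g(d) = g0·round(k·Y(d)/5)` with
`Y(d) = −2.3 + 29.7·exp(−d/70.4)` and `g0 = 0.9 nS` (`k` scales coupling;
`k = 0` is the uncoupled control). Neurons are two-compartment
integrate-and-fire cells with spike-triggered adaptation and gap-junction
spikelet transmission, calibrated by root-finding to the measured 3–9 Hz
spontaneous rates and 14–25 Hz/nA f–I slopes. Mossy-fiber and
parallel-fiber inputs fire as inhomogeneous Poisson processes with rates
`r_k(t) = A·(w_k·b(t)) + c` read out from a six-dimensional behavioral
state vector (binary state, locomotion, whisker setpoint, whisker motion
index, whisking amplitude, pupil), under four connectivity/weight schemes
(`Input-Beh`, `Bimodal`, `Uncorrelated`, `Tuned`).

**Analyses.** Activity (40 ms-binned spike rates or ΔF/F) is decomposed by
SVD into population modes; reliability is assessed by bi-cross-validation
(70/30 time split, latent dynamics estimated from 80% of neurons, variance
explained on the held-out 20%), whose peak over mode count K defines the
*shared dimensionality*; the *effective dimensionality* is the
participation ratio `D_eff = (Σλ)²/Σλ²`. Pairwise correlations (total and
after projecting out PM1) get circular-shuffle significance labels and
distance-dependence fits; ridge regression decodes behavior from rank-K
reconstructions with within/across-period block-shuffle controls; air-puff
responses are classified (fast-transient / variable-delay / unresponsive)
and step-cycle modulation is tested against an event-shuffle null.

**Synthetic data.** `gocpop.behavior.generate_behavior` and
`gocpop.synthetic` produce behavioral sessions with alternating
quiet/active bouts and surrogate population recordings with a known common
mode, differential modes and noise, so every analysis runs — and is tested
for parameter recovery — without any recorded data.

## Worked example

```python
import numpy as np
from gocpop import (build_network, generate_behavior, make_input_rates,
                    simulate, bin_rates, subsample_populations,
                    decompose, effective_dimensionality, cross_validated_evar)

behavior = generate_behavior(25.0, seed=1)            # 25 s synthetic session
network = build_network(seed=1, k=1.0)                # coupled realization
inputs = make_input_rates(behavior, scheme="Input-Beh", seed=1)
raster = simulate(network, inputs, duration=20.0, dt=0.1, seed=1)
activity = bin_rates(raster, positions=network.positions)

boxes = subsample_populations(activity, volume=(500, 500, 100), seed=1)
box = boxes[0]
print(f"{box.n_neurons} cells in the imaging volume")
c = np.corrcoef(box.rates)
print(f"mean pairwise r = {np.nanmean(c[np.triu_indices(box.n_neurons, 1)]):.2f}")
print(f"D_eff = {effective_dimensionality(decompose(box).eigenvalues):.2f}")
print(f"PM1 CVEV = {cross_validated_evar(box, k_max=1, seed=1).cvev[0]:.2f}")
```

prints (seed 1):

```
38 cells in the imaging volume
mean pairwise r = 0.56
D_eff = 2.36
PM1 CVEV = 0.63
```

i.e. in this subsampled volume the coupled network is dominated by a
common mode carrying ~60% of cross-validated variance, with strongly
positive pairwise correlations and an effective dimensionality near 2 —
removing the gap junctions (`build_network(..., k=0.0)`) collapses the
correlations to ~0 and raises `D_eff` more than tenfold.

A command-line interface wraps the same pipeline:

```bash
gocpop synth --config cfg.yaml --out session.h5
gocpop simulate --seed 1 --out run.h5        # add --no-gj for k = 0
gocpop modes session.h5 --kmax 15 --out modes.json
gocpop corr session.h5 --out corr.csv
gocpop decode session.h5 --target wmi --out decode.json
```

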