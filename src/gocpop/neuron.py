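"""Simplified Golgi-cell model and its calibration.

The multi-compartment, channel-based Golgi cell is replaced by a
two-compartment (soma + lumped dendrite) leaky integrate-and-fire neuron
with a pacemaker bias current and a spike-triggered adaptation conductance
(AHP-like, reversal -90 mV).
This keeps the two population-level properties the circuit model depends
on — intrinsic pacemaking and low-pass dendritic coupling through gap
junctions — while remaining cheap enough to integrate at the 0.025 ms
reference timestep.

Each parameter set is calibrated by nested 1-D root-finding (brentq):
the adaptation increment sets the f-I slope and, inside that loop, the
pacemaker bias sets the spontaneous rate, against targets sampled from the
experimental ranges (spontaneous 3-9 Hz, f-I slope 14-25 Hz/nA).  Five
parameter sets are drawn per network and assigned randomly to cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from . import _kernel
from ._rng import substream

__all__ = ["NeuronParams", "single_cell_rate", "fi_slope", "calibrate_neuron",
           "calibrate_population"]

RATE_RANGE = (3.0, 9.0)      # Hz, spontaneous firing
SLOPE_RANGE = (14.0, 25.0)   # Hz/nA, f-I slope


@dataclass
class NeuronParams:
    """Two-compartment LIF with adaptation.  Units: pF, nS, mV, ms, pA."""

    c_s: float = 40.0        # somatic capacitance
    c_d: float = 10.0        # dendritic capacitance
    g_ls: float = 3.0        # somatic leak
    g_ld: float = 1.0        # dendritic leak
    g_c: float = 25.0        # soma-dendrite coupling
    e_l: float = -60.0       # leak reversal
    v_th: float = -40.0      # spike threshold
    v_reset: float = -55.0   # post-spike reset
    t_ref: float = 2.0       # refractory period
    tau_w: float = 200.0     # adaptation time constant
    b_w: float = 4.0         # adaptation conductance increment per spike (nS)
    i_pace: float = 300.0    # pacemaker bias current
    spike_area: float = 75.0  # mV*ms, AP time-integral driving GJ spikelets
    noise_sigma: float = 0.0  # pA, intrinsic OU current noise SD (optional)
    noise_tau: float = 3.0    # ms, noise correlation time
    target_rate: float = np.nan
    target_slope: float = np.nan


def _run_single(p: NeuronParams, i_ext: float, duration: float,
                dt: float) -> int:
    """Spike count of one isolated cell over `duration` s (after settling)."""
    n_steps = int(round(duration * 1000.0 / dt))
    one = np.ones(1)
    empty_i = np.empty(0, dtype=np.int64)
    sp_cell, sp_step, status, _ = _kernel.run_network(
        n_steps, dt,
        one * p.c_s, one * p.c_d, one * p.g_ls, one * p.g_ld, one * p.g_c,
        one * p.e_l, one * p.v_th, one * p.v_reset, one * p.i_pace,
        one * p.b_w, one * i_ext,
        int(round(p.t_ref / dt)), np.exp(-dt / p.tau_w),
        1.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0,
        np.zeros(2, dtype=np.int64), empty_i, np.empty(0),
        empty_i, empty_i, np.zeros(1, dtype=np.int64), empty_i,
        np.zeros(0, dtype=np.uint8),
        one * p.e_l, one * p.e_l,
        int(duration * 1000 / p.t_ref) + 10,
        0.0,
        p.noise_sigma, p.noise_tau, 12345,
    )
    if status != _kernel.STATUS_OK:
        raise RuntimeError("single-cell simulation diverged")
    discard = n_steps // 3
    return int(np.sum(sp_step >= discard)), duration * (1 - discard / n_steps)


def single_cell_rate(p: NeuronParams, i_ext: float = 0.0,
                     duration: float = 9.0, dt: float = 0.1) -> float:
    """Steady-state firing rate (Hz) under constant injected current (pA)."""
    count, window = _run_single(p, i_ext, duration, dt)
    return count / window


def fi_slope(p: NeuronParams, delta_i: float = 250.0, dt: float = 0.1) -> float:
    """f-I slope (Hz/nA) measured between 0 and `delta_i` pA."""
    f0 = single_cell_rate(p, 0.0, dt=dt)
    f1 = single_cell_rate(p, delta_i, dt=dt)
    return (f1 - f0) / (delta_i / 1000.0)


def _pace_for_rate(p: NeuronParams, target_rate: float, dt: float) -> float:
    lo, hi = 0.0, 8000.0
    f = lambda ip: single_cell_rate(replace(p, i_pace=ip), dt=dt) - target_rate
    return brentq(f, lo, hi, xtol=1.0)


def calibrate_neuron(target_rate: float, target_slope: float,
                     base: NeuronParams | None = None,
                     dt: float = 0.1) -> NeuronParams:
    """Calibrate (adaptation increment, pacemaker bias) to hit the targets.

    Outer brentq on the adaptation increment matches the f-I slope; for
    every trial increment an inner brentq on the pacemaker bias matches the
    spontaneous rate.  If the slope target is outside what the adaptation
    range can reach, the nearest bracket end is used with a warning.
    """
    base = base or NeuronParams()

    def slope_err(b_w: float) -> float:
        p = replace(base, b_w=b_w)
        p = replace(p, i_pace=_pace_for_rate(p, target_rate, dt))
        return fi_slope(p, dt=dt) - target_slope

    lo, hi = 0.2, 60.0
    e_lo, e_hi = slope_err(lo), slope_err(hi)
    if e_lo * e_hi > 0:
        warnings.warn("f-I slope target outside reachable range; clamping")
        b_best = lo if abs(e_lo) < abs(e_hi) else hi
    else:
        b_best = brentq(slope_err, lo, hi, xtol=0.05)
    p = replace(base, b_w=b_best)
    p = replace(p, i_pace=_pace_for_rate(p, target_rate, dt),
                target_rate=target_rate, target_slope=target_slope)
    return p


def calibrate_population(n_cells: int, n_sets: int = 5, seed: int = 0,
                         dt: float = 0.1,
                         base: NeuronParams | None = None
                         ) -> tuple[list[NeuronParams], np.ndarray]:
    """Sample `n_sets` calibrated parameter sets and assign them to cells.

    Returns the parameter sets and the per-cell set index (random
    assignment), mirroring the heterogeneous population construction of
    sampling a few calibrated cell types per network.
    """
    rng = substream(seed, "neuron/targets")
    sets = []
    for _ in range(n_sets):
        r = rng.uniform(*RATE_RANGE)
        s = rng.uniform(*SLOPE_RANGE)
        sets.append(calibrate_neuron(r, s, base=base, dt=dt))
    assignment = rng.integers(0, n_sets, size=n_cells)
    return sets, assignment
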