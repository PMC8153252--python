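"""Network simulation: wiring, integration, binning, subsampling.

Mossy-fiber inputs contact Golgi-cell somata (connection probability 0.2
within 300 um) and parallel-fiber inputs contact apical dendrites (0.2
within 100 um along the mediolateral x axis, the parallel-fiber axis); the
"Tuned" scheme further restricts mossy fibers to their 125 um sagittal
module.  Only spike times are stored; rates are obtained by 40 ms binning
and population statistics are averaged over 10 sub-populations subsampled
from 300 x 300 x 100 um boxes, matching the imaging volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from ._rng import substream
from .activity import PopulationActivity
from .inputs import InputEnsemble, MODULE_WIDTH, sample_poisson_spikes
from .network import MF_GOC, PF_GOC, NetworkGeometry, _component_norm
from .neuron import NeuronParams, calibrate_population

__all__ = ["SpikeRaster", "SimulationDiverged", "connect_inputs", "simulate",
           "bin_rates", "subsample_populations"]

MF_RADIUS = 300.0      # um, mossy-fiber connection neighborhood
PF_X_RANGE = 100.0     # um, parallel-fiber reach along x
P_CONNECT = 0.2


class SimulationDiverged(RuntimeError):
    """Raised when a membrane potential leaves the plausible range."""

    def __init__(self, time_s: float):
        super().__init__(f"simulation diverged at t = {time_s:.4f} s")
        self.time_s = time_s


@dataclass
class SpikeRaster:
    """Per-cell spike times (s) over a fixed duration."""

    spike_times: list[np.ndarray]
    duration: float

    @property
    def n_cells(self) -> int:
        return len(self.spike_times)

    def rates(self) -> np.ndarray:
        """Mean firing rate per cell (Hz)."""
        return np.array([len(t) / self.duration for t in self.spike_times])


def connect_inputs(network: NetworkGeometry, inputs: InputEnsemble,
                   seed: int = 0, p_connect: float = P_CONNECT
                   ) -> list[np.ndarray]:
    """Target-cell index arrays per input under the geometric rules."""
    rng = substream(seed, "wiring")
    pos_c = network.positions
    targets: list[np.ndarray] = []
    for i in range(inputs.n_inputs):
        if inputs.kind[i] == "MF":
            d = np.linalg.norm(pos_c - inputs.positions[i], axis=1)
            eligible = d <= MF_RADIUS
            if inputs.module is not None and inputs.module[i] >= 0:
                cell_module = np.minimum(
                    (pos_c[:, 0] // MODULE_WIDTH).astype(int), 3)
                eligible &= cell_module == inputs.module[i]
        else:
            eligible = np.abs(pos_c[:, 0] - inputs.positions[i, 0]) <= PF_X_RANGE
        idx = np.flatnonzero(eligible)
        targets.append(idx[rng.uniform(size=len(idx)) < p_connect])
    return targets


def _event_arrays(inputs: InputEnsemble, dt_ms: float, n_steps: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    steps, ids = [], []
    for i, st in enumerate(inputs.spikes):
        s = (np.asarray(st) * 1000.0 / dt_ms).astype(np.int64)
        s = s[s < n_steps]
        steps.append(s)
        ids.append(np.full(len(s), i, dtype=np.int64))
    ev_step = np.concatenate(steps) if steps else np.empty(0, dtype=np.int64)
    ev_id = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
    order = np.argsort(ev_step, kind="stable")
    return ev_step[order], ev_id[order]


def _csr(list_of_arrays: list[np.ndarray], n_total: int
         ) -> tuple[np.ndarray, np.ndarray]:
    ptr = np.zeros(len(list_of_arrays) + 1, dtype=np.int64)
    for i, a in enumerate(list_of_arrays):
        ptr[i + 1] = ptr[i] + len(a)
    flat = (np.concatenate(list_of_arrays).astype(np.int64)
            if list_of_arrays else np.empty(0, dtype=np.int64))
    return ptr, flat


def _gj_csr(network: NetworkGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = network.n_cells
    neigh: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, g in network.gj_edges:
        if g > 0:
            neigh[i].append((j, g))
            neigh[j].append((i, g))
    indptr = np.zeros(n + 1, dtype=np.int64)
    idx, dat = [], []
    for i in range(n):
        indptr[i + 1] = indptr[i] + len(neigh[i])
        for j, g in neigh[i]:
            idx.append(j)
            dat.append(g)
    return (indptr, np.asarray(idx, dtype=np.int64),
            np.asarray(dat, dtype=float))


def simulate(
    network: NetworkGeometry,
    inputs: InputEnsemble | None,
    duration: float = 20.0,
    dt: float = 0.1,
    params: tuple[list[NeuronParams], np.ndarray] | None = None,
    i_ext: np.ndarray | float = 0.0,
    seed: int = 0,
) -> SpikeRaster:
    """Integrate the coupled network and return the spike raster.

    `dt` is the integration step in ms (0.025 ms is the reference; 0.1 ms
    is the fast mode, convergence-checked by the test suite).  Neuron
    parameters are calibrated on demand (5 sets per network) unless
    supplied.  Deterministic given `seed` and `dt`.
    """
    n = network.n_cells
    if params is None:
        params = calibrate_population(n, seed=seed, dt=dt)
    sets, assign = params

    def per_cell(attr: str) -> np.ndarray:
        return np.array([getattr(sets[assign[i]], attr) for i in range(n)])

    n_steps = int(round(duration * 1000.0 / dt))
    if inputs is not None:
        if not inputs.spikes:
            t_len = min(inputs.rates.shape[1],
                        int(round(duration / inputs.rate_dt)))
            inputs.spikes = sample_poisson_spikes(
                inputs.rates[:, :t_len], inputs.rate_dt, seed=seed)
        targets = connect_inputs(network, inputs, seed=seed)
        tgt_ptr, tgt_cell = _csr(targets, n)
        ev_step, ev_id = _event_arrays(inputs, dt, n_steps)
        is_mf = (inputs.kind == "MF").astype(np.uint8)
    else:
        tgt_ptr = np.zeros(1, dtype=np.int64)
        tgt_cell = np.empty(0, dtype=np.int64)
        ev_step = np.empty(0, dtype=np.int64)
        ev_id = np.empty(0, dtype=np.int64)
        is_mf = np.zeros(0, dtype=np.uint8)

    gj_indptr, gj_indices, gj_data = _gj_csr(network)

    p0 = sets[0]
    rng = substream(seed, "simulate/init")
    vs0 = per_cell("e_l") + rng.uniform(0.0, 15.0, n)
    vd0 = per_cell("e_l").copy()
    i_ext_arr = np.broadcast_to(np.asarray(i_ext, float), (n,)).copy()

    mf_n1 = _component_norm(MF_GOC.tau_rise, MF_GOC.tau_d1)
    mf_n2 = _component_norm(MF_GOC.tau_rise, MF_GOC.tau_d2)
    pf_n = _component_norm(PF_GOC.tau_rise, PF_GOC.tau_d1)

    max_spikes = int(n * duration * 1000.0 / p0.t_ref) + n
    sp_cell, sp_step, status, stop = _kernel.run_network(
        n_steps, dt,
        per_cell("c_s"), per_cell("c_d"), per_cell("g_ls"), per_cell("g_ld"),
        per_cell("g_c"), per_cell("e_l"), per_cell("v_th"),
        per_cell("v_reset"), per_cell("i_pace"), per_cell("b_w"), i_ext_arr,
        int(round(p0.t_ref / dt)), np.exp(-dt / p0.tau_w),
        np.exp(-dt / MF_GOC.tau_d1), np.exp(-dt / MF_GOC.tau_d2),
        np.exp(-dt / MF_GOC.tau_rise), MF_GOC.g1 / mf_n1, MF_GOC.g2 / mf_n2,
        np.exp(-dt / PF_GOC.tau_d1), np.exp(-dt / PF_GOC.tau_rise),
        PF_GOC.g1 / pf_n,
        gj_indptr, gj_indices, gj_data,
        ev_step, ev_id, tgt_ptr, tgt_cell, is_mf,
        vs0, vd0, max_spikes,
        p0.spike_area,
        p0.noise_sigma, p0.noise_tau,
        int(rng.integers(0, 2**31 - 1)),
    )
    if status != _kernel.STATUS_OK:
        raise SimulationDiverged(stop * dt / 1000.0)

    times = sp_step.astype(float) * dt / 1000.0
    spike_times = [np.sort(times[sp_cell == i]) for i in range(n)]
    return SpikeRaster(spike_times=spike_times, duration=duration)


def bin_rates(raster: SpikeRaster, bin: float = 0.04,
              positions: np.ndarray | None = None) -> PopulationActivity:
    """Convert spike times to firing rates (Hz) in `bin` s bins.

    Total spike count is conserved: sum over bins of rate * bin equals the
    per-cell spike count.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    n_bins = int(np.ceil(raster.duration / bin - 1e-9))
    rates = np.zeros((raster.n_cells, n_bins))
    for i, t in enumerate(raster.spike_times):
        idx = np.minimum((np.asarray(t) / bin).astype(int), n_bins - 1)
        np.add.at(rates[i], idx, 1.0 / bin)
    return PopulationActivity(rates=rates, bin=bin, positions=positions,
                              kind="events")


def subsample_populations(
    activity: PopulationActivity,
    volume: tuple[float, float, float],
    box: tuple[float, float, float] = (300.0, 300.0, 100.0),
    n: int = 10,
    seed: int = 0,
) -> list[PopulationActivity]:
    """Sub-populations from `n` randomly offset boxes inside the volume.

    Cells strictly inside each box are kept; downstream statistics are
    averaged over the boxes to emulate repeated imaging volumes.
    """
    if activity.positions is None:
        raise ValueError("activity carries no positions")
    if any(b > v for b, v in zip(box, volume)):
        raise ValueError("box must fit inside the volume")
    rng = substream(seed, "subsample")
    out = []
    for _ in range(n):
        offset = np.array([rng.uniform(0, v - b) for b, v in zip(box, volume)])
        inside = np.all(
            (activity.positions > offset)
            & (activity.positions < offset + np.asarray(box)), axis=1)
        out.append(activity.select(np.flatnonzero(inside)))
    return out
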