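"""Golgi-cell network construction: geometry, gap junctions, synapse kinetics.

Cells are placed uniformly at random in a 500 x 500 x 100 um slab of the
granule cell layer (115 cells at the measured anatomical density).  The
probability that two cells at intersomatic distance d (um) are electrically
coupled follows the paired-recording-derived sigmoid

    P(d) = H(0.01 * (-1745 + 1836 / (1 + exp((d - 267) / 39)))),

with H clamping to [0, 1], and the total gap-junction conductance of a
connected pair is a quantized, distance-dependent multiple of the
single-junction conductance g0 = 0.9 nS:

    g(d) = g0 * round(k * Y(d) / 5),   Y(d) = -2.3 + 29.7 * exp(-d / 70.4),

where k scales coupling strength (k = 1 physiological, k = 0 uncoupled).
At k = 1 this yields a mean total GJ conductance per cell of ~22 nS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream

__all__ = [
    "NetworkGeometry",
    "SynapseKinetics",
    "MF_GOC",
    "PF_GOC",
    "connection_probability",
    "gj_conductance",
    "build_network",
    "synaptic_waveform",
    "peak_conductance",
]

DEFAULT_VOLUME = (500.0, 500.0, 100.0)   # um
DEFAULT_N_CELLS = 115
DEFAULT_G0 = 0.9                          # nS, single gap junction


def connection_probability(d) -> np.ndarray:
    """Probability of electrical coupling at intersomatic distance d (um)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    with np.errstate(over="ignore"):        # exp overflow -> P = 0 anyway
        inner = 0.01 * (-1745.0 + 1836.0 / (1.0 + np.exp((d - 267.0) / 39.0)))
    return np.clip(inner, 0.0, 1.0)


def gj_conductance(d, k: float = 1.0, g0: float = DEFAULT_G0) -> np.ndarray:
    """Total gap-junction conductance (nS) of a connected pair at distance d.

    The number of junctions is the quantized distance-dependent count
    round(k * Y(d) / 5) (half-away-from-zero rounding, clamped at zero),
    each contributing g0.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or k < 0:
        raise ValueError("distance and coupling scale must be non-negative")
    y = -2.3 + 29.7 * np.exp(-d / 70.4)
    n = np.floor(k * y / 5.0 + 0.5)       # round half away from zero for x>=0
    return g0 * np.clip(n, 0.0, None)


@dataclass
class NetworkGeometry:
    """Cell positions and gap-junction adjacency of one network realization."""

    positions: np.ndarray                      # (n, 3) um
    gj_edges: list[tuple[int, int, float]]     # (i, j, conductance nS), i < j
    volume: tuple[float, float, float] = DEFAULT_VOLUME
    coupling_scale: float = 1.0
    g0: float = DEFAULT_G0
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def adjacency(self) -> np.ndarray:
        """Dense symmetric conductance matrix (nS), zero diagonal."""
        g = np.zeros((self.n_cells, self.n_cells))
        for i, j, c in self.gj_edges:
            g[i, j] = g[j, i] = c
        return g

    def total_conductance_per_cell(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)

    def distances(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(-1))


def build_network(
    n_cells: int = DEFAULT_N_CELLS,
    volume: tuple[float, float, float] = DEFAULT_VOLUME,
    k: float = 1.0,
    g0: float = DEFAULT_G0,
    seed: int = 0,
) -> NetworkGeometry:
    """Random network realization: uniform placement, stochastic GJ wiring.

    Each unordered pair is connected with probability P(d) and assigned
    conductance g(d); k = 0 produces the uncoupled ("noGJ") control in
    which every edge has zero conductance.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = substream(seed, "network/geometry")
    positions = rng.uniform(0, 1, (n_cells, 3)) * np.asarray(volume)
    diff = positions[:, None, :] - positions[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n_cells, k=1)
    p = connection_probability(d[iu])
    connected = rng.uniform(size=len(p)) < p
    g = gj_conductance(d[iu][connected], k=k, g0=g0)
    edges = [(int(a), int(b), float(c))
             for a, b, c in zip(iu[0][connected], iu[1][connected], g)]
    return NetworkGeometry(positions=positions, gj_edges=edges, volume=volume,
                           coupling_scale=k, g0=g0, seed=seed)


@dataclass
class SynapseKinetics:
    """Rise/decay bi-exponential AMPA conductance, one or two decay terms.

    Each component i is peak-normalized so its amplitude equals g_i; the
    printed "peak conductance" of a synapse is the maximum of the summed
    waveform (slightly below g1 + g2 because the components peak at
    different times).
    """

    e_rev: float                 # mV
    tau_rise: float              # ms
    g1: float                    # nS
    tau_d1: float                # ms
    g2: float | None = None      # nS, absent for single-exponential decay
    tau_d2: float | None = None  # ms
    target: str = "soma"

    def __post_init__(self) -> None:
        decays = [self.tau_d1] + ([self.tau_d2] if self.tau_d2 else [])
        if self.tau_rise <= 0 or any(t <= 0 for t in decays):
            raise ValueError("time constants must be positive")
        if any(self.tau_rise >= t for t in decays):
            raise ValueError("tau_rise must be smaller than every decay constant")

    @property
    def components(self) -> list[tuple[float, float]]:
        comps = [(self.g1, self.tau_d1)]
        if self.g2 is not None and self.tau_d2 is not None:
            comps.append((self.g2, self.tau_d2))
        return comps


#: mossy fiber -> GoC soma (double-exponential decay)
MF_GOC = SynapseKinetics(e_rev=0.0, tau_rise=0.1, g1=0.7, tau_d1=0.7,
                         g2=0.2, tau_d2=3.5, target="soma")
#: parallel fiber -> GoC apical dendrite (single-exponential decay)
PF_GOC = SynapseKinetics(e_rev=0.0, tau_rise=0.1, g1=0.67, tau_d1=1.06,
                         target="dendrite")


def _component_norm(tau_r: float, tau_d: float) -> float:
    """Peak of exp(-t/tau_d) - exp(-t/tau_r)."""
    t_peak = tau_d * tau_r / (tau_d - tau_r) * np.log(tau_d / tau_r)
    return np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)


def synaptic_waveform(kin: SynapseKinetics, t) -> np.ndarray:
    """Summed conductance waveform (nS) at time(s) t (ms) after a spike."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    g = np.zeros_like(t)
    for gi, tau_d in kin.components:
        norm = _component_norm(kin.tau_rise, tau_d)
        g = g + gi * (np.exp(-t / tau_d) - np.exp(-t / kin.tau_rise)) / norm
    return g


def peak_conductance(kin: SynapseKinetics) -> float:
    """Peak (nS) of the summed waveform.

    For a single component the peak equals its g value exactly (by
    peak-normalization); for summed components the maximum is located
    numerically around the analytic component peaks.
    """
    t_peaks = [tau * kin.tau_rise / (tau - kin.tau_rise)
               * np.log(tau / kin.tau_rise) for _, tau in kin.components]
    if len(t_peaks) == 1:
        return float(synaptic_waveform(kin, [t_peaks[0]])[0])
    t = np.linspace(0.0, 3.0 * max(t_peaks), 200001)
    return float(synaptic_waveform(kin, t).max())
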