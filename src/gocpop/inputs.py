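"""Behavior-modulated Poisson input populations (mossy and parallel fibers).

Each input k fires as an inhomogeneous Poisson process whose rate is a
sparse linear readout of the normalized 6-dimensional behavioral vector,

    r_k(t) = A * (w_k . b(t)) + c,

clamped below at a 2 Hz floor.  Four connectivity/weight schemes are
supported — "Input-Beh" (A = 50 Hz, c = 7 Hz, weights uniform [0, 1] with
50% sparsity), "Bimodal" (a second, negatively modulated population with
A = -25 Hz, c = 30 Hz), "Uncorrelated" (extra inputs driven by different
behavior segments) and "Tuned" (four 125 um sagittal modules, each
dominated by one behavioral variable) — plus a constant-rate background
population (30 MFs at 5 Hz, 60 PFs at 2 Hz) that is always present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .behavior import BehaviorTraces

__all__ = ["InputEnsemble", "make_input_rates", "sample_poisson_spikes"]

SCHEMES = ("Input-Beh", "Bimodal", "Uncorrelated", "Tuned")
RATE_FLOOR = 2.0      # Hz
A_DEFAULT = 50.0      # Hz
C_DEFAULT = 7.0       # Hz
A_NEG = -25.0         # Hz, negatively modulated (Bimodal) population
C_NEG = 30.0          # Hz
N_BG_MF, BG_MF_RATE = 30, 5.0
N_BG_PF, BG_PF_RATE = 60, 2.0
MODULE_WIDTH = 125.0  # um, sagittal module width for the Tuned scheme


@dataclass
class InputEnsemble:
    """A population of input spike trains with their rate definitions."""

    kind: np.ndarray              # (n,) "MF" | "PF"
    background: np.ndarray        # (n,) bool, constant-rate background inputs
    positions: np.ndarray         # (n, 3) um
    weights: np.ndarray           # (n, 6); zeros for background inputs
    rates: np.ndarray             # (n, T) Hz on the behavior grid
    rate_dt: float                # s, grid step of `rates`
    scheme: str = "Input-Beh"
    a_scale: float = A_DEFAULT
    c_offset: float = C_DEFAULT
    rate_floor: float = RATE_FLOOR
    module: np.ndarray | None = None   # Tuned scheme module index per input
    spikes: list = field(default_factory=list)   # spike-time arrays, s

    @property
    def n_inputs(self) -> int:
        return len(self.kind)

    def modulated(self) -> np.ndarray:
        """Indices of behavior-driven (non-background) inputs."""
        return np.flatnonzero(~self.background)

    def binned_rates(self, bin: float = 0.04,
                     include_background: bool = False) -> np.ndarray:
        """Empirical spike rates (Hz) of the sampled trains in `bin` s bins."""
        if not self.spikes:
            raise ValueError("no spike trains sampled yet")
        duration = self.rates.shape[1] * self.rate_dt
        n_bins = int(round(duration / bin))
        sel = (np.arange(self.n_inputs) if include_background
               else self.modulated())
        out = np.zeros((len(sel), n_bins))
        for row, i in enumerate(sel):
            idx = np.minimum((np.asarray(self.spikes[i]) / bin).astype(int),
                             n_bins - 1)
            np.add.at(out[row], idx, 1.0 / bin)
        return out


def _sparse_uniform_weights(rng: np.random.Generator, n: int,
                            p_zero: float = 0.5) -> np.ndarray:
    w = rng.uniform(0.0, 1.0, (n, 6))
    w[rng.uniform(size=w.shape) < p_zero] = 0.0
    return w


def make_input_rates(
    behavior: BehaviorTraces,
    scheme: str = "Input-Beh",
    n_mf: int = 24,
    n_pf: int = 60,
    volume: tuple[float, float, float] = (500.0, 500.0, 100.0),
    seed: int = 0,
    bimodal_fraction: float = 0.5,
    uncorrelated_fraction: float = 1.0,
) -> InputEnsemble:
    """Build the input ensemble's positions, weights and rate traces.

    The behavioral matrix b(t) is the min-max-normalized 6-channel state
    vector; rates are read from a fixed 20 s segment, so `behavior`
    must cover at least 20 s.  "Uncorrelated" extra inputs read a different
    random circularly-shifted segment of the behavior, decorrelating them
    from the ongoing-behavior-driven population.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if behavior.duration < 20.0:
        raise ValueError("behavior must cover at least 20 s")
    rng = substream(seed, "inputs")
    b = behavior.matrix(normalize=True)
    t_len = b.shape[1]
    rate_dt = 1.0 / behavior.sampling_rate

    kinds = ["MF"] * n_mf + ["PF"] * n_pf
    n_beh = len(kinds)
    weights = _sparse_uniform_weights(rng, n_beh)
    a = np.full(n_beh, A_DEFAULT)
    c = np.full(n_beh, C_DEFAULT)
    shifts = np.zeros(n_beh, dtype=int)
    module = None

    if scheme == "Bimodal":
        neg = rng.uniform(size=n_beh) < bimodal_fraction
        a[neg], c[neg] = A_NEG, C_NEG
    elif scheme == "Uncorrelated":
        n_extra_mf = int(round(uncorrelated_fraction * n_mf))
        n_extra_pf = int(round(uncorrelated_fraction * n_pf))
        kinds += ["MF"] * n_extra_mf + ["PF"] * n_extra_pf
        n_extra = n_extra_mf + n_extra_pf
        weights = np.vstack([weights, _sparse_uniform_weights(rng, n_extra)])
        a = np.concatenate([a, np.full(n_extra, A_DEFAULT)])
        c = np.concatenate([c, np.full(n_extra, C_DEFAULT)])
        shifts = np.concatenate([
            shifts, rng.integers(int(2.0 / rate_dt), t_len, size=n_extra)])
        n_beh += n_extra

    positions = rng.uniform(0, 1, (n_beh, 3)) * np.asarray(volume)

    if scheme == "Tuned":
        # four sagittal slabs along x; dominant variable permuted across them
        module = np.minimum((positions[:, 0] // MODULE_WIDTH).astype(int), 3)
        variable_sets = [("loco",), ("wmi", "wamp"), ("pupil",), ("wsp",)]
        perm = rng.permutation(4)
        chan_idx = {"state": 0, "loco": 1, "wsp": 2, "wmi": 3, "wamp": 4,
                    "pupil": 5}
        weights = rng.uniform(-0.1, 0.1, (n_beh, 6))
        for i in range(n_beh):
            for name in variable_sets[perm[module[i]]]:
                weights[i, chan_idx[name]] = rng.uniform(0.5, 1.0)
        weights[rng.uniform(size=weights.shape) < 0.3] = 0.0

    rates = np.empty((n_beh, t_len))
    for i in range(n_beh):
        bi = np.roll(b, shifts[i], axis=1) if shifts[i] else b
        rates[i] = np.clip(a[i] * (weights[i] @ bi) + c[i], RATE_FLOOR, None)

    # constant-rate background population, always present
    n_bg = N_BG_MF + N_BG_PF
    kinds += ["MF"] * N_BG_MF + ["PF"] * N_BG_PF
    bg_rates = np.concatenate([np.full(N_BG_MF, BG_MF_RATE),
                               np.full(N_BG_PF, BG_PF_RATE)])
    rates = np.vstack([rates, np.tile(bg_rates[:, None], (1, t_len))])
    weights = np.vstack([weights, np.zeros((n_bg, 6))])
    positions = np.vstack([positions,
                           rng.uniform(0, 1, (n_bg, 3)) * np.asarray(volume)])
    background = np.zeros(n_beh + n_bg, dtype=bool)
    background[n_beh:] = True
    if module is not None:
        module = np.concatenate([module, np.full(n_bg, -1)])

    return InputEnsemble(
        kind=np.array(kinds), background=background, positions=positions,
        weights=weights, rates=rates, rate_dt=rate_dt, scheme=scheme,
        module=module,
    )


def sample_poisson_spikes(rates: np.ndarray, rate_dt: float,
                          seed: int = 0) -> list[np.ndarray]:
    """Draw spike trains from inhomogeneous Poisson processes by thinning.

    `rates` is (n_trains, T) in Hz on a grid with step `rate_dt` seconds
    (piecewise-constant rate).  Exact for piecewise-constant intensities:
    candidates are generated at each train's maximal rate and accepted with
    probability r(t)/r_max.
    """
    rates = np.atleast_2d(np.asarray(rates, float))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    rng = substream(seed, "poisson")
    duration = rates.shape[1] * rate_dt
    out: list[np.ndarray] = []
    for r in rates:
        rmax = float(r.max())
        if rmax == 0:
            out.append(np.empty(0))
            continue
        n_cand = rng.poisson(rmax * duration)
        cand = np.sort(rng.uniform(0, duration, n_cand))
        local = r[np.minimum((cand / rate_dt).astype(int), len(r) - 1)]
        keep = rng.uniform(size=n_cand) < local / rmax
        out.append(cand[keep])
    return out
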