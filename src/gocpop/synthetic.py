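"""Surrogate population recordings with known ground truth.

Emulates the structure of Golgi-cell population recordings: a dominant slow
common mode (PM1) tracking the overall level of behavioral activity with
all-positive loadings, a handful of faster differential modes with spatially
unstructured mixed-sign loadings, and independent noise — optionally passed
through slow calcium-indicator kinetics.  The generator returns its own
loadings and dynamics so that mode-recovery, dimensionality and decoding
analyses can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._rng import substream
from .activity import PopulationActivity
from .behavior import BEHAVIOR_CHANNELS, BehaviorTraces

__all__ = [
    "SyntheticSessionSpec",
    "SyntheticGroundTruth",
    "generate_population_activity",
    "generate_puff_trials",
    "generate_step_session",
]


@dataclass
class SyntheticSessionSpec:
    """Parameters of one surrogate session.

    Variance fractions are of the total per-entry variance of the generated
    matrix; they must sum to at most 1 (any remainder is simply absent
    variance).  ``indicator_tau = 0`` disables the indicator convolution.
    """

    n_neurons: int = 40
    duration: float = 300.0          # s
    bin: float = 0.04                # s
    volume: tuple[float, float, float] = (300.0, 300.0, 100.0)  # um
    pm1_amplitude: float = 0.7       # variance fraction of the common mode
    n_diff_modes: int = 5
    diff_mode_variance: float = 0.2  # total fraction across differential modes
    noise_variance: float = 0.1
    indicator_tau: float = 0.0       # s, single-exponential kernel
    mode_behaviors: tuple[str, ...] = ()  # behavior carried by diff modes
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.pm1_amplitude, self.diff_mode_variance, self.noise_variance)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ValueError("variance fractions must lie in [0,1] and sum <= 1")
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")
        if self.n_diff_modes < 0:
            raise ValueError("n_diff_modes must be >= 0")
        for name in self.mode_behaviors:
            if name not in BEHAVIOR_CHANNELS:
                raise ValueError(f"unknown behavior channel {name!r}")


@dataclass
class SyntheticGroundTruth:
    """What the generator actually put into the matrix."""

    pm1_loading: np.ndarray              # (n,) unit norm, all positive
    pm1_dynamics: np.ndarray             # (T,) centered
    diff_loadings: np.ndarray            # (n, n_diff) orthonormal, w/ mixed signs
    diff_dynamics: np.ndarray            # (T, n_diff) centered
    variance_fractions: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return 1 + self.diff_loadings.shape[1]

    @property
    def loadings(self) -> np.ndarray:
        return np.column_stack([self.pm1_loading, self.diff_loadings])


def _resample_mean(x: np.ndarray, fs: float, bin: float) -> np.ndarray:
    """Bin-average a trace sampled at `fs` into bins of width `bin` seconds."""
    step = max(int(round(bin * fs)), 1)
    n = len(x) // step
    return x[: n * step].reshape(n, step).mean(axis=1)


def _indicator(x: np.ndarray, tau: float, bin: float) -> np.ndarray:
    """Causal single-exponential convolution (unit-area kernel) along time."""
    if tau <= 0:
        return x
    t = np.arange(0, 6 * tau, bin)
    kern = np.exp(-t / tau)
    kern /= kern.sum()
    # causal: prepend the edge value so onset transients are not inflated
    if x.ndim == 1:
        xp = np.concatenate([np.full(len(kern) - 1, x[0]), x])
        return np.convolve(xp, kern, mode="valid")
    xp = np.concatenate([np.tile(x[:, :1], (1, len(kern) - 1)), x], axis=1)
    return np.apply_along_axis(lambda r: np.convolve(r, kern, "valid"), 1, xp)


def _scaled(component: np.ndarray, fraction: float) -> np.ndarray:
    """Scale a centered component matrix so its mean per-entry variance is
    `fraction` (total generated variance is 1 in arbitrary units)."""
    v = float(np.mean(component**2))
    if v == 0 or fraction == 0:
        return np.zeros_like(component)
    return component * np.sqrt(fraction / v)


def generate_population_activity(
    spec: SyntheticSessionSpec, behavior: BehaviorTraces
) -> tuple[PopulationActivity, SyntheticGroundTruth]:
    """Build a surrogate neurons x time matrix from a behavioral session.

    PM1 dynamics are a slow (>= 1 s autocorrelation) transform of overall
    behavioral intensity with strictly positive loadings; differential modes
    have faster dynamics and spatially unstructured loadings orthogonal to
    PM1 and each other; optionally a differential mode carries the fast
    component of a named behavioral channel (``spec.mode_behaviors``).
    """
    if behavior.duration + 1e-9 < spec.duration:
        raise ValueError("behavior does not cover the requested duration")
    fs = behavior.sampling_rate
    n_bins = int(round(spec.duration / spec.bin))
    rng = substream(spec.seed, "synthetic/loadings")

    # -- loadings -----------------------------------------------------------
    pm1_load = np.abs(1.0 + 0.3 * rng.standard_normal(spec.n_neurons))
    pm1_load /= np.linalg.norm(pm1_load)
    raw = rng.standard_normal((spec.n_neurons, spec.n_diff_modes))
    basis = np.column_stack([pm1_load, raw])
    q, _ = np.linalg.qr(basis)
    diff_load = q[:, 1:] * np.sign(np.sum(q[:, 1:], axis=0) + 1e-12)

    # -- dynamics -----------------------------------------------------------
    b = behavior.matrix(normalize=True)
    intensity = b[[1, 3, 4, 5]].mean(axis=0)          # loco, WMI, WAmp, pupil
    slow = gaussian_filter1d(intensity, sigma=0.5 * fs, mode="nearest")
    pm1_dyn = _resample_mean(slow, fs, spec.bin)[:n_bins]
    pm1_dyn = pm1_dyn - pm1_dyn.mean()

    rng_dyn = substream(spec.seed, "synthetic/dynamics")
    diff_dyn = np.empty((n_bins, spec.n_diff_modes))
    for k in range(spec.n_diff_modes):
        if k < len(spec.mode_behaviors):
            chan = np.asarray(getattr(behavior, spec.mode_behaviors[k]), float)
            fast = chan - gaussian_filter1d(chan, sigma=1.0 * fs, mode="nearest")
            d = _resample_mean(fast, fs, spec.bin)[:n_bins]
        else:
            white = rng_dyn.standard_normal(int(spec.duration * fs))
            d = _resample_mean(
                gaussian_filter1d(white, sigma=0.2 * fs, mode="nearest"),
                fs, spec.bin)[:n_bins]
        d = d - d.mean()
        sd = d.std()
        diff_dyn[:, k] = d / sd if sd > 0 else d

    if spec.indicator_tau > 0:
        pm1_dyn = _indicator(pm1_dyn, spec.indicator_tau, spec.bin)
        pm1_dyn -= pm1_dyn.mean()
        diff_dyn = _indicator(diff_dyn.T, spec.indicator_tau, spec.bin).T
        diff_dyn -= diff_dyn.mean(axis=0)

    # -- assemble with exact variance fractions; differential-mode variances
    # decay geometrically (0.7 ratio) so the planted spectrum is
    # non-degenerate and the modes identifiable, as in recorded eigenspectra
    if spec.n_diff_modes:
        w = 0.7 ** np.arange(spec.n_diff_modes)
        per_mode = spec.diff_mode_variance * w / w.sum()
    else:
        per_mode = np.empty(0)
    pm1_part = _scaled(np.outer(pm1_load, pm1_dyn), spec.pm1_amplitude)
    diff_part = np.zeros((spec.n_neurons, n_bins))
    for k in range(spec.n_diff_modes):
        diff_part += _scaled(
            np.outer(diff_load[:, k], diff_dyn[:, k]), per_mode[k])

    rng_noise = substream(spec.seed, "synthetic/noise")
    noise = rng_noise.standard_normal((spec.n_neurons, n_bins))
    if spec.indicator_tau > 0:
        noise = _indicator(noise, spec.indicator_tau, spec.bin)
    noise = _scaled(noise - noise.mean(axis=1, keepdims=True),
                    spec.noise_variance)

    x = pm1_part + diff_part + noise + 5.0     # baseline offset, a.u.

    rng_pos = substream(spec.seed, "synthetic/positions")
    positions = rng_pos.uniform(0, 1, (spec.n_neurons, 3)) * np.array(spec.volume)

    activity = PopulationActivity(rates=x, bin=spec.bin, positions=positions,
                                  kind="events", meta={"synthetic": True})
    truth = SyntheticGroundTruth(
        pm1_loading=pm1_load, pm1_dynamics=pm1_dyn,
        diff_loadings=diff_load, diff_dynamics=diff_dyn,
        variance_fractions={
            "pm1": spec.pm1_amplitude,
            "diff": spec.diff_mode_variance,
            "noise": spec.noise_variance,
        },
    )
    return activity, truth


# ---------------------------------------------------------------------------
# event-aligned surrogates
# ---------------------------------------------------------------------------

def generate_puff_trials(
    n_trials: int = 20,
    n_neurons: int = 30,
    fs: float = 1000.0,
    pre: float = 0.6,
    post: float = 1.0,
    class_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    latency_spread_neurons: float = 0.15,
    latency_jitter_trials: float = 0.03,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Simulate air-puff-aligned event trains for a population.

    Returns ``(rates, event_times, puff_times, truth)`` where `rates` is a
    neurons x time matrix of event counts at `fs`, `event_times` a list of
    event-time arrays per neuron, `puff_times` the puff onsets (s) and
    `truth` a dict holding each neuron's class and mean latency.  Class I
    neurons respond fast and transiently, class II with a sustained/variable
    delay, class III not at all; neuron-to-neuron latency spread exceeds
    trial-to-trial jitter by construction.
    """
    rng = substream(seed, "puff")
    trial_len = pre + post + 0.4
    duration = n_trials * trial_len
    puff_times = pre + trial_len * np.arange(n_trials)
    classes = rng.choice([1, 2, 3], size=n_neurons, p=class_fractions)
    # fast-transient cells respond promptly; variable-delay cells span a
    # broad latency range (that is what distinguishes the classes)
    mean_latency = np.where(
        classes == 1,
        np.clip(0.04 + np.abs(rng.normal(0, 0.03, n_neurons)), 0.02, 0.12),
        np.clip(0.1 + rng.exponential(latency_spread_neurons, n_neurons),
                0.05, 0.6))

    n_samp = int(duration * fs)
    t = np.arange(n_samp) / fs
    event_times: list[np.ndarray] = []
    rates = np.zeros((n_neurons, n_samp))
    for i in range(n_neurons):
        lam = np.full(n_samp, 1.0)                     # 1 Hz baseline
        for p in puff_times:
            lat = mean_latency[i] + latency_jitter_trials * rng.standard_normal()
            onset = p + max(lat, 0.01)
            if classes[i] == 1:
                m = (t >= onset) & (t < onset + 0.15)
                lam[m] += 25.0
            elif classes[i] == 2:
                m = (t >= onset) & (t < p + 0.8)
                lam[m] += 6.0
        spikes = t[rng.uniform(size=n_samp) < lam / fs]
        event_times.append(spikes)
        idx = (spikes * fs).astype(int)
        np.add.at(rates[i], idx, 1.0)
    truth = {"classes": classes, "mean_latency": mean_latency}
    return rates, np.array(event_times, dtype=object), puff_times, truth


def generate_step_session(
    n_lifts: int = 40,
    n_neurons: int = 12,
    modulated_fraction: float = 0.5,
    fs: float = 200.0,
    cycle: float = 0.5,
    seed: int = 0,
) -> dict:
    """Simulate a running bout with periodic paw lifts and phase-locked cells.

    Returns a dict with per-neuron event times, lift times, the paw-height
    trace (time, height) and the ground-truth modulation flags.  Modulated
    neurons fire preferentially near the lift peak; unmodulated neurons are
    homogeneous Poisson at the same mean rate.
    """
    rng = substream(seed, "step")
    duration = (n_lifts + 2) * cycle
    t = np.arange(int(duration * fs)) / fs
    lift_times = cycle * (1 + np.arange(n_lifts)) + 0.02 * rng.standard_normal(n_lifts)
    paw = np.zeros_like(t)
    for lt in lift_times:
        paw += np.exp(-0.5 * ((t - lt) / 0.08) ** 2)   # 80 ms lift bump

    modulated = np.zeros(n_neurons, dtype=bool)
    modulated[: int(round(modulated_fraction * n_neurons))] = True
    base_rate = 8.0
    events: list[np.ndarray] = []
    for i in range(n_neurons):
        if modulated[i]:
            lam = base_rate * (0.2 + 3.0 * paw)
        else:
            lam = np.full_like(t, base_rate)
        events.append(t[rng.uniform(size=len(t)) < lam / fs])
    return {
        "events": events,
        "lift_times": lift_times,
        "paw_time": t,
        "paw_height": paw,
        "modulated": modulated,
    }
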