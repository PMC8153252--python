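"""Behavioral time series: synthesis, whisker kinematics, active-period detection.

The behavioral state vector b(t) used throughout the package has six
channels — binary state, locomotion speed, whisker setpoint (WSP), whisker
motion index (WMI), whisking amplitude (WAmp) and pupil area — mirroring the
covariates recorded in head-fixed mice on a running wheel.  The synthetic
generator emulates their joint statistics (alternating quiet/active bouts,
8-15 Hz whisking during activity, slow pupil dynamics, pairwise correlation
between channels) so that the downstream analyses run without any recorded
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import butter, filtfilt, hilbert

from ._rng import substream
from .activity import PopulationActivity

__all__ = [
    "BehaviorTraces",
    "ActivePeriods",
    "EpochParams",
    "generate_behavior",
    "whisker_kinematics",
    "detect_active_periods",
    "compute_dff",
]

#: order of channels in the behavioral state vector b(t)
BEHAVIOR_CHANNELS = ("state", "loco", "wsp", "wmi", "wamp", "pupil")


@dataclass
class BehaviorTraces:
    """Multivariate behavioral time series on a uniform grid."""

    time: np.ndarray          # s
    state: np.ndarray         # binary {0, 1}
    loco: np.ndarray          # locomotion speed, a.u. >= 0
    wmi: np.ndarray           # whisker motion index, a.u. >= 0
    phi: np.ndarray           # whisker angle, deg
    wamp: np.ndarray          # whisking amplitude, deg >= 0
    wsp: np.ndarray           # whisker setpoint, deg
    pupil: np.ndarray         # pupil area, a.u. >= 0
    sampling_rate: float      # Hz
    active_bouts: list[tuple[float, float]] | None = None  # generator truth

    def __post_init__(self) -> None:
        arrays = [self.time, self.state, self.loco, self.wmi, self.phi,
                  self.wamp, self.wsp, self.pupil]
        n = len(self.time)
        if any(len(a) != n for a in arrays):
            raise ValueError("all behavioral channels must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isin(self.state, (0, 1)).all():
            raise ValueError("state must be binary")
        if (self.wamp < 0).any():
            raise ValueError("whisking amplitude must be non-negative")

    @property
    def duration(self) -> float:
        return len(self.time) / self.sampling_rate

    def matrix(self, normalize: bool = True) -> np.ndarray:
        """Return b(t) as a (6, T) matrix in channel order
        (state, loco, WSP, WMI, WAmp, pupil).

        With ``normalize`` each channel is min-max scaled to [0, 1] over the
        session (a constant channel maps to 0), the scale on which input
        weights and activity thresholds are defined.
        """
        rows = [self.state, self.loco, self.wsp, self.wmi, self.wamp, self.pupil]
        b = np.vstack([np.asarray(r, dtype=float) for r in rows])
        if normalize:
            lo = b.min(axis=1, keepdims=True)
            hi = b.max(axis=1, keepdims=True)
            span = np.where(hi - lo > 0, hi - lo, 1.0)
            b = (b - lo) / span
        return b

    def segment(self, t0: float, t1: float) -> "BehaviorTraces":
        """Extract the sub-interval [t0, t1)."""
        i0 = int(round(t0 * self.sampling_rate))
        i1 = int(round(t1 * self.sampling_rate))
        sl = slice(i0, i1)
        return replace(
            self,
            time=self.time[sl] - self.time[sl][0],
            state=self.state[sl], loco=self.loco[sl], wmi=self.wmi[sl],
            phi=self.phi[sl], wamp=self.wamp[sl], wsp=self.wsp[sl],
            pupil=self.pupil[sl], active_bouts=None,
        )


@dataclass
class ActivePeriods:
    """Non-overlapping behaviorally active intervals, in seconds."""

    intervals: list[tuple[float, float]]
    padding: float = 0.5

    def __post_init__(self) -> None:
        for (a, b), (c, _) in zip(self.intervals, self.intervals[1:]):
            if b > c:
                raise ValueError("intervals must be sorted and non-overlapping")

    def total_time(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def mask(self, time: np.ndarray, padded: bool = False) -> np.ndarray:
        """Boolean mask over `time` (s), optionally widened by `padding`."""
        pad = self.padding if padded else 0.0
        m = np.zeros(len(time), dtype=bool)
        for a, b in self.intervals:
            m |= (time >= a - pad) & (time < b + pad)
        return m


@dataclass
class EpochParams:
    """Bout and correlation structure of the synthetic behavior.

    Bout lengths are log-normal (the generator's stand-in for the broad,
    right-skewed bout-duration distributions of freely behaving mice);
    ``active_prob`` is the probability that a scheduled active bout actually
    occurs, so 0 yields an entirely quiet session.  Active bouts are
    whisking bouts; each additionally contains locomotion with probability
    ``run_prob`` (mice whisk without running far more often than the
    converse), so the behavioral channels are correlated but not
    redundant, as in head-fixed recordings.
    """

    active_prob: float = 1.0
    active_mean: float = 4.0     # s, log-normal mean of active bouts
    active_sigma: float = 0.4    # log-sd
    quiet_mean: float = 4.0      # s
    quiet_sigma: float = 0.5
    run_prob: float = 0.5        # P(locomotion | active bout)
    whisk_freq: tuple[float, float] = (8.0, 15.0)   # Hz
    wamp_active: float = 12.0    # deg, typical amplitude when whisking
    wsp_base: float = 5.0        # deg
    wsp_active: float = 12.0     # deg protraction of the setpoint
    loco_amp: float = 10.0       # a.u.
    shared_noise: float = 0.4    # fraction of within-bout noise shared


def _ou(rng: np.random.Generator, n: int, fs: float, tau: float,
        sigma: float = 1.0) -> np.ndarray:
    """Ornstein-Uhlenbeck noise with correlation time `tau` (s), unit-ish SD."""
    a = np.exp(-1.0 / (fs * tau))
    x = np.empty(n)
    scale = sigma * np.sqrt(1 - a * a)
    w = rng.standard_normal(n)
    x[0] = sigma * w[0]
    for i in range(1, n):
        x[i] = a * x[i - 1] + scale * w[i]
    return x


def generate_behavior(
    duration: float,
    sampling_rate: float = 100.0,
    epoch_params: EpochParams | None = None,
    seed: int = 0,
) -> BehaviorTraces:
    """Simulate a behavioral session with alternating quiet/active bouts.

    During active bouts locomotion and whisker motion are elevated, the
    whisker oscillates at 8-15 Hz about a protracted setpoint, and pupil
    area rises slowly; channels share a common bout envelope plus partially
    shared noise, giving the pairwise correlations the analyses expect.
    Deterministic given `seed`.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    p = epoch_params or EpochParams()
    fs = float(sampling_rate)
    n = int(round(duration * fs))
    time = np.arange(n) / fs

    rng_bouts = substream(seed, "behavior/bouts")
    # -- alternating bout schedule ------------------------------------------
    bouts: list[tuple[float, float]] = []
    running: list[bool] = []
    t = float(rng_bouts.lognormal(np.log(p.quiet_mean), p.quiet_sigma))
    while t < duration:
        length = float(rng_bouts.lognormal(np.log(p.active_mean), p.active_sigma))
        occurs = rng_bouts.uniform() < p.active_prob
        runs = rng_bouts.uniform() < p.run_prob
        if occurs:
            bouts.append((t, min(t + length, duration)))
            running.append(runs)
        t += length
        t += float(rng_bouts.lognormal(np.log(p.quiet_mean), p.quiet_sigma))

    state = np.zeros(n)
    run_state = np.zeros(n)
    for (a, b), runs in zip(bouts, running):
        state[int(a * fs): int(b * fs)] = 1.0
        if runs:
            run_state[int(a * fs): int(b * fs)] = 1.0

    # smooth bout envelopes (300 ms shoulders); locomotion bouts are a
    # subset of whisking bouts, so channels correlate without redundancy
    env = gaussian_filter1d(state, sigma=0.3 * fs, mode="nearest")
    env_run = gaussian_filter1d(run_state, sigma=0.3 * fs, mode="nearest")

    rng_amp = substream(seed, "behavior/amplitudes")
    shared = _ou(substream(seed, "behavior/shared"), n, fs, tau=0.5)

    def bout_gain(channel_rng: np.random.Generator) -> np.ndarray:
        """Per-bout amplitude variation, constant within a bout."""
        g = np.ones(n)
        for a, b in bouts:
            g[int(a * fs): int(b * fs)] = channel_rng.lognormal(0.0, 0.3)
        return g

    def mix(own: np.ndarray) -> np.ndarray:
        return p.shared_noise * shared + (1 - p.shared_noise) * own

    # -- locomotion and whisker motion index --------------------------------
    rng_loco = substream(seed, "behavior/loco")
    loco = p.loco_amp * env_run * bout_gain(rng_amp) * (
        1 + 0.3 * mix(_ou(rng_loco, n, fs, tau=0.5)))
    loco += 0.1 * p.loco_amp * np.abs(_ou(rng_loco, n, fs, tau=0.2, sigma=0.2))
    loco = np.clip(loco, 0.0, None)

    rng_wmi = substream(seed, "behavior/wmi")
    wmi = env * bout_gain(rng_amp) * (
        1 + 0.35 * mix(_ou(rng_wmi, n, fs, tau=0.2)))
    wmi += 0.05 * np.abs(_ou(rng_wmi, n, fs, tau=0.1, sigma=0.3))
    wmi = np.clip(wmi, 0.0, None)

    # -- whisker kinematics --------------------------------------------------
    rng_whisk = substream(seed, "behavior/whisker")
    freq = np.full(n, rng_whisk.uniform(*p.whisk_freq))
    for a, b in bouts:
        freq[int(a * fs):] = rng_whisk.uniform(*p.whisk_freq)
    phase = 2 * np.pi * np.cumsum(freq) / fs
    wamp = p.wamp_active * env * (1 + 0.25 * _ou(rng_whisk, n, fs, tau=1.0))
    wamp = np.clip(wamp, 0.0, None)
    wsp = (p.wsp_base + p.wsp_active * env
           + 2.0 * _ou(rng_whisk, n, fs, tau=2.0))
    phi = wsp + wamp * np.sin(phase)

    # -- pupil: slow, lagging follower of arousal ---------------------------
    rng_pupil = substream(seed, "behavior/pupil")
    lag = int(0.5 * fs)
    arousal = np.concatenate([np.zeros(lag), (0.7 * env + 0.3 * env_run)[:n - lag]])
    pupil = gaussian_filter1d(
        1.0 + arousal + 0.4 * _ou(rng_pupil, n, fs, tau=2.0), sigma=1.0 * fs,
        mode="nearest")
    pupil = np.clip(pupil, 0.0, None)

    return BehaviorTraces(
        time=time, state=state, loco=loco, wmi=wmi, phi=phi, wamp=wamp,
        wsp=wsp, pupil=pupil, sampling_rate=fs,
        active_bouts=[(float(a), float(b)) for a, b in bouts],
    )


def whisker_kinematics(
    phi_raw: np.ndarray, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose a raw whisker-angle trace into (phi, WAmp, WSP).

    phi is the 30 Hz 4th-order zero-phase (forward-backward Butterworth)
    low-pass of the raw angle; WSP is a 500 ms Gaussian smoothing of phi
    (sigma = window/6, so +-3 sigma spans the window); WAmp is the magnitude
    of the analytic signal of the setpoint-subtracted angle.
    """
    phi_raw = np.asarray(phi_raw, dtype=float)
    if sampling_rate < 60.0:
        raise ValueError(
            "sampling_rate must be >= 60 Hz for the 30 Hz low-pass filter")
    b, a = butter(4, 30.0, btype="low", fs=sampling_rate)
    phi = filtfilt(b, a, phi_raw)
    wsp = gaussian_filter1d(phi, sigma=(0.5 * sampling_rate) / 6.0,
                            mode="nearest")
    wamp = np.abs(hilbert(phi - wsp))
    return phi, wamp, wsp


def detect_active_periods(
    behavior: BehaviorTraces,
    onset_wmi: float = 0.25,
    onset_loco: float = 0.4,
    offset_wmi: float = 0.2,
    offset_loco: float = 0.1,
    avg_bin: float = 0.1,
    merge_gap: float = 1.0,
    min_duration: float = 1.0,
    padding: float = 0.5,
) -> ActivePeriods:
    """Detect behaviorally active periods from WMI and locomotion.

    Both traces are min-max normalized to [0, 1] over the session, averaged
    in 100 ms bins, and thresholded: a period starts at the first upward
    crossing of either onset threshold and ends when *both* traces fall below
    their offset thresholds (ending on either alone would truncate sustained
    running without whisking).  Periods separated by less than 1 s are
    merged and periods shorter than 1 s discarded.
    """
    if len(behavior.time) == 0:
        raise ValueError("behavior traces are empty")

    def norm(x: np.ndarray) -> np.ndarray:
        lo, hi = float(np.min(x)), float(np.max(x))
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    fs = behavior.sampling_rate
    step = max(int(round(avg_bin * fs)), 1)
    n_bins = len(behavior.time) // step
    if n_bins == 0:
        raise ValueError("behavior shorter than one averaging bin")

    def binavg(x: np.ndarray) -> np.ndarray:
        return norm(x)[: n_bins * step].reshape(n_bins, step).mean(axis=1)

    wmi, loco = binavg(behavior.wmi), binavg(behavior.loco)
    dt = step / fs

    periods: list[tuple[float, float]] = []
    active, onset = False, 0.0
    for i in range(n_bins):
        if not active:
            if wmi[i] >= onset_wmi or loco[i] >= onset_loco:
                active, onset = True, i * dt
        else:
            if wmi[i] < offset_wmi and loco[i] < offset_loco:
                periods.append((onset, i * dt))
                active = False
    if active:
        periods.append((onset, n_bins * dt))

    merged: list[tuple[float, float]] = []
    for a, b in periods:
        if merged and a - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    kept = [(a, b) for a, b in merged if b - a >= min_duration]
    return ActivePeriods(intervals=kept, padding=padding)


def compute_dff(f_raw: np.ndarray, sampling_rate: float,
                smooth: float = 0.1) -> PopulationActivity:
    """Baseline-normalized fluorescence change.

    Per neuron, F0 is the 10th percentile of the raw trace and
    dF/F = (F - F0) / F0, temporally smoothed with a 100 ms square filter.
    """
    f_raw = np.atleast_2d(np.asarray(f_raw, dtype=float))
    f0 = np.percentile(f_raw, 10.0, axis=1, keepdims=True)
    bad = np.flatnonzero(f0.ravel() <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive baseline fluorescence for neuron(s) {bad.tolist()}")
    dff = (f_raw - f0) / f0
    size = max(int(round(smooth * sampling_rate)), 1)
    dff = uniform_filter1d(dff, size=size, axis=1, mode="nearest")
    return PopulationActivity(rates=dff, bin=1.0 / sampling_rate, kind="dff")
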