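"""Event-aligned response analysis: air-puff classification and step cycle.

Responses are quantified in 50 ms bins aligned to stimulus onset, in four
windows: pre-puff baseline A1 = [-400, -200) ms, post-puff A2 = [0, 800) ms,
early R1 = [0, 300) ms and late R2 = [300, 800) ms.  Neurons are classed as
fast/transient (I: A2 > A1 and R1 - R2 > 0.05 Hz), variable-delay
(II: A2 > A1, R1 - R2 <= 0.05 Hz) or unresponsive (III).  Population
reliability across trials is the mean pairwise dot product of population
rate vectors per 100 ms bin, S(t).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .activity import PopulationActivity

__all__ = [
    "PuffAlignedData",
    "ResponseClassification",
    "TrialSimilarity",
    "align_to_events",
    "classify_response",
    "response_variability",
    "trial_similarity",
    "step_cycle_modulation",
]

log = logging.getLogger(__name__)

#: analysis windows in seconds relative to puff onset, as (start, stop)
WINDOWS = {"A1": (-0.4, -0.2), "A2": (0.0, 0.8),
           "R1": (0.0, 0.3), "R2": (0.3, 0.8)}
CHANCE_RATE = 0.05          # Hz, chance-level rate difference for classing


@dataclass
class PuffAlignedData:
    """Trials x neurons x time event rates aligned to stimulus onset."""

    rates: np.ndarray           # (n_trials, n_neurons, n_bins), Hz
    time: np.ndarray            # bin centers, s relative to onset
    bin: float                  # s
    windows: dict = field(default_factory=lambda: dict(WINDOWS))
    puff_duration: float = 0.1

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]

    def window_mask(self, name: str) -> np.ndarray:
        a, b = self.windows[name]
        return (self.time >= a) & (self.time < b)

    def window_rate(self, name: str) -> np.ndarray:
        """Mean rate in a named window, per trial and neuron."""
        return self.rates[:, :, self.window_mask(name)].mean(axis=2)


def align_to_events(
    activity: PopulationActivity,
    event_times: np.ndarray,
    window: tuple[float, float] = (-0.6, 1.0),
    bin: float = 0.05,
) -> PuffAlignedData:
    """Cut event rates into stimulus-aligned trials in 50 ms bins.

    Events whose window would extend past the recording edge are dropped
    (logged).  The native binning is mean-aggregated to the target bin, so
    rates stay in Hz.
    """
    step = int(round(bin / activity.bin))
    if step < 1 or abs(step * activity.bin - bin) > 1e-9:
        raise ValueError("target bin must be a multiple of the activity bin")
    x = activity.rates
    n_coarse = x.shape[1] // step
    xb = x[:, : n_coarse * step].reshape(x.shape[0], n_coarse, step).mean(axis=2)
    n_pre = int(round(-window[0] / bin))
    n_post = int(round(window[1] / bin))
    trials = []
    for t in np.atleast_1d(event_times):
        c = int(np.floor(t / bin + 1e-9))
        if c - n_pre < 0 or c + n_post > n_coarse:
            log.info("dropping event at %.3f s: window outside recording", t)
            continue
        trials.append(xb[:, c - n_pre: c + n_post])
    rates = (np.stack(trials) if trials
             else np.empty((0, x.shape[0], n_pre + n_post)))
    time = (np.arange(-n_pre, n_post) + 0.5) * bin
    return PuffAlignedData(rates=rates, time=time, bin=bin)


@dataclass
class ResponseClassification:
    classes: np.ndarray             # (n_neurons,) in {1, 2, 3}
    mean_latency: np.ndarray        # s, NaN when no events
    sd_latency: np.ndarray
    flagged_silent: np.ndarray      # all-zero neurons, forced class III
    threshold: float = CHANCE_RATE

    def counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.classes == c)) for c in (1, 2, 3)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron": np.arange(len(self.classes)),
            "class": self.classes,
            "mean_latency_ms": self.mean_latency * 1e3,
            "sd_latency_ms": self.sd_latency * 1e3,
        })


def _first_event_latencies(aligned: PuffAlignedData,
                           search: tuple[float, float] = (0.0, 0.8)) -> np.ndarray:
    """(trials, neurons) latency of the first post-onset event, NaN if none."""
    m = (aligned.time >= search[0]) & (aligned.time < search[1])
    t_in = aligned.time[m]
    seg = aligned.rates[:, :, m] > 0
    lat = np.full(seg.shape[:2], np.nan)
    any_ev = seg.any(axis=2)
    first = seg.argmax(axis=2)
    lat[any_ev] = t_in[first[any_ev]]
    return lat


def classify_response(aligned: PuffAlignedData) -> ResponseClassification:
    """Assign each neuron a response class from trial-averaged windows."""
    if aligned.n_trials < 5:
        warnings.warn("fewer than 5 trials: classification may be unstable")
    a1 = aligned.window_rate("A1").mean(axis=0)
    a2 = aligned.window_rate("A2").mean(axis=0)
    r1 = aligned.window_rate("R1").mean(axis=0)
    r2 = aligned.window_rate("R2").mean(axis=0)
    classes = np.full(aligned.n_neurons, 3)
    responsive = a2 > a1
    classes[responsive & (r1 - r2 > CHANCE_RATE)] = 1
    classes[responsive & (r1 - r2 <= CHANCE_RATE)] = 2
    silent = aligned.rates.sum(axis=(0, 2)) == 0
    classes[silent] = 3
    lat = _first_event_latencies(aligned)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean_lat = np.nanmean(lat, axis=0)
        sd_lat = np.nanstd(lat, axis=0)
    return ResponseClassification(classes=classes, mean_latency=mean_lat,
                                  sd_latency=sd_lat, flagged_silent=silent)


def response_variability(aligned: PuffAlignedData) -> dict:
    """Inter-trial vs intra-trial variability of latencies and rates.

    Inter-trial: per-neuron SD across trials (of first-event latency and of
    R1/R2 rates), averaged over neurons.  Intra-trial: per-trial SD across
    neurons, averaged over trials.  Neurons without events are excluded
    from latency statistics but kept in the rate statistics.
    """
    if aligned.n_trials < 2 or aligned.n_neurons < 2:
        raise ValueError("need at least 2 trials and 2 neurons")
    lat = _first_event_latencies(aligned)
    r1 = aligned.window_rate("R1")
    r2 = aligned.window_rate("R2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        inter = {
            "latency": float(np.nanmean(np.nanstd(lat, axis=0))),
            "r1": float(np.mean(np.std(r1, axis=0))),
            "r2": float(np.mean(np.std(r2, axis=0))),
        }
        intra = {
            "latency": float(np.nanmean(np.nanstd(lat, axis=1))),
            "r1": float(np.mean(np.std(r1, axis=1))),
            "r2": float(np.mean(np.std(r2, axis=1))),
        }
    return {"inter_trial": inter, "intra_trial": intra}


@dataclass
class TrialSimilarity:
    time: np.ndarray
    similarity: np.ndarray          # S(t), mean pairwise dot product
    decay_integral: float           # integral of [0,1]-normalized S over [0,0.8] s
    behavior_cv: np.ndarray | None = None


def trial_similarity(
    aligned: PuffAlignedData,
    bin: float = 0.1,
    wmi_aligned: np.ndarray | None = None,
    normalize_vectors: bool = False,
) -> TrialSimilarity:
    """Across-trial reliability of the population response.

    S(t) is the dot product of population rate vectors of two trials,
    averaged over all trial pairs, per 100 ms aligned bin (raw rates by
    default; ``normalize_vectors`` uses unit vectors for cross-session
    comparability).  The decay timescale is the integral over [0, 800] ms
    of the [0, 1]-normalized profile.  If trial-aligned WMI is supplied its
    across-trial coefficient of variation per bin is returned alongside.
    """
    if aligned.n_trials < 2:
        raise ValueError("trial similarity needs at least 2 trials")
    step = int(round(bin / aligned.bin))
    nb = aligned.rates.shape[2] // step
    r = aligned.rates[:, :, : nb * step]
    r = r.reshape(aligned.n_trials, aligned.n_neurons, nb, step).mean(axis=3)
    time = aligned.time[: nb * step].reshape(nb, step).mean(axis=1)
    if normalize_vectors:
        nrm = np.linalg.norm(r, axis=1, keepdims=True)
        r = np.divide(r, nrm, out=np.zeros_like(r), where=nrm > 0)
    dots = np.einsum("int,jnt->ijt", r, r)
    iu = np.triu_indices(aligned.n_trials, k=1)
    s = dots[iu].mean(axis=0)
    post = (time >= 0) & (time < 0.8)
    span = s[post].max() - s[post].min()
    norm_profile = (s[post] - s[post].min()) / span if span > 0 else np.zeros(post.sum())
    decay = float(np.sum(norm_profile) * bin)
    cv = None
    if wmi_aligned is not None:
        w = np.asarray(wmi_aligned, float)
        nbw = w.shape[1] // step
        wb = w[:, : nbw * step].reshape(w.shape[0], nbw, step).mean(axis=2)
        mu = wb.mean(axis=0)
        cv = np.divide(wb.std(axis=0), mu, out=np.zeros_like(mu), where=mu > 0)
    return TrialSimilarity(time=time, similarity=s, decay_integral=decay,
                           behavior_cv=cv)


def step_cycle_modulation(
    events: list[np.ndarray],
    lift_times: np.ndarray,
    paw_time: np.ndarray,
    paw_height: np.ndarray,
    window: float = 1.0,
    bin: float = 0.05,
    r_threshold: float = 0.5,
    seed: int = 0,
    min_instances: int = 10,
) -> pd.DataFrame:
    """Flag neurons modulated within the step cycle.

    For each paw-lift instance, events in a +-1 s window are binned; the
    across-instance average is the lift-aligned event probability.  The
    shuffle control redistributes each instance's events uniformly within
    its window before averaging.  A neuron is modulated iff its event
    probability correlates with the mean paw trajectory (|r| > 0.5,
    p < 0.01, two-sided t approximation on n = number of bins) while the
    shuffle control does not (p > 0.1).
    """
    lift_times = np.asarray(lift_times, float)
    if len(lift_times) < min_instances:
        warnings.warn("too few lift instances: step-cycle analysis skipped")
        return pd.DataFrame()
    edges = np.arange(-window, window + bin / 2, bin)
    centers = 0.5 * (edges[:-1] + edges[1:])
    traj = np.mean([np.interp(centers + t, paw_time, paw_height)
                    for t in lift_times], axis=0)
    rng = substream(seed, "step-shuffle")

    rows = []
    for ni, ev in enumerate(events):
        ev = np.asarray(ev, float)
        prob = np.zeros(len(centers))
        prob_sh = np.zeros(len(centers))
        for t in lift_times:
            rel = ev[(ev >= t - window) & (ev < t + window)] - t
            prob += np.histogram(rel, bins=edges)[0]
            sh = rng.uniform(-window, window, size=len(rel))
            prob_sh += np.histogram(sh, bins=edges)[0]
        prob /= len(lift_times)
        prob_sh /= len(lift_times)

        def corr(p):
            if p.std() == 0 or traj.std() == 0:
                return 0.0, 1.0
            r, pv = stats.pearsonr(p, traj)
            return float(r), float(pv)

        r_ev, p_ev = corr(prob)
        r_sh, p_sh = corr(prob_sh)
        rows.append({
            "neuron": ni, "r_event": r_ev, "p_event": p_ev,
            "r_shuffle": r_sh, "p_shuffle": p_sh,
            "modulated": (abs(r_ev) > r_threshold and p_ev < 0.01
                          and p_sh > 0.1),
        })
    return pd.DataFrame(rows)
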