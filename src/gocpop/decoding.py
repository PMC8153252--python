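"""Ridge regression between population modes and behavior.

Two directions are supported: explaining the common mode (PM1) from
behavioral variables (single variables or their linear combination), and
decoding a behavioral variable from rank-K reconstructions of population
activity.  All regressions are restricted to behaviorally active periods
(± 500 ms padding), resampled to 20 Hz, partitioned in 500 ms blocks to
respect autocorrelation, and L2-regularized with the penalty chosen by
blocked inner cross-validation.  Performance is cross-validated explained
variance (CVEV) on held-out blocks, averaged over 100 random partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .activity import PopulationActivity
from .behavior import BEHAVIOR_CHANNELS, ActivePeriods, BehaviorTraces
from .modes import decompose

__all__ = [
    "RegressionData",
    "DecodingResult",
    "prepare_regression_data",
    "ridge_cv",
    "decode_rank_k",
    "shuffle_controls",
    "regress_pm1_on_behavior",
]

ALPHA_GRID = np.logspace(-4, 4, 9)


def _resample_overlap(x: np.ndarray, src_bin: float, dst_bin: float,
                      n_out: int) -> np.ndarray:
    """Area-weighted resampling of piecewise-constant rows (conserves means).

    Each output sample is the average of the signal over its window, with
    source bins weighted by their fractional overlap — e.g. a 50 ms sample
    over 40 ms bins averages exactly two bins with weights 0.8/0.2.
    """
    x = np.atleast_2d(x)
    t = x.shape[1]
    cum = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1)
    grid = np.arange(t + 1) * src_bin
    edges = np.arange(n_out + 1) * dst_bin
    out = np.empty((x.shape[0], n_out))
    for i in range(x.shape[0]):
        c = np.interp(edges, grid, cum[i] * src_bin)
        out[i] = np.diff(c) / dst_bin
    return out


@dataclass
class RegressionData:
    """Aligned predictors and behavioral targets on a common 20 Hz grid."""

    modes: np.ndarray          # (samples, n_modes)
    behavior: np.ndarray       # (samples, 6) in BEHAVIOR_CHANNELS order
    block_id: np.ndarray       # (samples,) global 500 ms block index
    period_id: np.ndarray      # (samples,) active-period index
    rate: float                # Hz

    @property
    def n_blocks(self) -> int:
        return len(np.unique(self.block_id))

    def channel(self, name: str) -> np.ndarray:
        return self.behavior[:, BEHAVIOR_CHANNELS.index(name)]


def prepare_regression_data(
    mode_dynamics: np.ndarray,
    activity_bin: float,
    behavior: BehaviorTraces,
    periods: ActivePeriods,
    rate: float = 20.0,
    block: float = 0.5,
) -> RegressionData:
    """Restrict mode dynamics and behavior to padded active periods at 20 Hz.

    Both sides are area-weighted-resampled to the common rate (the slowest
    acquisition rate), then cut to active periods ± padding; each retained
    sample carries its period index and a 500 ms block index used for all
    train/test partitioning.
    """
    if not periods.intervals:
        raise ValueError("no active periods: empty regression design")
    dyn = np.atleast_2d(np.asarray(mode_dynamics, float))
    if dyn.shape[0] > dyn.shape[1]:
        dyn = dyn.T                       # accept (T, M) or (M, T)
    t_total = min(dyn.shape[1] * activity_bin, behavior.duration)
    n_out = int(t_total * rate)
    modes_rs = _resample_overlap(dyn, activity_bin, 1.0 / rate, n_out)
    beh_rs = _resample_overlap(behavior.matrix(normalize=True),
                               1.0 / behavior.sampling_rate, 1.0 / rate, n_out)
    t_samp = (np.arange(n_out) + 0.5) / rate

    pad = periods.padding
    keep = np.zeros(n_out, dtype=bool)
    period_id = np.full(n_out, -1)
    block_id = np.full(n_out, -1)
    samples_per_block = max(int(round(block * rate)), 1)
    next_block = 0
    for pi, (a, b) in enumerate(periods.intervals):
        m = (t_samp >= a - pad) & (t_samp < b + pad)
        idx = np.flatnonzero(m)
        keep[idx] = True
        period_id[idx] = pi
        nb = int(np.ceil(len(idx) / samples_per_block))
        block_id[idx] = next_block + np.arange(len(idx)) // samples_per_block
        next_block += nb
    if not keep.any():
        raise ValueError("no samples inside active periods: empty design")
    return RegressionData(modes=modes_rs[:, keep].T, behavior=beh_rs[:, keep].T,
                          block_id=block_id[keep], period_id=period_id[keep],
                          rate=rate)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0)
    return (a - a.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


def _ridge_solve(xtr, ytr, xte, alphas):
    """Ridge predictions on xte for every alpha (variables pre-centered)."""
    g = xtr.T @ xtr
    c = xtr.T @ ytr
    preds = []
    eye = np.eye(g.shape[0])
    for a in alphas:
        beta = np.linalg.solve(g + a * eye, c)
        preds.append(xte @ beta)
    return preds


@dataclass
class RidgeCvResult:
    cvev: float
    per_partition: np.ndarray = field(repr=False)
    alphas: np.ndarray = field(repr=False)


def ridge_cv(
    design: np.ndarray,
    target: np.ndarray,
    block_id: np.ndarray,
    n_partitions: int = 100,
    train_frac: float = 0.8,
    alphas: np.ndarray = ALPHA_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> RidgeCvResult:
    """Blocked, L2-regularized regression with cross-validated EV.

    Blocks (500 ms) are randomly assigned to train/test per partition; the
    penalty is chosen per partition by `inner_folds`-fold blocked CV on the
    training side; CVEV = 1 - MSE/var on the held-out blocks, averaged over
    partitions.  Predictors and target are z-scored over the included
    samples so a single penalty grid applies to all designs.
    """
    x = _zscore(np.atleast_2d(np.asarray(design, float).T).T)
    y = np.asarray(target, float)
    if y.std() == 0:
        raise ValueError("zero-variance regression target")
    y = (y - y.mean()) / y.std()
    blocks = np.unique(block_id)
    if len(blocks) < inner_folds + 1:
        raise ValueError("too few blocks for blocked cross-validation")
    rng = substream(seed, "ridge-cv")
    n_train = int(round(train_frac * len(blocks)))
    out = np.empty(n_partitions)
    for p in range(n_partitions):
        order = rng.permutation(blocks)
        tr_blocks, te_blocks = order[:n_train], order[n_train:]
        tr = np.isin(block_id, tr_blocks)
        te = np.isin(block_id, te_blocks)
        xtr, ytr = x[tr], y[tr]
        # inner blocked CV over the penalty grid
        folds = np.array_split(rng.permutation(tr_blocks), inner_folds)
        inner_err = np.zeros(len(alphas))
        for fold in folds:
            v = np.isin(block_id, fold) & tr
            f = tr & ~v
            mx, my = x[f].mean(axis=0), y[f].mean()
            preds = _ridge_solve(x[f] - mx, y[f] - my, x[v] - mx, alphas)
            for i, pr in enumerate(preds):
                inner_err[i] += np.sum((y[v] - my - pr) ** 2)
        a_best = alphas[int(np.argmin(inner_err))]
        mx, my = xtr.mean(axis=0), ytr.mean()
        pred = _ridge_solve(xtr - mx, ytr - my, x[te] - mx, [a_best])[0]
        resid = y[te] - my - pred
        var = np.sum((y[te] - y[te].mean()) ** 2)
        out[p] = 1.0 - np.sum(resid**2) / var if var > 0 else 0.0
    return RidgeCvResult(cvev=float(out.mean()), per_partition=out,
                         alphas=alphas)


@dataclass
class DecodingResult:
    """Rank-K decoding of one behavioral variable."""

    target: str
    K: np.ndarray
    cvev_by_K: np.ndarray
    cvev_pm1: float
    optimal_K: int
    cvev_optimal: float
    shuffle_cvev: dict = field(default_factory=dict)


def _optimal_k(cvev: np.ndarray) -> int:
    """Smallest K capturing >= 90% of the maximal improvement over PM1."""
    imp = cvev - cvev[0]
    if imp.max() <= 0:
        return 1
    return int(np.flatnonzero(imp >= 0.9 * imp.max())[0]) + 1


def decode_rank_k(
    activity: PopulationActivity,
    behavior: BehaviorTraces,
    target: str,
    periods: ActivePeriods,
    k_range=None,
    n_partitions: int = 100,
    seed: int = 0,
    shuffles: bool = False,
) -> DecodingResult:
    """Decode a behavioral variable from rank-K mode reconstructions.

    The SVD is computed once on all time points; the rank-K predictor set is
    the first K mode dynamics.  The same block partitions (same seed) are
    used for every K so the CVEV-vs-K curves are directly comparable; the
    optimal K is the smallest reaching 90% of the maximal improvement over
    the PM1-only regression.  With ``shuffles`` the within-period and
    across-period block-shuffle controls are decoded with the same pipeline
    and their maximal CVEV recorded.
    """
    dec = decompose(activity)
    data = prepare_regression_data(dec.dynamics, activity.bin, behavior, periods)
    k_max = dec.n_modes if k_range is None else int(max(k_range))
    if k_max > dec.n_modes:
        import warnings
        warnings.warn(f"K range truncated to {dec.n_modes} available modes")
        k_max = dec.n_modes
    ks = np.arange(1, k_max + 1)
    y = data.channel(target)

    def curve(yv: np.ndarray) -> np.ndarray:
        return np.array([
            ridge_cv(data.modes[:, :k], yv, data.block_id,
                     n_partitions=n_partitions, seed=seed).cvev
            for k in ks
        ])

    cvev = curve(y)
    opt = _optimal_k(cvev)
    shuffle_cvev = {}
    if shuffles:
        for mode in ("within", "across"):
            ys = shuffle_controls(y, data.block_id, data.period_id, mode,
                                  seed=seed)
            shuffle_cvev[mode] = float(curve(ys).max())
    return DecodingResult(target=target, K=ks, cvev_by_K=cvev,
                          cvev_pm1=float(cvev[0]), optimal_K=opt,
                          cvev_optimal=float(cvev[opt - 1]),
                          shuffle_cvev=shuffle_cvev)


def shuffle_controls(
    target: np.ndarray,
    block_id: np.ndarray,
    period_id: np.ndarray,
    mode: str,
    seed: int = 0,
) -> np.ndarray:
    """Block-shuffled surrogate of a behavioral target.

    "within" permutes the 500 ms blocks inside each active period
    (preserving the period's mean context); "across" permutes blocks over
    all periods (preserving only local dynamics).  The marginal distribution
    of the target is preserved exactly; a single-block period is left
    unchanged by the within shuffle.
    """
    if mode not in ("within", "across"):
        raise ValueError("mode must be 'within' or 'across'")
    y = np.asarray(target, float).copy()
    rng = substream(seed, f"shuffle-{mode}")
    out = np.empty_like(y)

    def blocks_in(idx: np.ndarray) -> list[np.ndarray]:
        ids = block_id[idx]
        return [idx[ids == b] for b in pd_unique(ids)]

    def pd_unique(a):
        # order-preserving unique
        _, first = np.unique(a, return_index=True)
        return a[np.sort(first)]

    if mode == "within":
        for p in np.unique(period_id):
            idx = np.flatnonzero(period_id == p)
            bl = blocks_in(idx)
            order = rng.permutation(len(bl))
            vals = np.concatenate([y[bl[i]] for i in order])
            out[idx] = vals[: len(idx)]
    else:
        idx = np.arange(len(y))
        bl = blocks_in(idx)
        order = rng.permutation(len(bl))
        vals = np.concatenate([y[bl[i]] for i in order])
        out = vals[: len(y)]
    return out


def regress_pm1_on_behavior(
    activity: PopulationActivity,
    behavior: BehaviorTraces,
    periods: ActivePeriods,
    n_partitions: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Explain PM1 dynamics from single behaviors and their combination.

    Returns CVEV per behavioral channel plus "linear_comb" for the
    multilinear regression on all six channels simultaneously; regularized
    cross-validation makes the comparison fair despite the different
    numbers of parameters.
    """
    dec = decompose(activity)
    data = prepare_regression_data(dec.dynamics[:, :1], activity.bin,
                                   behavior, periods)
    pm1 = data.modes[:, 0]
    out = {}
    for name in BEHAVIOR_CHANNELS:
        x = data.channel(name)[:, None]
        if x.std() == 0:
            continue
        out[name] = ridge_cv(x, pm1, data.block_id,
                             n_partitions=n_partitions, seed=seed).cvev
    out["linear_comb"] = ridge_cv(data.behavior, pm1, data.block_id,
                                  n_partitions=n_partitions, seed=seed).cvev
    return out
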