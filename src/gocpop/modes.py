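"""Population-mode decomposition and dimensionality estimation.

Activity is decomposed with SVD into orthogonal population modes
(X = U S V^T on the per-neuron centered matrix).  Reliability of modes is
assessed with bi-cross-validation: loadings are learned on a training time
split, and on held-out times the latent dynamics are estimated from 80% of
the neurons and evaluated on the remaining 20%, giving a cross-validated
explained variance (CVEV) as a function of the number of modes K.  The peak
of that curve is the *shared dimensionality* — a lower bound on the number
of modes shared across neurons.  The *effective dimensionality* is the
participation ratio of the covariance eigenspectrum,
D_eff = (sum λ_i)^2 / sum λ_i^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import subspace_angles
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from ._rng import substream
from .activity import PopulationActivity

__all__ = [
    "ModeDecomposition",
    "CvevCurve",
    "IcaStabilityResult",
    "decompose",
    "project_out_pm1",
    "cross_validated_evar",
    "effective_dimensionality",
    "loading_overlap",
    "ica_stability_dimensionality",
]


def _as_matrix(x) -> tuple[np.ndarray, float]:
    if isinstance(x, PopulationActivity):
        return np.asarray(x.rates, float), x.bin
    return np.asarray(x, dtype=float), np.nan


@dataclass
class ModeDecomposition:
    """SVD of centered population activity: X - mean = U S V^T."""

    loadings: np.ndarray        # (n_neurons, n_modes), orthonormal columns
    singular_values: np.ndarray
    dynamics: np.ndarray        # (n_bins, n_modes)
    eigenvalues: np.ndarray     # covariance eigenvalues, non-increasing
    mean: np.ndarray            # per-neuron centering vector

    @property
    def n_modes(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """Rank-k reconstruction (centered; add `mean` for raw scale)."""
        k = self.n_modes if k is None else k
        u, s, v = self.loadings[:, :k], self.singular_values[:k], self.dynamics[:, :k]
        return (u * s) @ v.T


def decompose(x) -> ModeDecomposition:
    """SVD mode decomposition of zero-centered population activity.

    Each loading column is sign-flipped so that its entry-sum is
    non-negative, making the dominant common mode (PM1) carry positive
    loadings for population-wide co-activation.  Zero-variance neurons are
    retained with a warning.
    """
    x, _ = _as_matrix(x)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 neurons and 2 time points")
    if np.any(x.std(axis=1) == 0):
        warnings.warn("zero-variance neuron(s) retained in decomposition")
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    flip = np.where(u.sum(axis=0) < 0, -1.0, 1.0)
    u *= flip
    v = vt.T * flip
    lam = s**2 / max(x.shape[1] - 1, 1)
    return ModeDecomposition(loadings=u, singular_values=s, dynamics=v,
                             eigenvalues=lam, mean=mean)


def project_out_pm1(x) -> np.ndarray:
    """Residual activity after removing the first population mode.

    Reconstructs the centered matrix from modes 2..N; the result has zero
    projection onto the PM1 loading vector.
    """
    xm, _ = _as_matrix(x)
    if xm.shape[0] < 2:
        raise ValueError("residual activity requires at least 2 neurons")
    dec = decompose(xm)
    u1 = dec.loadings[:, :1]
    xc = xm - dec.mean[:, None]
    return xc - u1 @ (u1.T @ xc)


@dataclass
class CvevCurve:
    """Bi-cross-validated explained variance as a function of mode count."""

    K: np.ndarray
    cvev: np.ndarray                  # mean over repeats
    n_repeats: int
    shared_dimensionality: int
    max_cvev: float
    per_repeat: np.ndarray = field(repr=False, default=None)  # (repeats, K)


def _time_blocks(n_bins: int, bin: float, block: float) -> list[np.ndarray]:
    size = max(int(round(block / bin)), 1) if np.isfinite(bin) else max(n_bins // 40, 1)
    edges = np.arange(0, n_bins, size)
    return [np.arange(a, min(a + size, n_bins)) for a in edges]


def cross_validated_evar(
    x,
    k_max: int = 15,
    n_repeats: int = 30,
    train_frac_time: float = 0.7,
    train_frac_neurons: float = 0.8,
    block: float = 0.5,
    seed: int = 0,
) -> CvevCurve:
    """Bi-cross-validation of the mode decomposition.

    Per repeat the time axis is split 70/30 in 500 ms blocks; loadings come
    from the training times.  On the test times, 80% of neurons (X1)
    estimate the K latent dynamics by least squares through the
    pseudoinverse of their loadings, and the remaining 20% (X2) are
    predicted: X2_hat = U2K pinv(U1K) X1.  CVEV = 1 - |X2-X2_hat|^2/|X2|^2,
    averaged over repeats; the curve's peak K is the shared dimensionality
    (ties resolved to the smallest K within 1e-6).
    """
    xm, bin_s = _as_matrix(x)
    n, t = xm.shape
    n_test_neurons = int(round((1 - train_frac_neurons) * n))
    if n_test_neurons < 2:
        raise ValueError(
            "population too small: the held-out neuron split must be >= 2")
    k_cap = min(k_max, n - n_test_neurons, t)
    if k_cap < k_max:
        warnings.warn(f"k_max truncated to {k_cap}")
    rng = substream(seed, "bicv")
    blocks = _time_blocks(t, bin_s, block)
    n_train_blocks = int(round(train_frac_time * len(blocks)))
    per_repeat = np.empty((n_repeats, k_cap))

    for r in range(n_repeats):
        order = rng.permutation(len(blocks))
        tr = np.concatenate([blocks[i] for i in order[:n_train_blocks]])
        te = np.concatenate([blocks[i] for i in order[n_train_blocks:]])
        mu = xm[:, tr].mean(axis=1, keepdims=True)
        xtr, xte = xm[:, tr] - mu, xm[:, te] - mu
        u, _, _ = np.linalg.svd(xtr, full_matrices=False)
        perm = rng.permutation(n)
        test_n, train_n = perm[:n_test_neurons], perm[n_test_neurons:]
        x1, x2 = xte[train_n], xte[test_n]
        denom = float(np.sum(x2**2))
        for k in range(1, k_cap + 1):
            u1, u2 = u[train_n, :k], u[test_n, :k]
            latent, *_ = np.linalg.lstsq(u1, x1, rcond=None)
            x2_hat = u2 @ latent
            per_repeat[r, k - 1] = 1.0 - np.sum((x2 - x2_hat) ** 2) / denom

    cvev = per_repeat.mean(axis=0)
    peak = float(cvev.max())
    shared = int(np.flatnonzero(cvev >= peak - 1e-6)[0]) + 1
    return CvevCurve(K=np.arange(1, k_cap + 1), cvev=cvev, n_repeats=n_repeats,
                     shared_dimensionality=shared, max_cvev=peak,
                     per_repeat=per_repeat)


def effective_dimensionality(eigenvalues) -> float:
    """Participation ratio D_eff = (sum λ)^2 / sum λ^2 of an eigenspectrum."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative and non-empty")
    total = lam.sum()
    if total == 0:
        raise ValueError("all-zero eigenvalue spectrum")
    return float(total**2 / np.sum(lam**2))


def loading_overlap(loadings: np.ndarray, signal_k: int,
                    exclude_pm1: bool = True) -> np.ndarray:
    """Pairwise similarity of neurons within the signal subspace.

    overlap(m, n) is the dot product of the neurons' loading rows over modes
    2..K (PM1 excluded by default, since its near-uniform positive weights
    would dominate the similarity of every pair).
    """
    u = np.asarray(loadings, dtype=float)
    if signal_k < 2:
        raise ValueError("signal_k must be >= 2")
    if signal_k > u.shape[1]:
        raise ValueError("signal_k exceeds the number of available modes")
    cols = u[:, 1:signal_k] if exclude_pm1 else u[:, :signal_k]
    return cols @ cols.T


@dataclass
class IcaStabilityResult:
    dimensionality: int
    stability: dict                 # K -> mean aligned |corr|
    loadings: np.ndarray            # ICA loadings at the chosen K (n, K)
    pm1_principal_angle_deg: float


def _ica_loadings(xc: np.ndarray, k: int, seed: int) -> np.ndarray:
    """FastICA mode loadings (neurons x k) on centered activity.

    Non-convergence (typical on near-Gaussian data) is retried with fresh
    seeds and, failing that, the non-converged estimate is used — the
    stability criterion downstream will score such loadings as unstable.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        for attempt in range(3):
            try:
                ica = FastICA(n_components=k, fun="logcosh",
                              whiten="unit-variance", max_iter=500,
                              random_state=seed + attempt)
                ica.fit(xc.T)
                m = ica.mixing_
                return m / np.linalg.norm(m, axis=0, keepdims=True)
            except ConvergenceWarning:          # retry with a new seed
                continue
    logging.getLogger(__name__).info(
        "FastICA did not converge at k=%d; using last iterate", k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ica = FastICA(n_components=k, fun="logcosh", whiten="unit-variance",
                      max_iter=500, random_state=seed)
        ica.fit(xc.T)
        m = ica.mixing_
    return m / np.linalg.norm(m, axis=0, keepdims=True)


def _align_stability(a: np.ndarray, b: np.ndarray) -> float:
    """Greedy alignment of two loading sets by maximal |dot product|."""
    c = np.abs(a.T @ b)
    total, k = 0.0, c.shape[0]
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(c), c.shape)
        total += c[i, j]
        c[i, :], c[:, j] = -1.0, -1.0
    return total / k


def ica_stability_dimensionality(
    x,
    k_candidates=range(2, 9),
    n_partitions: int = 10,
    block: float = 0.5,
    stability_threshold: float = 0.9,
    seed: int = 0,
) -> IcaStabilityResult:
    """Minimal population dimensionality from split-half ICA stability.

    For each candidate K the time axis is split into random halves (500 ms
    blocks), ICA is run on both, and the loadings greedily aligned by
    maximal |dot product|; the mean aligned correlation, averaged over 10
    partitions, is the stability of K.  The chosen dimensionality is the
    largest K whose stability reaches the threshold — every larger K is
    below it.  Also reports the first principal angle between the PM1
    loading and the span of the remaining signal modes.
    """
    xm, bin_s = _as_matrix(x)
    blocks = _time_blocks(xm.shape[1], bin_s, block)
    if len(blocks) < 20:
        raise ValueError("need at least 20 time blocks for split-half ICA")
    rng = substream(seed, "ica")
    xc = xm - xm.mean(axis=1, keepdims=True)

    stability: dict[int, float] = {}
    for k in k_candidates:
        vals = []
        for p in range(n_partitions):
            order = rng.permutation(len(blocks))
            half = len(blocks) // 2
            ia = np.concatenate([blocks[i] for i in order[:half]])
            ib = np.concatenate([blocks[i] for i in order[half:]])
            la = _ica_loadings(xc[:, ia], k, seed=1000 * k + p)
            lb = _ica_loadings(xc[:, ib], k, seed=2000 * k + p)
            vals.append(_align_stability(la, lb))
        stability[k] = float(np.mean(vals))

    stable = [k for k, s in stability.items() if s >= stability_threshold]
    dim = max(stable) if stable else 1

    k_fit = max(dim, 2)
    loadings = _ica_loadings(xc, k_fit, seed=seed)
    pm1 = decompose(xm).loadings[:, :1]
    corr_with_pm1 = np.abs(pm1.T @ loadings).ravel()
    rest = loadings[:, np.argsort(corr_with_pm1)[:-1]] if k_fit > 1 else loadings
    angle = float(np.degrees(subspace_angles(pm1, rest)[-1]))
    return IcaStabilityResult(dimensionality=dim, stability=stability,
                              loadings=loadings, pm1_principal_angle_deg=angle)
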