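"""End-to-end circuit-model experiments and their population statistics.

One "experiment" is: generate synthetic behavior, build a network
realization, drive it with behavior-modulated Poisson inputs for 20 s,
bin spikes at 40 ms, and measure population statistics (mean pairwise
correlation, effective dimensionality, bi-cross-validated PM1 variance)
averaged over 10 sub-populations subsampled from imaging-volume-sized
boxes — with and without gap junctions, and for the input trains
themselves.
"""

from __future__ import annotations

import numpy as np

from .activity import PopulationActivity
from .behavior import generate_behavior
from .inputs import InputEnsemble, make_input_rates
from .modes import cross_validated_evar, decompose, effective_dimensionality
from .network import build_network
from .neuron import NeuronParams, calibrate_population
from .simulate import bin_rates, simulate, subsample_populations

__all__ = ["simulate_condition", "population_statistics", "input_statistics",
           "model_experiment"]

VOLUME = (500.0, 500.0, 100.0)


def simulate_condition(
    seed: int,
    k: float = 1.0,
    duration: float = 20.0,
    dt: float = 0.1,
    base: NeuronParams | None = None,
    params=None,
    behavior=None,
    scheme: str = "Input-Beh",
) -> tuple[PopulationActivity, InputEnsemble]:
    """Simulate one network realization at coupling scale `k`.

    Returns the 40 ms-binned activity (with positions) and the input
    ensemble (with its sampled spike trains).
    """
    if behavior is None:
        behavior = generate_behavior(duration + 5.0, seed=seed)
    net = build_network(seed=seed, k=k)
    if params is None:
        params = calibrate_population(net.n_cells, seed=seed, dt=dt, base=base)
    ens = make_input_rates(behavior, scheme=scheme, seed=seed)
    raster = simulate(net, ens, duration=duration, dt=dt, params=params,
                      seed=seed)
    return bin_rates(raster, positions=net.positions), ens


def population_statistics(
    activity: PopulationActivity,
    seed: int = 0,
    n_boxes: int = 10,
    n_repeats: int = 30,
    min_cells: int = 10,
) -> dict:
    """Subsampled-population statistics of one simulated network.

    Box-level values are averaged over the subsampled volumes; global
    values are computed on the full population.
    """
    corr = np.corrcoef(activity.rates)
    iu = np.triu_indices(activity.n_neurons, k=1)
    out = {
        "corr_global": float(np.nanmean(corr[iu])),
        "deff_global": effective_dimensionality(
            decompose(activity).eigenvalues),
    }
    box_corr, box_deff, box_cvev = [], [], []
    boxes = subsample_populations(activity, volume=VOLUME, n=n_boxes,
                                  seed=seed)
    for b in boxes:
        if b.n_neurons < min_cells:
            continue
        c = np.corrcoef(b.rates)
        iub = np.triu_indices(b.n_neurons, k=1)
        box_corr.append(np.nanmean(c[iub]))
        box_deff.append(effective_dimensionality(decompose(b).eigenvalues))
        box_cvev.append(cross_validated_evar(
            b, k_max=1, n_repeats=n_repeats, seed=seed).cvev[0])
    out.update({
        "corr_box": float(np.mean(box_corr)),
        "deff_box": float(np.mean(box_deff)),
        "pm1_cvev_box": float(np.mean(box_cvev)),
        "box_sizes": [b.n_neurons for b in boxes],
    })
    return out


def input_statistics(ens: InputEnsemble, seed: int = 0,
                     n_repeats: int = 30) -> dict:
    """PM1 CVEV and mean pairwise correlation of the binned input trains
    (behavior-driven inputs only, background excluded)."""
    x = ens.binned_rates(bin=0.04, include_background=False)
    act = PopulationActivity(rates=x, bin=0.04)
    cvev = cross_validated_evar(act, k_max=1, n_repeats=n_repeats,
                                seed=seed).cvev[0]
    c = np.corrcoef(x)
    iu = np.triu_indices(x.shape[0], k=1)
    return {"pm1_cvev": float(cvev), "corr": float(np.nanmean(c[iu]))}


def model_experiment(seed: int, ks=(0.0, 1.0), dt: float = 0.1,
                     base: NeuronParams | None = None) -> dict:
    """Run the coupled/uncoupled experiment for one seed.

    Neuron calibration and behavior are shared across coupling scales so
    that k is the only difference between conditions.
    """
    behavior = generate_behavior(25.0, seed=seed)
    params = calibrate_population(115, seed=seed, dt=dt, base=base)
    out: dict = {"seed": seed, "k": {}}
    for k in ks:
        activity, ens = simulate_condition(
            seed, k=k, dt=dt, params=params, behavior=behavior)
        stats = population_statistics(activity, seed=seed)
        if k == max(ks):
            stats["inputs"] = input_statistics(ens, seed=seed)
        out["k"][k] = stats
    return out
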