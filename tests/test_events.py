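"""Air-puff-aligned responses, classification, similarity, step cycle."""

import numpy as np
import pytest

from gocpop.activity import PopulationActivity
from gocpop.events import (PuffAlignedData, align_to_events, classify_response,
                           response_variability, step_cycle_modulation,
                           trial_similarity)
from gocpop.synthetic import generate_puff_trials, generate_step_session


def aligned_from(rates_by_window, n_trials=6, bin=0.05):
    """Build a PuffAlignedData tensor with prescribed window rates."""
    time = (np.arange(-12, 20) + 0.5) * bin        # [-0.6, 1.0) s
    n_neurons = len(rates_by_window)
    rates = np.zeros((n_trials, n_neurons, len(time)))
    for ni, spec in enumerate(rates_by_window):
        for (a, b), value in spec.items():
            m = (time >= a) & (time < b)
            rates[:, ni, m] = value
    return PuffAlignedData(rates=rates, time=time, bin=bin)


@pytest.fixture(scope="module")
def puff_session():
    rates, events, puffs, truth = generate_puff_trials(
        n_trials=20, n_neurons=30, seed=5)
    act = PopulationActivity(rates=rates * 1000.0, bin=0.001)  # counts -> Hz
    aligned = align_to_events(act, puffs, window=(-0.6, 1.0), bin=0.05)
    return aligned, truth


class TestAlign:
    def test_flat_rate_fills_all_bins(self):
        act = PopulationActivity(np.full((2, 1000), 4.0), bin=0.01)
        out = align_to_events(act, [5.0], window=(-0.5, 0.5), bin=0.05)
        assert out.rates.shape == (1, 2, 20)
        np.testing.assert_allclose(out.rates, 4.0)

    def test_impulse_lands_in_expected_bin(self):
        """An impulse 120 ms after the event falls in post-onset bin 2."""
        x = np.zeros((1, 1000))
        x[0, 612] = 100.0          # event at 5.0 s, impulse at 6.12... no: 0.612 s
        act = PopulationActivity(x, bin=0.001)
        out = align_to_events(act, [0.5], window=(-0.2, 0.4), bin=0.05)
        post = out.time >= 0
        bins = out.rates[0, 0, post]
        assert np.argmax(bins) == 2

    def test_edge_events_dropped(self):
        act = PopulationActivity(np.zeros((1, 100)), bin=0.01)
        out = align_to_events(act, [0.1, 0.5, 0.95], window=(-0.2, 0.2))
        assert out.n_trials == 1

    def test_empty_event_list(self):
        act = PopulationActivity(np.zeros((3, 100)), bin=0.01)
        out = align_to_events(act, [], window=(-0.2, 0.2))
        assert out.rates.shape[0] == 0


class TestClassify:
    def test_rule_application(self):
        aligned = aligned_from([
            {(0.0, 0.3): 2.0, (0.3, 0.8): 0.5},   # fast transient -> I
            {(0.0, 0.8): 1.5},                    # sustained -> II
            {(-0.4, -0.2): 2.0},                  # pre only -> III
        ])
        cls = classify_response(aligned)
        np.testing.assert_array_equal(cls.classes, [1, 2, 3])
        assert sum(cls.counts().values()) == 3

    def test_silent_neuron_flagged_class_three(self):
        aligned = aligned_from([{}, {(0.0, 0.3): 1.0}])
        cls = classify_response(aligned)
        assert cls.classes[0] == 3
        assert cls.flagged_silent[0] and not cls.flagged_silent[1]

    def test_rate_rescaling_can_flip_class(self):
        """The 0.05 Hz chance threshold is absolute: doubling rates flips a
        borderline sustained cell to transient."""
        spec = [{(0.0, 0.3): 1.0, (0.3, 0.8): 0.96}]
        a = classify_response(aligned_from(spec))
        doubled = aligned_from(spec)
        doubled.rates = doubled.rates * 2.0
        b = classify_response(doubled)
        assert a.classes[0] == 2 and b.classes[0] == 1

    def test_few_trials_warns(self):
        aligned = aligned_from([{(0.0, 0.3): 1.0}], n_trials=3)
        with pytest.warns(UserWarning, match="trials"):
            classify_response(aligned)

    def test_generator_classes_recovered(self, puff_session):
        """Transient responders are recovered reliably; the II/III boundary
        (A2 vs A1 on a 1 Hz baseline) is noisier by construction."""
        aligned, truth = puff_session
        cls = classify_response(aligned)
        is_one = truth["classes"] == 1
        assert (cls.classes[is_one] == 1).mean() >= 0.8
        assert (cls.classes == truth["classes"]).mean() >= 0.6


class TestVariability:
    def test_identical_trials_zero_inter(self):
        aligned = aligned_from([{(0.0, 0.3): 2.0}, {(0.0, 0.8): 1.0}])
        v = response_variability(aligned)
        assert v["inter_trial"]["r1"] == 0.0
        assert v["inter_trial"]["latency"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_neurons_zero_intra(self):
        aligned = aligned_from([{(0.0, 0.3): 2.0}] * 4)
        v = response_variability(aligned)
        assert v["intra_trial"]["r1"] == 0.0

    def test_neuron_spread_exceeds_trial_jitter(self, puff_session):
        """Latencies vary more across neurons than across trials for one
        neuron, by construction of the generator."""
        aligned, _ = puff_session
        v = response_variability(aligned)
        assert v["intra_trial"]["latency"] > v["inter_trial"]["latency"]

    def test_minimum_sizes(self):
        aligned = aligned_from([{(0.0, 0.3): 1.0}], n_trials=1)
        with pytest.raises(ValueError):
            response_variability(aligned)


class TestSimilarity:
    def test_identical_unit_trials(self):
        aligned = aligned_from([{(-0.6, 1.0): 1.0}, {(-0.6, 1.0): 0.0}])
        sim = trial_similarity(aligned, normalize_vectors=True)
        np.testing.assert_allclose(sim.similarity, 1.0)

    def test_single_trial_rejected(self):
        aligned = aligned_from([{(0.0, 0.3): 1.0}], n_trials=1)
        with pytest.raises(ValueError):
            trial_similarity(aligned)

    def test_trial_relabeling_symmetry(self, puff_session):
        aligned, _ = puff_session
        s1 = trial_similarity(aligned)
        flipped = PuffAlignedData(rates=aligned.rates[::-1].copy(),
                                  time=aligned.time, bin=aligned.bin)
        s2 = trial_similarity(flipped)
        np.testing.assert_allclose(s1.similarity, s2.similarity, atol=1e-9)

    def test_reliable_early_response_elevates_s(self, puff_session):
        """Transient, reliable responses raise S(t) early; variability later
        brings it back toward baseline."""
        aligned, _ = puff_session
        sim = trial_similarity(aligned)
        early = sim.similarity[(sim.time >= 0) & (sim.time < 0.3)].mean()
        late = sim.similarity[(sim.time >= 0.5) & (sim.time < 0.8)].mean()
        pre = sim.similarity[sim.time < 0].mean()
        assert early > 2 * pre
        assert early > late
        assert 0.0 <= sim.decay_integral <= 0.8

    def test_behavior_cv_profile(self, puff_session):
        aligned, _ = puff_session
        wmi = np.abs(np.random.default_rng(0).standard_normal(
            (aligned.n_trials, aligned.rates.shape[2])))
        sim = trial_similarity(aligned, wmi_aligned=wmi)
        assert sim.behavior_cv.shape == sim.similarity.shape


class TestStepCycle:
    def test_phase_locked_neurons_flagged(self):
        """Phase-locked cells are flagged; homogeneous Poisson cells pass
        the null at the ~5% nominal rate."""
        s = generate_step_session(n_neurons=40, n_lifts=60, seed=2)
        df = step_cycle_modulation(s["events"], s["lift_times"],
                                   s["paw_time"], s["paw_height"], seed=0)
        mod, unmod = s["modulated"], ~s["modulated"]
        assert df.loc[mod, "modulated"].mean() >= 0.8
        assert df.loc[unmod, "modulated"].mean() <= 0.1

    def test_shuffle_control_not_locked(self):
        s = generate_step_session(seed=2)
        df = step_cycle_modulation(s["events"], s["lift_times"],
                                   s["paw_time"], s["paw_height"], seed=0)
        assert (df.loc[s["modulated"], "p_shuffle"] > 0.1).mean() >= 0.8

    def test_too_few_instances_skipped(self):
        s = generate_step_session(n_lifts=5, seed=1)
        with pytest.warns(UserWarning, match="few"):
            df = step_cycle_modulation(s["events"], s["lift_times"],
                                       s["paw_time"], s["paw_height"])
        assert df.empty
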