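"""Ridge decoding of behavior from population modes, with shuffle controls."""

import numpy as np
import pytest

from gocpop.behavior import detect_active_periods, generate_behavior
from gocpop.decoding import (decode_rank_k, prepare_regression_data,
                             regress_pm1_on_behavior, ridge_cv,
                             shuffle_controls, _resample_overlap)
from gocpop.modes import decompose
from gocpop.synthetic import SyntheticSessionSpec, generate_population_activity


@pytest.fixture(scope="module")
def decode_session():
    """Session whose first differential mode carries fast whisking-amplitude
    dynamics, so decoding gains from modes beyond PM1."""
    behavior = generate_behavior(300.0, seed=13)
    spec = SyntheticSessionSpec(seed=13, mode_behaviors=("wamp",),
                                diff_mode_variance=0.25, noise_variance=0.05)
    activity, truth = generate_population_activity(spec, behavior)
    periods = detect_active_periods(behavior)
    return behavior, activity, truth, periods


class TestPrepare:
    def test_resampling_conserves_mean(self, rng):
        x = rng.standard_normal((3, 500))
        out = _resample_overlap(x, 0.04, 0.05, 400)
        np.testing.assert_allclose(out.mean(axis=1), x.mean(axis=1),
                                   atol=1e-10)

    def test_fifty_ms_sample_spans_two_40ms_bins(self):
        """Each 20 Hz sample overlaps exactly two 40 ms bins (0.8/0.2)."""
        x = np.zeros((1, 10))
        x[0, 1] = 1.0   # bin [40, 80) ms
        out = _resample_overlap(x, 0.04, 0.05, 8)
        # sample [0, 50) overlaps the bin for 10 ms -> 10/50 of its value;
        # sample [50, 100) overlaps for 30 ms -> 30/50
        np.testing.assert_allclose(out[0, :2], [0.2, 0.6], atol=1e-9)

    def test_blocks_and_periods(self, decode_session):
        behavior, activity, _, periods = decode_session
        dec = decompose(activity)
        data = prepare_regression_data(dec.dynamics[:, :3], activity.bin,
                                       behavior, periods)
        # 500 ms blocks at 20 Hz hold at most 10 samples
        _, counts = np.unique(data.block_id, return_counts=True)
        assert counts.max() == 10
        assert data.modes.shape[1] == 3
        assert len(data.block_id) == len(data.period_id)

    def test_empty_periods_rejected(self, decode_session):
        behavior, activity, _, _ = decode_session
        dec = decompose(activity)
        from gocpop.behavior import ActivePeriods
        with pytest.raises(ValueError):
            prepare_regression_data(dec.dynamics, activity.bin, behavior,
                                    ActivePeriods([]))


class TestRidgeCv:
    @staticmethod
    def blocked(n=800):
        return np.arange(n) // 10

    def test_noiseless_linear_target(self, rng):
        x = rng.standard_normal((800, 4))
        y = x @ np.array([1.0, -2.0, 0.5, 3.0])
        res = ridge_cv(x, y, self.blocked(), n_partitions=20, seed=0)
        assert res.cvev > 0.99

    def test_independent_target_negative(self, rng):
        x = rng.standard_normal((800, 4))
        y = rng.standard_normal(800)
        res = ridge_cv(x, y, self.blocked(), n_partitions=30, seed=0)
        assert res.cvev <= 0.0

    def test_duplicated_columns_stable(self, rng):
        x = rng.standard_normal((800, 3))
        y = x @ np.array([1.0, 0.5, -1.0]) + 0.3 * rng.standard_normal(800)
        a = ridge_cv(x, y, self.blocked(), n_partitions=20, seed=2)
        b = ridge_cv(np.hstack([x, x]), y, self.blocked(), n_partitions=20,
                     seed=2)
        assert abs(a.cvev - b.cvev) < 0.02

    def test_zero_variance_target(self, rng):
        with pytest.raises(ValueError):
            ridge_cv(rng.standard_normal((800, 2)), np.ones(800),
                     self.blocked())


class TestDecodeRankK:
    def test_pm1_target_decoded_at_rank_one(self, decode_session):
        """If the target IS the common-mode dynamics, rank 1 suffices."""
        behavior, activity, _, periods = decode_session
        dec = decompose(activity)
        pm1 = dec.dynamics[:, 0]
        t_act = (np.arange(activity.n_bins) + 0.5) * activity.bin
        beh2 = generate_behavior(300.0, seed=13)
        interp = np.interp(beh2.time, t_act, pm1)
        beh2.wmi = interp - interp.min() + 0.01
        res = decode_rank_k(activity, beh2, "wmi", periods,
                            k_range=range(1, 4), n_partitions=10, seed=0)
        assert res.cvev_pm1 > 0.95
        assert res.optimal_K == 1

    def test_differential_mode_carries_behavior(self, decode_session):
        """A behavior loaded on a differential mode needs K > 1 and the
        optimal-K rule captures the improvement."""
        behavior, activity, _, periods = decode_session
        res = decode_rank_k(activity, behavior, "wamp", periods,
                            k_range=range(1, 8), n_partitions=15, seed=0)
        assert res.optimal_K > 1
        assert res.cvev_optimal - res.cvev_pm1 > 0.05

    def test_optimal_at_least_pm1_by_construction(self, decode_session):
        behavior, activity, _, periods = decode_session
        for target in ("wmi", "loco"):
            res = decode_rank_k(activity, behavior, target, periods,
                                k_range=range(1, 6), n_partitions=10, seed=1)
            assert res.cvev_optimal >= res.cvev_pm1 - 1e-12

    def test_k_range_truncated(self, decode_session):
        behavior, activity, _, periods = decode_session
        with pytest.warns(UserWarning, match="truncated"):
            decode_rank_k(activity, behavior, "wmi", periods,
                          k_range=range(1, 500), n_partitions=2, seed=0)


class TestShuffleControls:
    @staticmethod
    def data():
        y = np.arange(60, dtype=float)
        block = np.arange(60) // 10
        period = np.repeat([0, 1, 2], 20)
        return y, block, period

    def test_marginal_preserved(self):
        y, block, period = self.data()
        for mode in ("within", "across"):
            ys = shuffle_controls(y, block, period, mode, seed=1)
            np.testing.assert_array_equal(np.sort(ys), np.sort(y))

    def test_single_block_period_unchanged(self):
        y = np.arange(30, dtype=float)
        block = np.concatenate([np.zeros(10), [1] * 10, [2] * 10]).astype(int)
        period = np.repeat([0, 1, 2], 10)   # one block per period
        ys = shuffle_controls(y, block, period, "within", seed=0)
        np.testing.assert_array_equal(ys, y)

    def test_within_keeps_period_content(self):
        y, block, period = self.data()
        ys = shuffle_controls(y, block, period, "within", seed=3)
        for p in (0, 1, 2):
            np.testing.assert_array_equal(np.sort(ys[period == p]),
                                          np.sort(y[period == p]))

    def test_across_shuffle_destroys_decoding(self, decode_session):
        behavior, activity, _, periods = decode_session
        res = decode_rank_k(activity, behavior, "wamp", periods,
                            k_range=range(1, 4), n_partitions=10, seed=0,
                            shuffles=True)
        assert res.shuffle_cvev["across"] <= 0.0
        assert res.shuffle_cvev["across"] <= res.shuffle_cvev["within"] + 0.05


class TestPm1Regression:
    def test_linear_combination_beats_single_behaviors(self, decode_session):
        """PM1 tracks overall behavioral intensity, so the multilinear fit
        outperforms every single-variable regression."""
        behavior, activity, _, periods = decode_session
        out = regress_pm1_on_behavior(activity, behavior, periods,
                                      n_partitions=15, seed=0)
        singles = [v for k, v in out.items() if k != "linear_comb"]
        assert out["linear_comb"] >= max(singles) - 1e-9
        assert out["linear_comb"] > 0.3
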