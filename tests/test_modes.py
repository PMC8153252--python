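"""Mode decomposition, bi-cross-validation, dimensionality, ICA stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gocpop.activity import PopulationActivity
from gocpop.modes import (cross_validated_evar, decompose,
                          effective_dimensionality,
                          ica_stability_dimensionality, loading_overlap,
                          project_out_pm1)


class TestDecompose:
    def test_rank_one_single_singular_value(self, rng):
        u = rng.standard_normal(6)
        v = rng.standard_normal(200)
        x = np.outer(u, v)
        dec = decompose(x)
        assert dec.singular_values[0] > 1.0
        assert np.all(dec.singular_values[1:] < 1e-10 * dec.singular_values[0])

    def test_full_rank_reconstruction(self, rng):
        x = rng.standard_normal((8, 60))
        dec = decompose(x)
        rec = dec.reconstruct() + dec.mean[:, None]
        assert np.linalg.norm(rec - x) < 1e-8 * np.linalg.norm(x)

    def test_orthonormal_loadings(self, rng):
        dec = decompose(rng.standard_normal((10, 100)))
        np.testing.assert_allclose(dec.loadings.T @ dec.loadings,
                                   np.eye(10), atol=1e-8)

    def test_eigenvalues_match_bruteforce_covariance(self, rng):
        """Oracle: eigenvalues equal eigh of the sample covariance matrix."""
        x = rng.standard_normal((8, 50))
        dec = decompose(x)
        xc = x - x.mean(axis=1, keepdims=True)
        lam = np.sort(np.linalg.eigvalsh(xc @ xc.T / (x.shape[1] - 1)))[::-1]
        np.testing.assert_allclose(dec.eigenvalues, lam, atol=1e-8)

    def test_pm1_loadings_positive_on_common_mode_session(self, synthetic_session):
        _, activity, _ = synthetic_session
        dec = decompose(activity)
        assert np.all(dec.loadings[:, 0] > 0)

    def test_zero_variance_neuron_warns(self, rng):
        x = rng.standard_normal((4, 50))
        x[2] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            decompose(x)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.ones((1, 50)))


class TestResidual:
    def test_rank_one_residual_vanishes(self, rng):
        x = np.outer(rng.standard_normal(6), rng.standard_normal(100))
        assert np.abs(project_out_pm1(x)).max() < 1e-10

    def test_orthogonal_to_pm1(self, synthetic_session):
        _, activity, _ = synthetic_session
        res = project_out_pm1(activity)
        u1 = decompose(activity).loadings[:, 0]
        assert np.abs(u1 @ res).max() < 1e-8 * np.linalg.norm(activity.rates)

    def test_pythagoras(self, rng):
        x = rng.standard_normal((8, 200))
        dec = decompose(x)
        xc = x - dec.mean[:, None]
        res = project_out_pm1(x)
        pm1_part = xc - res
        assert (np.sum(xc**2) ==
                pytest.approx(np.sum(res**2) + np.sum(pm1_part**2), rel=1e-10))

    def test_residual_correlations_mixed_sign(self, synthetic_session):
        _, activity, _ = synthetic_session
        res = project_out_pm1(activity)
        c = np.corrcoef(res)
        iu = np.triu_indices(c.shape[0], 1)
        assert (c[iu] > 0.05).any() and (c[iu] < -0.05).any()
        assert abs(np.mean(c[iu])) < 0.05

    def test_single_neuron_rejected(self):
        with pytest.raises(ValueError):
            project_out_pm1(np.ones((1, 30)))


class TestCrossValidatedEvar:
    def test_noiseless_rank_one(self, rng):
        u = np.abs(rng.standard_normal(20)) + 0.1
        v = rng.standard_normal(400)
        act = PopulationActivity(np.outer(u, v), bin=0.04)
        curve = cross_validated_evar(act, k_max=4, n_repeats=10, seed=0)
        assert curve.cvev[0] == pytest.approx(1.0, abs=1e-6)
        assert curve.shared_dimensionality == 1

    def test_white_noise_does_not_generalize(self, rng):
        act = PopulationActivity(rng.standard_normal((20, 1000)), bin=0.04)
        curve = cross_validated_evar(act, k_max=8, n_repeats=10, seed=0)
        assert curve.max_cvev <= 0.0

    def test_invariance_to_global_scale(self, rng):
        x = rng.standard_normal((15, 500)) + 2.0 * np.outer(
            np.ones(15), rng.standard_normal(500))
        a = cross_validated_evar(PopulationActivity(x, bin=0.04),
                                 k_max=3, n_repeats=8, seed=1)
        b = cross_validated_evar(PopulationActivity(5.0 * x, bin=0.04),
                                 k_max=3, n_repeats=8, seed=1)
        np.testing.assert_allclose(a.cvev, b.cvev, atol=1e-10)

    def test_invariance_to_neuron_permutation(self, rng):
        """Permutation changes only which neurons fall in random splits, so
        the mean curve agrees up to estimator variance."""
        x = rng.standard_normal((15, 500)) + 2.0 * np.outer(
            np.ones(15), rng.standard_normal(500))
        a = cross_validated_evar(PopulationActivity(x, bin=0.04),
                                 k_max=3, n_repeats=40, seed=1)
        b = cross_validated_evar(PopulationActivity(x[rng.permutation(15)],
                                                    bin=0.04),
                                 k_max=3, n_repeats=40, seed=1)
        np.testing.assert_allclose(a.cvev, b.cvev, atol=0.06)

    def test_kmax_truncated_with_warning(self, rng):
        act = PopulationActivity(rng.standard_normal((12, 200)), bin=0.04)
        with pytest.warns(UserWarning, match="truncated"):
            curve = cross_validated_evar(act, k_max=50, n_repeats=3, seed=0)
        assert curve.K.max() <= 10

    def test_population_too_small(self, rng):
        with pytest.raises(ValueError):
            cross_validated_evar(
                PopulationActivity(rng.standard_normal((5, 100)), bin=0.04))


class TestEffectiveDimensionality:
    @pytest.mark.parametrize("m", [1, 3, 7])
    def test_equal_variance_gives_mode_count(self, m):
        lam = np.zeros(10)
        lam[:m] = 2.5
        assert effective_dimensionality(lam) == pytest.approx(m, abs=1e-12)

    def test_hand_computed_value(self):
        assert effective_dimensionality([3.0, 1.0]) == pytest.approx(1.6)

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=20),
           st.floats(0.01, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, lam, c):
        a = effective_dimensionality(lam)
        b = effective_dimensionality([c * x for x in lam])
        assert a == pytest.approx(b, rel=1e-9)
        assert 1.0 - 1e-9 <= a <= len(lam) + 1e-9

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            effective_dimensionality([0.0, 0.0])
        with pytest.raises(ValueError):
            effective_dimensionality([-1.0, 2.0])


class TestLoadingOverlap:
    def test_identical_rows(self):
        u = np.tile(np.array([[0.5, 0.3, 0.2, 0.1]]), (3, 1))
        ov = loading_overlap(u, signal_k=4)
        expected = np.sum(u[0, 1:4] ** 2)
        np.testing.assert_allclose(ov, expected)

    def test_orthogonal_rows(self):
        u = np.zeros((2, 3))
        u[0, 1], u[1, 2] = 1.0, 1.0
        assert loading_overlap(u, signal_k=3)[0, 1] == 0.0

    def test_bad_signal_k(self):
        u = np.ones((4, 3))
        with pytest.raises(ValueError):
            loading_overlap(u, signal_k=1)
        with pytest.raises(ValueError):
            loading_overlap(u, signal_k=5)

    def test_no_spatial_structure_in_synthetic_modes(self, synthetic_session):
        """Position-independent loadings: overlap ~ flat in distance."""
        _, activity, truth = synthetic_session
        dec = decompose(activity)
        ov = loading_overlap(dec.loadings, signal_k=truth.n_modes)
        d = np.linalg.norm(activity.positions[:, None]
                           - activity.positions[None, :], axis=-1)
        iu = np.triu_indices(ov.shape[0], 1)
        slope = np.polyfit(d[iu], ov[iu], 1)[0]
        assert abs(slope * 300.0) < 0.1


class TestIcaStability:
    @staticmethod
    def _laplace_modes(n_modes, n_neurons=30, n_bins=2400, noise=0.03, seed=0):
        rng = np.random.default_rng(seed)
        u, _ = np.linalg.qr(rng.standard_normal((n_neurons, n_modes)))
        d = rng.laplace(size=(n_modes, n_bins))
        x = u @ d + noise * rng.standard_normal((n_neurons, n_bins))
        return PopulationActivity(x, bin=0.04), u

    def test_recovers_well_separated_modes(self):
        act, _ = self._laplace_modes(3)
        res = ica_stability_dimensionality(act, k_candidates=range(2, 6),
                                           n_partitions=4, seed=0)
        assert res.dimensionality == 3
        assert res.stability[3] > 0.9
        assert res.stability[5] < res.stability[3]

    def test_white_noise_unstable(self, rng):
        act = PopulationActivity(rng.standard_normal((20, 2400)), bin=0.04)
        res = ica_stability_dimensionality(act, k_candidates=range(2, 4),
                                           n_partitions=4, seed=0)
        assert res.stability[2] < 0.9
        assert res.dimensionality == 1

    def test_principal_angle_orthogonal_construction(self, synthetic_session):
        """PM1 is orthogonal to the differential modes by construction."""
        _, activity, _ = synthetic_session
        res = ica_stability_dimensionality(activity,
                                           k_candidates=range(2, 8),
                                           n_partitions=4, seed=0)
        assert res.pm1_principal_angle_deg > 60.0

    def test_too_short_rejected(self, rng):
        act = PopulationActivity(rng.standard_normal((10, 100)), bin=0.04)
        with pytest.raises(ValueError):
            ica_stability_dimensionality(act)
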