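"""Forward model physics, covariance, LCMV weights and spectral utilities."""

import numpy as np
import pytest
from scipy import signal

from opmconn.bands import BandDefinition, band_catalog
from opmconn.beamformer import (
    LCMVBeamformer,
    compute_covariance,
    lcmv_weights,
    optimal_orientation,
    project_sources,
    regularize_covariance,
)
from opmconn.datatypes import Recording
from opmconn.forward import dipole_leadfield, parcel_leadfields
from opmconn.preprocess import bandpass_filter
from opmconn.simulate import (
    SimulationSpec,
    dipole_orientations,
    make_parcels,
    make_sensor_array,
    project_to_sensors,
    simulate_sources,
)
from opmconn.spectral import psd_fractional_difference, relative_band_power, welch_psd

FS = 1200.0
MU0_4PI = 1e-7 * 1e-9 * 1e15  # fT per nAm at metre scale


def random_interior_point(rng, r_max=0.08):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v) * rng.uniform(0.01, r_max)


class TestForwardModel:
    def test_radial_dipoles_are_silent(self):
        # at 100 random interior points, a radial moment produces a field
        # orders of magnitude below a tangential one
        rng = np.random.default_rng(0)
        array = make_sensor_array(10, 0.10)
        for _ in range(100):
            r0 = random_interior_point(rng)
            radial = r0 / np.linalg.norm(r0)
            tang = np.cross(radial, [0.0, 0.0, 1.0])
            if np.linalg.norm(tang) < 1e-6:
                tang = np.cross(radial, [1.0, 0.0, 0.0])
            tang /= np.linalg.norm(tang)
            l_rad = dipole_leadfield(r0, radial, array)
            l_tan = dipole_leadfield(r0, tang, array)
            assert np.linalg.norm(l_rad) < 1e-12 * np.linalg.norm(l_tan)

    def test_radial_field_component_matches_free_space_dipole(self):
        # classical sphere-conductor property: the radial field equals the
        # primary (Biot-Savart) current-dipole term's radial component
        rng = np.random.default_rng(1)
        from opmconn.forward import _sarvas_field

        for _ in range(100):
            r0 = random_interior_point(rng)
            q = rng.normal(size=3)
            r = rng.normal(size=3)
            r = r / np.linalg.norm(r) * rng.uniform(0.095, 0.2)
            B = _sarvas_field(r0, q, r[None])[0]
            a = r - r0
            B_primary = MU0_4PI * np.cross(q, a) / np.linalg.norm(a) ** 3
            rhat = r / np.linalg.norm(r)
            assert B @ rhat == pytest.approx(B_primary @ rhat, rel=1e-8)

    def test_leadfield_independent_of_sphere_radius(self):
        array = make_sensor_array(8, 0.10)
        r0 = np.array([0.02, -0.03, 0.05])
        q = np.array([0.0, 1.0, 0.0])
        l1 = dipole_leadfield(r0, q, array, sphere_radius=0.09)
        l2 = dipole_leadfield(r0, q, array, sphere_radius=0.095)
        np.testing.assert_allclose(l1, l2, atol=1e-10)

    def test_geometry_validation(self):
        array = make_sensor_array(8, 0.10)
        with pytest.raises(ValueError):
            dipole_leadfield([0.0, 0.0, 0.095], [1.0, 0, 0], array, sphere_radius=0.09)

    def test_parcel_leadfields_shape_and_center_silence(self):
        array = make_sensor_array(8, 0.10)
        parcels = make_parcels(5, 0.09, seed=0)
        L = parcel_leadfields(parcels, array, sphere_radius=0.09)
        assert L.shape == (5, 24, 3)
        assert np.isfinite(L).all()
        # a dipole exactly at the centre is fully silent (q x r0 = 0)
        l_centre = np.column_stack(
            [dipole_leadfield([0.0, 0.0, 0.0], ax, array) for ax in np.eye(3)]
        )
        assert np.abs(l_centre).max() == 0.0


class TestCovariance:
    def test_white_noise_gives_scaled_identity(self):
        rng = np.random.default_rng(0)
        rec = Recording(data=rng.normal(size=(10, 120000)), fs=FS)
        C = compute_covariance(rec)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 0.05 * np.diag(C).mean()

    def test_duplicated_channel_makes_covariance_singular(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(5, 20000))
        data[3] = data[1]
        C = compute_covariance(Recording(data=data, fs=FS))
        np.testing.assert_allclose(C[1], C[3], atol=1e-12)
        assert np.linalg.eigvalsh(C).min() < 1e-10 * np.linalg.eigvalsh(C).max()

    def test_matches_brute_force_on_filtered_good_epochs(self):
        rng = np.random.default_rng(2)
        rec = Recording(
            data=rng.normal(size=(4, 36000)), fs=FS, epoch_length_s=10.0,
            epoch_good=np.array([True, False, True]),
            channel_good=np.array([True, True, False, True]),
        )
        band = BandDefinition("alpha", 8.0, 12.0)
        C = compute_covariance(rec, band)
        x = bandpass_filter(rec.data, 8.0, 12.0, FS)
        keep = np.r_[0:12000, 24000:36000]
        seg = x[np.array([0, 1, 3])][:, keep]
        np.testing.assert_allclose(C, np.cov(seg), atol=1e-10)

    def test_regularisation_hand_example(self):
        C_r, mu = regularize_covariance(np.diag([4.0, 1.0]), 0.05)
        assert mu == pytest.approx(0.2)
        np.testing.assert_allclose(C_r, np.diag([4.2, 1.2]))
        C_r0, mu0 = regularize_covariance(np.zeros((3, 3)))
        assert mu0 == 0.0 and not C_r0.any()

    def test_largest_singular_value_matches_svd_oracle(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(20, 20))
        C = A @ A.T
        _, mu = regularize_covariance(C, 0.05)
        assert mu == pytest.approx(0.05 * np.linalg.svd(C, compute_uv=False)[0], abs=1e-10)


class TestOrientationAndWeights:
    def test_identity_covariance_maximises_projected_amplitude(self):
        # with no source structure in the covariance, unit-gain projected
        # power (l' C^-1 l)^-1 is largest along the weakest leadfield
        # column: the eigen formulation must pick the min-eigenvalue axis
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 3)))
        L = Q @ np.diag([5.0, 1.0, 0.5])
        eta = optimal_orientation(L, np.eye(12))
        assert abs(eta @ np.array([0.0, 0, 1.0])) > 0.999
        projected_power = 1.0 / (eta @ (L.T @ L) @ eta)
        for trial in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            assert projected_power >= 1.0 / (v @ (L.T @ L) @ v) - 1e-12

    def test_orientation_recovered_from_simulated_source(self):
        array = make_sensor_array(16, 0.10)
        parcels = make_parcels(8, 0.09, seed=5)
        m = dipole_orientations(parcels, seed=5)
        spec = SimulationSpec(n_parcels=8, n_sensors=16, duration_s=30.0, seed=5)
        src, _ = simulate_sources(spec, 0, 0)
        rec = project_to_sensors(src, parcels, array, m, FS)
        rng = np.random.default_rng(5)
        rec = rec.copy_with(data=rec.data + rng.normal(scale=1.0, size=rec.data.shape))
        C_r, _ = regularize_covariance(compute_covariance(rec))
        L = parcel_leadfields(parcels, array)
        radial = parcels.centroids / np.linalg.norm(
            parcels.centroids, axis=1, keepdims=True
        )
        for p in range(8):
            eta = optimal_orientation(L[p], C_r)
            # only the tangential moment is externally visible in a sphere
            m_tan = m[p] - (m[p] @ radial[p]) * radial[p]
            m_tan /= np.linalg.norm(m_tan)
            assert abs(eta @ m_tan) > 0.99

    def test_orientation_invariant_to_leadfield_scale(self):
        rng = np.random.default_rng(1)
        L = rng.normal(size=(10, 3))
        C = np.eye(10) + 0.1 * np.outer(np.ones(10), np.ones(10))
        np.testing.assert_allclose(
            optimal_orientation(L, C), optimal_orientation(17.3 * L, C), atol=1e-10
        )

    def test_unit_gain_constraint(self):
        rng = np.random.default_rng(2)
        L = rng.normal(size=(15, 3))
        A = rng.normal(size=(15, 15))
        C_r, _ = regularize_covariance(A @ A.T)
        eta = optimal_orientation(L, C_r)
        w = lcmv_weights(L, eta, C_r)
        assert w @ (L @ eta) == pytest.approx(1.0, abs=1e-8)

    def test_identity_covariance_gives_matched_filter(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(10, 3))
        eta = optimal_orientation(L, np.eye(10))
        w = lcmv_weights(L, eta, np.eye(10))
        l = L @ eta
        np.testing.assert_allclose(w, l / (l @ l), atol=1e-12)

    def test_interference_suppression_between_sources(self):
        # the variance recovered at source A changes < 5% when source B
        # doubles in amplitude
        array = make_sensor_array(16, 0.10)
        parcels = make_parcels(6, 0.09, seed=7)
        m = dipole_orientations(parcels, seed=7)
        spec = SimulationSpec(n_parcels=6, n_sensors=16, duration_s=60.0, seed=7)
        src, _ = simulate_sources(spec, 0, 0)
        keep = np.zeros_like(src)
        keep[0], keep[3] = src[0], src[3]

        def recon_var_A(scale_B):
            s = keep.copy()
            s[3] *= scale_B
            rec = project_to_sensors(s, parcels, array, m, FS)
            rng = np.random.default_rng(7)
            rec = rec.copy_with(
                data=rec.data + rng.normal(scale=5.0, size=rec.data.shape)
            )
            bf = LCMVBeamformer().fit(rec, parcels, array)
            return bf.transform(rec)[0].var()

        v1, v2 = recon_var_A(1.0), recon_var_A(2.0)
        assert abs(v2 - v1) / v1 < 0.05

    def test_project_sources_contracts(self):
        rec = Recording(data=np.zeros((6, 6000)), fs=FS)
        w = np.ones((2, 6)) / 6
        assert not project_sources(rec, w).any()
        with pytest.raises(ValueError):
            project_sources(rec, np.ones((2, 5)))


class TestSpectral:
    def test_welch_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=240000)
        f, P = welch_psd(x, FS)
        df = f[1] - f[0]
        assert np.sum(P) * df == pytest.approx(x.var(), rel=0.05)
        # one-sided density of unit-variance white noise is 2/fs
        assert P[(f > 50) & (f < 500)].mean() == pytest.approx(2 / FS, rel=0.10)

    def test_welch_peak_at_tone_frequency(self):
        t = np.arange(24000) / FS
        f, P = welch_psd(np.sin(2 * np.pi * 10.0 * t), FS)
        assert f[np.argmax(P)] == pytest.approx(10.0, abs=0.5)
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), FS)

    def test_band_power_of_alpha_tone_concentrates_in_alpha(self):
        t = np.arange(120000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        vals = relative_band_power(x, band_catalog(), FS)
        by_name = dict(zip([b.name for b in band_catalog()], vals))
        assert by_name["alpha"] >= 0.98
        assert by_name["theta"] < 0.02 and by_name["beta"] < 0.02
        assert (vals >= 0).all() and (vals <= 1.02).all()

    def test_band_power_of_white_noise_follows_bandwidth(self):
        rng = np.random.default_rng(1)
        x = bandpass_filter(rng.normal(size=600000), 1.0, 150.0, FS)
        vals = relative_band_power(x, band_catalog(), FS)
        for b, v in zip(band_catalog(), vals):
            expected = (b.hi - b.lo) / 149.0
            assert v == pytest.approx(expected, rel=0.10)

    def test_psd_difference_identical_runs_is_zero(self):
        rng = np.random.default_rng(2)
        f, P = welch_psd(rng.normal(size=24000), FS)
        assert psd_fractional_difference(P, P, f) == 0.0

    def test_psd_difference_three_bin_hand_computation(self):
        f = np.array([0.0, 0.5, 1.0])
        P1 = np.array([1.0, 2.0, 3.0])
        P2 = np.zeros(3)
        # sqrt(1+4+9) / ((0.5+1+1.5) * 0.5)
        expected = np.sqrt(14.0) / 1.5
        assert psd_fractional_difference(P1, P2, f) == pytest.approx(expected, abs=1e-12)
        # symmetric under run relabelling
        assert psd_fractional_difference(P2, P1, f) == pytest.approx(expected, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            psd_fractional_difference(np.ones(3), np.ones(4), np.arange(4.0))


class TestBeamformerEstimator:
    def test_empty_room_projection_below_signal_at_low_frequency(self, alpha_band):
        array = make_sensor_array(12, 0.10)
        parcels = make_parcels(6, 0.09, seed=9)
        m = dipole_orientations(parcels, seed=9)
        spec = SimulationSpec(n_parcels=6, n_sensors=12, duration_s=60.0, seed=9)
        src, _ = simulate_sources(spec, 0, 0)
        rec = project_to_sensors(src, parcels, array, m, FS)
        rng = np.random.default_rng(9)
        noise_sd = 13.0 * np.sqrt(FS / 2)
        signal_rec = rec.copy_with(
            data=rec.data + rng.normal(scale=noise_sd, size=rec.data.shape)
        )
        empty_room = Recording(
            data=rng.normal(scale=noise_sd, size=rec.data.shape), fs=FS
        )
        bf = LCMVBeamformer(band=alpha_band).fit(signal_rec, parcels, array)
        s_sig = bf.transform(signal_rec)
        s_noise = bf.transform(empty_room)
        assert (s_sig.var(axis=1) > s_noise.var(axis=1)).all()
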