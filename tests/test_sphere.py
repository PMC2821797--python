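"""Analytic multilayer-sphere solver and the sensor-fitted scheme."""

import numpy as np
import pytest
from scipy.special import eval_legendre

from headpsf.geometry import (
    SensorArray,
    ShellSpec,
    make_cortex_source_space,
    make_shell_spec,
)
from headpsf.sphere import (
    Dipole,
    fit_sensor_sphere,
    layer_transfer_coefficients,
    sensor_fitted_leadfield,
    sphere_potential,
)

RADII = (92.0, 87.4, 80.04, 77.28)


def homogeneous_oracle(pos, mom, electrodes, R, sigma, n_terms=300):
    """Independent Legendre-series evaluation of the homogeneous sphere
    (scipy eval_legendre + finite-difference derivative, textbook T_n)."""
    pos, mom = np.asarray(pos, float), np.asarray(mom, float)
    b = np.linalg.norm(pos)
    rhat = pos / b if b > 0 else np.array([0.0, 0.0, 1.0])
    out = []
    for e in electrodes:
        ehat = e / np.linalg.norm(e)
        cg = float(np.clip(rhat @ ehat, -1, 1))
        t = ehat - cg * rhat
        st = np.linalg.norm(t)
        that = t / st if st > 1e-12 else t * 0
        mr, mt = mom @ rhat, mom @ that
        v = 0.0
        h = 1e-7
        for n in range(1, n_terms + 1):
            P = eval_legendre(n, cg)
            hi, lo = min(cg + h, 1.0), max(cg - h, -1.0)
            dP = (eval_legendre(n, hi) - eval_legendre(n, lo)) / (hi - lo)
            v += (2 * n + 1) / n * (b / R) ** (n - 1) * (n * mr * P + mt * st * dP)
        out.append(v / (4 * np.pi * sigma * R**2))
    out = np.asarray(out)
    return out - out.mean()


@pytest.fixture(scope="module")
def ring_electrodes():
    """24 electrodes on a tilted great circle of the scalp sphere."""
    t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    pts = np.column_stack([np.cos(t), 0.3 * np.sin(t), np.sin(t)])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return SensorArray(pts * 92.0)


class TestTransferCoefficients:
    def test_homogeneous_closed_form(self):
        sh = ShellSpec(RADII, (0.4, 0.4, 0.4, 0.4))
        T = layer_transfer_coefficients(sh, 120)
        n = np.arange(1, 121)
        assert np.abs(T - (2 * n + 1) / n).max() < 1e-12

    def test_two_layer_closed_form(self):
        """Single conductivity jump: frozen values from the exact symbolic
        solution of the two-layer boundary system (rational arithmetic)."""
        sh = ShellSpec(RADII, (0.33, 0.33, 1.79, 1.79))
        T = layer_transfer_coefficients(sh, 3)
        expected = [3.6841140790521134, 3.313301184627375, 3.287542376328336]
        np.testing.assert_allclose(T, expected, rtol=1e-12)

    def test_high_contrast_skull_attenuates(self):
        sh_full = make_shell_spec()
        sh_homo = ShellSpec(RADII, (0.33, 0.33, 0.33, 0.33))
        Tf = layer_transfer_coefficients(sh_full, 50)
        Th = layer_transfer_coefficients(sh_homo, 50)
        assert np.all(Tf < Th)  # insulating skull reduces every harmonic
        assert Tf[40] / Th[40] < Tf[0] / Th[0]  # and high n more strongly


class TestSpherePotential:
    def test_center_dipole_matches_closed_form(self, ring_electrodes):
        sh = ShellSpec(RADII, (0.4, 0.4, 0.4, 0.4))
        v = sphere_potential(Dipole([0, 0, 0], [0, 0, 1.0]), sh, ring_electrodes)
        expected = 3 * ring_electrodes.positions[:, 2] / 92.0 / (4 * np.pi * 0.4 * 92**2)
        expected -= expected.mean()
        np.testing.assert_allclose(v, expected, atol=1e-8 * np.abs(expected).max())

    @pytest.mark.parametrize(
        "pos,mom",
        [([20.0, 10.0, 40.0], [0.3, -1.2, 0.7]), ([0, 0, 60.0], [1.0, 0, 0])],
    )
    def test_homogeneous_matches_independent_oracle(self, ring_electrodes, pos, mom):
        sh = ShellSpec(RADII, (0.4, 0.4, 0.4, 0.4))
        v = sphere_potential(Dipole(pos, mom), sh, ring_electrodes)
        w = homogeneous_oracle(pos, mom, ring_electrodes.positions, 92.0, 0.4)
        np.testing.assert_allclose(v, w, atol=1e-6 * np.abs(w).max())

    def test_axial_symmetry_and_antipodes(self, shells):
        # central radial dipole: potential depends only on polar angle
        t = np.radians([30, 30, 30, 150, 150, 150])
        p = np.radians([0, 120, 240, 0, 120, 240])
        el = SensorArray(
            92.0
            * np.column_stack(
                [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)]
            )
        )
        v = sphere_potential(Dipole([0, 0, 30.0], [0, 0, 1.0]), shells, el)
        assert np.allclose(v[:3], v[0]) and np.allclose(v[3:], v[3])
        assert abs(v[0] + v[3]) < 1e-12 * abs(v[0])  # antipodal pair sums to 0

    def test_linearity_in_moment(self, shells, ring_electrodes):
        d1 = Dipole([10, 5, 40.0], [1.0, 2.0, -0.5])
        d2 = Dipole([10, 5, 40.0], [2.0, 4.0, -1.0])
        v1 = sphere_potential(d1, shells, ring_electrodes)
        v2 = sphere_potential(d2, shells, ring_electrodes)
        np.testing.assert_allclose(v2, 2 * v1, rtol=1e-12)

    def test_series_converged_at_default_order(self, shells, ring_electrodes):
        d = Dipole([0, 0, 0.95 * shells.brain_radius], [1.0, 0, 0.5])
        a = sphere_potential(d, shells, ring_electrodes, n_terms=200)
        b = sphere_potential(d, shells, ring_electrodes, n_terms=400)
        assert np.abs(a - b).max() <= 1e-6 * np.abs(b).max()

    def test_rotation_equivariance(self, shells, ring_electrodes, rng):
        from scipy.spatial.transform import Rotation

        Rm = Rotation.random(random_state=3).as_matrix()
        d = Dipole([15, -20, 35.0], [0.5, 1.0, -1.0])
        v = sphere_potential(d, shells, ring_electrodes)
        el_rot = SensorArray(ring_electrodes.positions @ Rm.T)
        d_rot = Dipole(Rm @ d.position, Rm @ d.moment)
        v_rot = sphere_potential(d_rot, shells, el_rot)
        np.testing.assert_allclose(v, v_rot, atol=1e-10 * np.abs(v).max())

    def test_dipole_outside_brain_rejected(self, shells, ring_electrodes):
        with pytest.raises(ValueError):
            sphere_potential(
                Dipole([0, 0, shells.brain_radius], [1, 0, 0]), shells, ring_electrodes
            )


class TestFittedSphere:
    def test_spherical_scalp_recovers_center_and_radius(self, shells, sphere_head,
                                                        electrodes):
        for sensor in electrodes.positions[::13]:
            fit = fit_sensor_sphere(sphere_head[0], sensor, shells)
            assert np.linalg.norm(fit.center) < 1e-6 * 92
            assert abs(fit.radii[0] - np.linalg.norm(sensor)) < 1e-9
            assert not fit.degenerate

    def test_ellipsoidal_scalp_varies_across_sensors(self, shells):
        from headpsf.geometry import make_sphere_mesh
        import trimesh

        base = make_sphere_mesh(1.0, 642)
        verts = base.vertices * np.array([92.0, 82.8, 73.6])
        scalp = trimesh.Trimesh(verts, base.faces, process=False)
        radii = []
        for sensor in verts[::40]:
            fit = fit_sensor_sphere(scalp, sensor, shells, patch_radius=40.0)
            radii.append(fit.radii[0])
        assert np.ptp(radii) > 1.0  # fitted radius varies over the head

    def test_tiny_patch_rejected(self, shells, sphere_head):
        with pytest.raises(ValueError):
            fit_sensor_sphere(
                sphere_head[0], sphere_head[0].vertices[0], shells, patch_radius=1.0
            )


class TestSensorFittedLeadfield:
    def test_reduces_to_single_sphere_on_spherical_head(
        self, shells, sphere_head, electrodes
    ):
        # electrodes at the exact analytic radius so every fitted sphere
        # coincides with the global one (mesh vertices already lie at 92 mm)
        el = SensorArray(
            electrodes.positions
            / np.linalg.norm(electrodes.positions, axis=1, keepdims=True)
            * shells.scalp_radius
        )
        space = make_cortex_source_space(sphere_head[3], 40)
        L, clipped = sensor_fitted_leadfield(sphere_head[0], shells, el, space, "y")
        assert clipped == 0
        for j in (0, 17):
            v = sphere_potential(
                Dipole(space.positions[j], [0, 1.0, 0]), shells, el
            )
            np.testing.assert_allclose(L[:, j], v, atol=1e-6 * np.abs(v).max())

    def test_shape_and_average_reference(self, shells, sphere_head, electrodes):
        space = make_cortex_source_space(sphere_head[3], 30)
        L, _ = sensor_fitted_leadfield(sphere_head[0], shells, electrodes, space, "x")
        assert L.shape == (62, 30)
        np.testing.assert_allclose(L.sum(axis=0), 0, atol=1e-12 * np.abs(L).max())

    def test_sensor_permutation_permutes_rows(self, shells, sphere_head, electrodes):
        space = make_cortex_source_space(sphere_head[3], 20)
        perm = np.random.default_rng(0).permutation(62)
        L, _ = sensor_fitted_leadfield(sphere_head[0], shells, electrodes, space, "z")
        Lp, _ = sensor_fitted_leadfield(
            sphere_head[0], shells, SensorArray(electrodes.positions[perm]),
            space, "z",
        )
        np.testing.assert_allclose(Lp, L[perm], atol=1e-11 * np.abs(L).max())
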