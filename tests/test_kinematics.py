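"""Kinematic wall model, chamber volumes, function indices and flow balance."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from atriflow import kinematics
from atriflow.kinematics import (atrial_function_indices, compute_volume_series,
                                 fit_fourier_model, mesh_volume,
                                 pv_flow_balance, sphericity)


def _single_point_frames(m=20, period=1.0):
    t = np.arange(m) / m * period
    verts = np.zeros((m, 1, 3))
    verts[:, 0, 0] = np.cos(2 * np.pi * t / period)
    return verts, t


class TestFourierModel:
    def test_static_frames_give_zero_velocity(self):
        verts = np.ones((15, 4, 3))
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        model = fit_fourier_model(verts, n_modes=6, period=1.0, faces=faces)
        for t in (0.0, 0.31, 0.77):
            assert np.allclose(model.positions(t), 1.0)
            assert np.allclose(model.velocities(t), 0.0, atol=1e-13)

    def test_analytic_derivative_of_cosine_motion(self):
        """A vertex moving as cos(2 pi t/T) must have velocity
        -(2 pi/T) sin(2 pi t/T) to near machine precision."""
        verts, _ = _single_point_frames(m=20)
        model = fit_fourier_model(verts, n_modes=6, period=1.0,
                                  faces=np.zeros((1, 3), dtype=int))
        for t in np.linspace(0, 1, 13):
            v = model.velocities(t)[0, 0]
            exact = -2 * np.pi * np.sin(2 * np.pi * t)
            assert abs(v - exact) <= 1e-10 * max(1.0, abs(exact))

    def test_exact_periodicity(self):
        verts, _ = _single_point_frames(m=17)
        model = fit_fourier_model(verts, n_modes=6, period=1.0,
                                  faces=np.zeros((1, 3), dtype=int))
        assert np.allclose(model.positions(0.0), model.positions(1.0),
                           atol=1e-13)
        assert np.allclose(model.velocities(0.0), model.velocities(1.0),
                           atol=1e-12)

    def test_exact_interpolation_at_frame_phases(self):
        """With M = 2K+1 frames the truncated-DFT fit interpolates exactly."""
        m = 13
        rng = np.random.default_rng(0)
        verts = rng.standard_normal((m, 5, 3))
        model = fit_fourier_model(verts, n_modes=6, period=2.0,
                                  faces=np.array([[0, 1, 2], [2, 3, 4]]))
        for i in range(m):
            assert np.allclose(model.positions(2.0 * i / m), verts[i],
                               atol=1e-10)

    def test_rejects_too_few_frames_and_mismatched_faces(self):
        with pytest.raises(ValueError, match="at least"):
            fit_fourier_model(np.zeros((10, 2, 3)), n_modes=6,
                              faces=np.zeros((1, 3), dtype=int))
        f1 = trimesh.creation.icosphere(1)
        f2 = trimesh.creation.icosphere(2)
        with pytest.raises(ValueError, match="connectivity"):
            fit_fourier_model([f1] * 7 + [f2] * 8, n_modes=3)


class TestMeshVolume:
    def test_unit_cube_exact(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        assert mesh_volume(box) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_matches_analytic_sphere(self):
        sph = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        assert mesh_volume(sph) == pytest.approx(4 * np.pi / 3, rel=1e-3)

    def test_refinement_reduces_sphere_deficit_second_order(self):
        v = [mesh_volume(trimesh.creation.icosphere(s, radius=1.0))
             for s in (2, 3, 4)]
        errs = [abs(x - 4 * np.pi / 3) for x in v]
        # inscribed-polyhedron deficit shrinks ~4x per subdivision
        assert errs[0] / errs[1] > 3.5
        assert errs[1] / errs[2] > 3.5

    def test_translation_invariance(self):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        v0 = mesh_volume(sph)
        moved = trimesh.Trimesh(vertices=sph.vertices + [17.0, -4.0, 8.5],
                                faces=sph.faces, process=False)
        assert mesh_volume(moved) == pytest.approx(v0, abs=1e-10)

    def test_open_surface_and_inverted_orientation_raise(self):
        sph = trimesh.creation.icosphere(1)
        open_faces = np.asarray(sph.faces)[:-3]
        with pytest.raises(ValueError, match="closed"):
            mesh_volume((np.asarray(sph.vertices), open_faces))
        inverted = np.asarray(sph.faces)[:, ::-1]
        with pytest.raises(ValueError, match="orientation"):
            mesh_volume((np.asarray(sph.vertices), inverted))


class TestVolumeSeries:
    def test_rigid_case_min_equals_max(self):
        verts = np.tile(trimesh.creation.icosphere(2).vertices, (15, 1, 1))
        model = fit_fourier_model(verts, n_modes=6, period=1.0,
                                  faces=trimesh.creation.icosphere(2).faces)
        vols = compute_volume_series(model, samples=40)
        assert vols.v_min == pytest.approx(vols.v_max, rel=1e-12)
        assert vols.v_mean == pytest.approx(vols.v_max, rel=1e-12)

    def test_sinusoidal_ellipsoid_matches_closed_form(self):
        """Ellipsoid with a(t) = a0(1 + e sin) has V(t) = 4/3 pi a(t) b c."""
        sph = trimesh.creation.icosphere(4)
        b, c, a0, eps = 2.0, 1.5, 1.0, 0.15
        m = 20
        frames = np.empty((m, len(sph.vertices), 3))
        for i in range(m):
            a = a0 * (1 + eps * np.sin(2 * np.pi * i / m))
            frames[i] = np.asarray(sph.vertices) * [a, b, c]
        model = fit_fourier_model(frames, n_modes=6, period=1.0,
                                  faces=sph.faces)
        vols = compute_volume_series(model, samples=80)
        a_t = a0 * (1 + eps * np.sin(2 * np.pi * vols.times))
        exact = 4 * np.pi / 3 * a_t * b * c
        assert np.max(np.abs(vols.v_la - exact) / exact) < 5e-3

    def test_case_recovers_generator_extrema(self, default_case):
        vols = compute_volume_series(default_case.model, samples=100,
                                     waveforms=default_case.waveforms)
        p = default_case.params
        assert vols.v_max == pytest.approx(p.v_max, rel=0.01)
        assert vols.v_min == pytest.approx(p.v_min, rel=0.01)


# the six-subject reference table of chamber volumes (ml) and the
# index values they imply (2-decimal agreement)
SUBJECT_VOLUMES = {
    1: (59.6, 108.0, 94.3), 2: (49.0, 91.2, 72.3), 3: (87.2, 145.0, 119.0),
    4: (119.0, 155.0, 149.0), 5: (150.0, 165.0, 153.0), 6: (157.0, 205.0, 178.0),
}
SUBJECT_INDICES = {  # global EF, expansion, passive EF, booster EF
    1: (0.45, 0.81, 0.13, 0.37), 2: (0.46, 0.86, 0.21, 0.32),
    3: (0.40, 0.66, 0.18, 0.27), 4: (0.23, 0.30, 0.04, 0.20),
    5: (0.09, 0.10, 0.07, 0.02), 6: (0.23, 0.31, 0.13, 0.12),
}


def _series_from_volumes(vmin, vmax, vpre):
    times = np.array([0.0, 0.25, 0.5, 0.75])
    v = np.array([vmin, vmax, vpre, vmin])
    return kinematics.ChamberVolumeSeries(times=times, v_la=v, v_laa=None,
                                          period=1.0, pre_a_time=0.5)


class TestFunctionIndices:
    @pytest.mark.parametrize("subject", sorted(SUBJECT_VOLUMES))
    def test_reference_volume_rows_reproduce_reference_indices(self, subject):
        vols = _series_from_volumes(*SUBJECT_VOLUMES[subject])
        idx = atrial_function_indices(vols)
        g, e, p, b = SUBJECT_INDICES[subject]
        assert round(idx.global_ef, 2) == pytest.approx(g, abs=5e-3)
        assert round(idx.expansion_index, 2) == pytest.approx(e, abs=5e-3)
        assert round(idx.passive_ef, 2) == pytest.approx(p, abs=5e-3)
        assert round(idx.booster_ef, 2) == pytest.approx(b, abs=5e-3)

    def test_booster_zero_when_pre_a_equals_min(self):
        vols = _series_from_volumes(60.0, 100.0, 60.0)
        assert atrial_function_indices(vols).booster_ef == 0.0

    @given(vmin=st.floats(10.0, 150.0), ratio=st.floats(1.01, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_expansion_identity(self, vmin, ratio):
        """expansion = EF/(1-EF) holds exactly for any valid volume pair."""
        vmax = vmin * ratio
        vols = _series_from_volumes(vmin, vmax, 0.5 * (vmin + vmax))
        idx = atrial_function_indices(vols)
        assert idx.expansion_index == pytest.approx(
            idx.global_ef / (1 - idx.global_ef), rel=1e-12)

    def test_zero_denominator_raises(self):
        vols = _series_from_volumes(60.0, 100.0, 80.0)
        with pytest.raises(ZeroDivisionError):
            atrial_function_indices(vols, stroke_volume=0.0)


class TestPVFlowBalance:
    def _rigid_model(self):
        sph = trimesh.creation.icosphere(2)
        verts = np.tile(np.asarray(sph.vertices), (13, 1, 1))
        return fit_fourier_model(verts, n_modes=6, period=1.0,
                                 faces=sph.faces)

    def test_rigid_chamber_gives_qpv_equal_qmv(self):
        model = self._rigid_model()
        wf = pv_flow_balance(model, q_mv=lambda t: 80.0 + 10 * np.sin(t))
        for t in (0.0, 0.4, 0.9):
            assert wf.q_pv(t) == pytest.approx(wf.q_mv(t), abs=1e-9)

    def test_sinusoidal_volume_gives_analytic_derivative(self):
        """V(t) = V0 + a sin(2 pi t/T), Q_MV = 0 -> Q_PV = (2 pi a/T) cos."""
        sph = trimesh.creation.icosphere(3)
        r0, amp, m = 1.0, 0.05, 20
        frames = np.empty((m, len(sph.vertices), 3))
        for i in range(m):
            # r^3 chosen so that V(t) = 4/3 pi (1 + amp sin)
            r = r0 * (1 + amp * np.sin(2 * np.pi * i / m)) ** (1 / 3)
            frames[i] = np.asarray(sph.vertices) * r
        model = fit_fourier_model(frames, n_modes=6, period=1.0,
                                  faces=sph.faces)
        wf = pv_flow_balance(model, q_mv=lambda t: 0.0)
        v_sphere = kinematics.mesh_volume(trimesh.creation.icosphere(3))
        for t in np.linspace(0.05, 0.95, 7):
            exact = v_sphere * amp * 2 * np.pi * np.cos(2 * np.pi * t)
            assert wf.q_pv(t) == pytest.approx(exact, rel=1e-4)

    def test_even_split_across_veins(self, default_case):
        wf = default_case.waveforms
        for t in (0.1, 0.5, 0.9):
            assert wf.q_i(t) * 4 == pytest.approx(wf.q_pv(t), rel=1e-14)

    def test_mass_conservation_closure(self, default_case):
        """max_t |Q_PV - Q_MV - dV/dt| / max |Q_MV| below 1e-3."""
        wf = default_case.waveforms
        model = default_case.model
        ts = np.linspace(0, 1, 101)
        qmv_peak = max(abs(wf.q_mv(t)) for t in ts)
        resid = max(abs(wf.q_pv(t) - wf.q_mv(t) - model.volume_rate(t))
                    for t in ts)
        assert resid / qmv_peak < 1e-3

    def test_target_velocity_along_inlet_normal(self, default_case):
        wf = default_case.waveforms
        vt = wf.target_velocity(0, 0.2)
        inlet = wf.inlets[0]
        assert np.allclose(np.cross(vt, inlet.normal), 0.0, atol=1e-12)
        assert vt @ inlet.normal == pytest.approx(wf.q_i(0.2) / inlet.area)


class TestSphericity:
    def test_sphere_is_one(self):
        sph = trimesh.creation.icosphere(4)
        assert sphericity(sph) == pytest.approx(1.0, abs=2e-3)

    def test_cube_closed_form(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        expected = np.pi ** (1 / 3) * 6 ** (2 / 3) / 6
        assert sphericity(box) == pytest.approx(expected, rel=1e-10)

    def test_scale_invariance(self):
        sph = trimesh.creation.icosphere(2)
        big = trimesh.Trimesh(vertices=7.3 * np.asarray(sph.vertices),
                              faces=sph.faces, process=False)
        assert sphericity(big) == pytest.approx(sphericity(sph), rel=1e-12)
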